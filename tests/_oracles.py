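"""Independent reference implementations used only to check the package.

Everything here is deliberately written with different algorithms from the
package: plain-Python pair enumeration, numpy broadcasting, and closed-form
expressions for i.i.d. Gaussian data.
"""
from itertools import combinations

import numpy as np
from scipy.stats import norm


def brute_force_counts(segments, m, tol):
    """Enumerate every unordered template pair explicitly."""
    templates = []
    for seg in segments:
        seg = [float(v) for v in seg]
        for i in range(len(seg) - m):
            templates.append(seg[i: i + m + 1])
    B = A = 0
    for a, b in combinations(templates, 2):
        if all(abs(a[k] - b[k]) <= tol for k in range(m)):
            B += 1
            if abs(a[m] - b[m]) <= tol:
                A += 1
    return B, A


def brute_force_sampen(segments, m, tol):
    B, A = brute_force_counts(segments, m, tol)
    if A == 0 or B == 0:
        return float("nan")
    return float(np.log(B / A))


def continuous_mse_reference(x, m, r, scales):
    """Classic continuous MSE via numpy broadcasting over all pairs."""
    x = np.asarray(x, dtype=np.float64)
    tol = r * np.std(x, ddof=1)
    out = []
    for s in scales:
        k = x.size // s
        cg = x[: k * s].reshape(k, s).mean(axis=1)
        T = cg.size - m
        idx = np.arange(T)[:, None] + np.arange(m + 1)[None, :]
        tmpl = cg[idx]
        diff = np.abs(tmpl[:, None, :] - tmpl[None, :, :])
        match_m = diff[..., :m].max(axis=-1) <= tol
        match_m1 = match_m & (diff[..., m] <= tol)
        iu = np.triu_indices(T, 1)
        B = int(match_m[iu].sum())
        A = int(match_m1[iu].sum())
        out.append(np.log(B / A) if A > 0 and B > 0 else float("nan"))
    return np.asarray(out)


def gaussian_sampen_limit(r, scale=1):
    """SampEn of i.i.d. standard normal data, coarse-grained at a scale.

    Component match probability p = P(|X - Y| <= r) with X, Y independent
    N(0, 1/scale) and fixed tolerance r (from the native scale), giving
    SampEn -> -ln(p) = -ln(2 * Phi(r * sqrt(scale) / sqrt(2)) - 1).
    """
    return -np.log(2 * norm.cdf(r * np.sqrt(scale) / np.sqrt(2)) - 1)
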