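"""Applied statistics for entropy maps: condition contrasts, bias tests and
precision-based sample-size planning.

The planning logic treats the *precision* of an entropy estimate — the SD of
entropy values across subjects/replicates at a given data density — as the
population SD in a two-group comparison, so the sample size needed to detect
an expected raw entropy difference follows directly from a standard
two-sample normal-approximation power formula.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "PowerQuery",
    "PowerResult",
    "BiasTestResult",
    "paired_t_map",
    "sensitivity_specificity",
    "required_n",
    "required_n_unrounded",
    "bias_t",
]

#: per-group sample sizes above this are reported as capped (">1000")
N_CAP = 1000


def paired_t_map(a: np.ndarray, b: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise paired-samples t-tests between two condition maps.

    ``a`` and ``b`` are aligned arrays with subjects on axis 0 and any cell
    structure (unit x scale, ...) on the remaining axes. Returns (t, p)
    arrays over the cell axes with df = N - 1, two-sided p. Cells with zero
    difference variance give t = 0, p = 1 when the mean difference is also
    zero (identical conditions) and NaN flags otherwise; cells containing
    missing values are flagged NaN.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"condition maps differ in shape: {a.shape} vs "
                         f"{b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = a - b
    complete = np.all(np.isfinite(d), axis=0)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    p = 2.0 * _st.t.sf(np.abs(t), df=n - 1)
    zero_var = (sd == 0) & complete
    t = np.where(zero_var & (mean == 0), 0.0, t)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    t = np.where(zero_var & (mean != 0), np.nan, t)
    p = np.where(zero_var & (mean != 0), np.nan, p)
    t = np.where(complete, t, np.nan)
    p = np.where(complete, p, np.nan)
    return t, p


def sensitivity_specificity(
    test_p_map: np.ndarray,
    benchmark_p_map: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Agreement of a reduced-data significance map with a benchmark map.

    Sensitivity: of the cells significant in the benchmark, the fraction
    still significant in the test map. Specificity: of the cells
    non-significant in the benchmark, the fraction non-significant in the
    test map. Either is NaN when its benchmark denominator is empty. Cells
    that are NaN in either map are excluded.
    """
    tp = np.asarray(test_p_map, dtype=np.float64)
    bp = np.asarray(benchmark_p_map, dtype=np.float64)
    if tp.shape != bp.shape:
        raise ValueError("maps are not aligned")
    valid = np.isfinite(tp) & np.isfinite(bp)
    test_sig = (tp <= alpha) & valid
    bench_sig = (bp <= alpha) & valid
    n_pos = int((bench_sig & valid).sum())
    n_neg = int((~bench_sig & valid).sum())
    sensitivity = (
        float((test_sig & bench_sig).sum() / n_pos) if n_pos else float("nan"))
    specificity = (
        float((~test_sig & ~bench_sig & valid).sum() / n_neg)
        if n_neg else float("nan"))
    return sensitivity, specificity


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a two-independent-group sample-size calculation.

    precision : SD of the entropy estimate across subjects (the dispersion
        at the planned data density), used directly as the population SD.
    delta : expected raw entropy difference between the groups.
    power : target statistical power (1 - beta).
    alpha : two-sided significance level.
    """

    precision: float
    delta: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.precision > 0:
            raise ValueError("precision must be > 0")
        if not self.delta > 0:
            raise ValueError("delta must be > 0 (no effect to detect)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Required per-group N, with a cap flag for impractical sizes."""

    n_per_group: int
    capped: bool
    n_exact: float
    query: PowerQuery

    def __str__(self) -> str:
        return f">{N_CAP}" if self.capped else str(self.n_per_group)


def required_n_unrounded(q: PowerQuery) -> float:
    """Exact (real-valued) per-group N before ceiling.

    ``N = 2 * ((z_{1-alpha/2} + z_{power}) * precision / delta) ** 2`` for a
    two-sided two-independent-sample comparison under the normal
    approximation.
    """
    z_alpha = _st.norm.ppf(1 - q.alpha / 2)
    z_power = _st.norm.ppf(q.power)
    return 2.0 * ((z_alpha + z_power) * q.precision / q.delta) ** 2


def required_n(q: PowerQuery) -> PowerResult:
    """Required per-group sample size, rounded up to the next integer.

    Sizes above 1000 are flagged as capped (conventionally printed ">1000").
    """
    exact = required_n_unrounded(q)
    n = int(math.ceil(exact))
    return PowerResult(n_per_group=n, capped=n > N_CAP, n_exact=exact,
                       query=q)


@dataclass(frozen=True)
class BiasTestResult:
    """Unit-wise accuracy-bias t-test results."""

    t: np.ndarray
    p: np.ndarray
    df: int
    exceedance_count: int
    expected_chance_count: float
    p_threshold: float


def bias_t(
    unit_accuracy: np.ndarray,
    overall_accuracy: float,
    unit_precision: np.ndarray,
    n_subjects: int,
    p_threshold: float = 0.001,
) -> BiasTestResult:
    """Test whether each unit's accuracy deviates from the overall accuracy.

    ``t = (unit accuracy - overall accuracy) / (unit precision / sqrt(N))``
    with df = N - 1; the exceedance count is the number of units whose
    two-sided p falls below ``p_threshold``, reported alongside the count
    expected by chance (threshold x number of units). Units with zero
    precision are flagged NaN.
    """
    acc = np.asarray(unit_accuracy, dtype=np.float64)
    prec = np.asarray(unit_precision, dtype=np.float64)
    if acc.shape != prec.shape:
        raise ValueError("accuracy and precision maps are not aligned")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    df = n_subjects - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (acc - overall_accuracy) / (prec / math.sqrt(n_subjects))
    t = np.where(prec > 0, t, np.nan)
    p = 2.0 * _st.t.sf(np.abs(t), df=df)
    exceed = int(np.nansum(p < p_threshold))
    return BiasTestResult(
        t=t,
        p=p,
        df=df,
        exceedance_count=exceed,
        expected_chance_count=float(p_threshold * acc.size),
        p_threshold=p_threshold,
    )
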