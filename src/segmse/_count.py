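"""Numba kernel for template-pair counting.

The quadratic pair enumeration is the hot loop of sample entropy; everything
else in the package is cheap by comparison. Templates are processed in
ascending order of their first component so the inner loop can stop as soon
as the first-component difference exceeds the tolerance.
"""
from __future__ import annotations

import numba
import numpy as np


@numba.njit(numba.types.UniTuple(numba.int64, 2)(
    numba.float64[::1], numba.int64[::1], numba.int64, numba.float64))
def _count_pairs_sorted(data, starts, m, tol):
    # starts must be ordered by data[start]; each start s guarantees that
    # data[s : s + m + 1] lies within one segment.
    B = np.int64(0)
    A = np.int64(0)
    T = starts.shape[0]
    for ai in range(T):
        sa = starts[ai]
        a0 = data[sa]
        for bi in range(ai + 1, T):
            sb = starts[bi]
            if data[sb] - a0 > tol:
                break  # sorted: no later template can match on component 0
            ok = True
            for k in range(1, m):
                if abs(data[sb + k] - data[sa + k]) > tol:
                    ok = False
                    break
            if ok:
                B += 1
                if abs(data[sb + m] - data[sa + m]) <= tol:
                    A += 1
    return B, A


def count_pairs(data: np.ndarray, starts: np.ndarray, m: int, tol: float):
    """Count matching m- and (m+1)-template pairs (Chebyshev, inclusive).

    ``data`` is the concatenation of all segments; ``starts`` are the valid
    template start offsets (m+1 samples available within the segment).
    Returns ``(B, A)``: the number of unordered template pairs matching on
    the first m components, and on all m+1 components.
    """
    data = np.ascontiguousarray(data, dtype=np.float64)
    starts = np.asarray(starts, dtype=np.int64)
    order = np.argsort(data[starts], kind="stable")
    return _count_pairs_sorted(data, starts[order], m, float(tol))
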