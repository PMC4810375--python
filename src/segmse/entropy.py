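"""Sample entropy (SampEn) and multiscale entropy (MSE) estimation.

Supports both classic continuous series and *discontinuous* collections of
equal-length segments. For segmented data two constraints apply:

1. coarse-graining is performed segment-wise (never across segments), and
2. templates (patterns) never span a segment border.

Pattern counts from all segments are pooled, so time scales far beyond the
reach of a single short segment become estimable as long as enough segments
are available; the largest admissible scale is ``floor(n / (m + 1))`` for
segments of n samples and pattern length m.

The tolerance within which two samples count as equal is ``r * SD`` where SD
is taken once from the native (scale-1) data and reused at every scale, so
entropy at coarse scales is measured relative to the overall variability of
the signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._count import count_pairs

__all__ = [
    "EntropyError",
    "InvalidScaleError",
    "SegmentTooShortError",
    "DegenerateSignalError",
    "EntropyParams",
    "SegmentSet",
    "SampEnResult",
    "MSEProfile",
    "coarse_grain",
    "max_scale",
    "count_pattern_pairs",
    "sample_entropy",
    "mse",
    "n_pattern_comparisons",
]


class EntropyError(ValueError):
    """Base class for entropy-domain errors."""


class InvalidScaleError(EntropyError):
    """A requested coarse-graining scale is out of range."""


class SegmentTooShortError(EntropyError):
    """A segment is too short for the requested pattern length / scale."""


class DegenerateSignalError(EntropyError):
    """The signal has zero variance, so no tolerance can be derived."""


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the SampEn / MSE estimator.

    m : pattern (template) length, a.k.a. embedding dimension.
    r : tolerance as a fraction of the native-scale standard deviation.
    sd_policy : "pooled" derives the SD from the SegmentSet itself (all
        native-scale samples pooled); "external" uses a caller-supplied SD,
        e.g. the SD of a longer series the segments were drawn from.
    match_rule : only "inclusive" is supported — two samples are equal when
        their absolute difference is <= r * SD.
    """

    m: int = 2
    r: float = 0.5
    sd_policy: str = "pooled"
    match_rule: str = "inclusive"

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise EntropyError(f"m must be a positive integer, got {self.m}")
        if not (self.r > 0):
            raise EntropyError(f"r must be > 0, got {self.r}")
        if self.sd_policy not in ("pooled", "external"):
            raise EntropyError(f"unknown sd_policy: {self.sd_policy!r}")
        if self.match_rule != "inclusive":
            raise EntropyError(f"unknown match_rule: {self.match_rule!r}")
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "r", float(self.r))


class SegmentSet:
    """Ordered collection of equal-length real-valued segments of one unit.

    A single-segment SegmentSet is an ordinary continuous time series; all
    entropy routines then reduce exactly to their classic continuous form.
    """

    def __init__(
        self,
        segments: Iterable[Sequence[float]],
        sampling_rate: float | None = None,
        unit_id: str = "unit",
        allow_unequal: bool = False,
    ) -> None:
        segs = [np.ascontiguousarray(s, dtype=np.float64) for s in segments]
        if len(segs) < 1:
            raise EntropyError("SegmentSet needs at least one segment")
        for i, s in enumerate(segs):
            if s.ndim != 1:
                raise EntropyError(f"segment {i} is not one-dimensional")
            if s.size < 1:
                raise EntropyError(f"segment {i} is empty")
            if not np.all(np.isfinite(s)):
                raise EntropyError(f"segment {i} contains non-finite values")
        lengths = {s.size for s in segs}
        if len(lengths) > 1 and not allow_unequal:
            raise EntropyError(
                f"segments have unequal lengths {sorted(lengths)}; "
                "pass allow_unequal=True to accept (max scale then follows "
                "the shortest segment)"
            )
        if sampling_rate is not None and not sampling_rate > 0:
            raise EntropyError("sampling_rate must be positive")
        self.segments: tuple[np.ndarray, ...] = tuple(segs)
        self.sampling_rate = sampling_rate
        self.unit_id = unit_id
        self.allow_unequal = allow_unequal

    @classmethod
    def from_continuous(
        cls,
        series: Sequence[float],
        sampling_rate: float | None = None,
        unit_id: str = "unit",
    ) -> "SegmentSet":
        return cls([series], sampling_rate=sampling_rate, unit_id=unit_id)

    @property
    def j(self) -> int:
        """Number of segments."""
        return len(self.segments)

    @property
    def n(self) -> int:
        """Segment length (shortest segment when lengths are unequal)."""
        return min(s.size for s in self.segments)

    @property
    def total_points(self) -> int:
        return sum(s.size for s in self.segments)

    def pooled_sd(self) -> float:
        """Sample SD over all native-scale samples pooled across segments."""
        pooled = np.concatenate(self.segments)
        if pooled.size < 2:
            return 0.0
        return float(np.std(pooled, ddof=1))

    def max_scale(self, m: int) -> int:
        return max_scale(self.n, m)

    def coarse_grained(self, s: int) -> "SegmentSet":
        """Segment-wise coarse-graining at scale s (never across borders)."""
        return SegmentSet(
            [coarse_grain(seg, s) for seg in self.segments],
            sampling_rate=None if self.sampling_rate is None
            else self.sampling_rate / s,
            unit_id=self.unit_id,
            allow_unequal=self.allow_unequal,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SegmentSet(unit_id={self.unit_id!r}, j={self.j}, "
                f"n={self.n})")


def coarse_grain(segment: Sequence[float], s: int) -> np.ndarray:
    """Average s successive non-overlapping samples; drop the remainder.

    The scale-s series has ``floor(n/s)`` points, the k-th being the mean of
    samples ``(k-1)*s .. k*s - 1``. Scale 1 returns the segment unchanged.
    """
    x = np.ascontiguousarray(segment, dtype=np.float64)
    if int(s) != s or s < 1:
        raise InvalidScaleError(f"scale must be a positive integer, got {s}")
    s = int(s)
    if s > x.size:
        raise InvalidScaleError(
            f"scale {s} exceeds segment length {x.size}")
    k = x.size // s
    return x[: k * s].reshape(k, s).mean(axis=1)


def max_scale(n: int, m: int) -> int:
    """Largest admissible coarse-graining scale, ``floor(n / (m + 1))``.

    At this scale each coarse-grained segment retains at least m + 1 points,
    the minimum needed to form one (m+1)-template.
    """
    if n < m + 1:
        raise SegmentTooShortError(
            f"segment length {n} < m + 1 = {m + 1}: no template fits")
    return n // (m + 1)


def _template_layout(segset: SegmentSet, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate segments and list valid template start offsets.

    Template starts are restricted to within-segment positions that leave
    m + 1 samples available, so every m-template has a same-start
    (m+1)-template and no template crosses a segment border.
    """
    offsets = []
    offset = 0
    for i, seg in enumerate(segset.segments):
        if seg.size < m + 1:
            raise SegmentTooShortError(
                f"segment {i} of unit {segset.unit_id!r} has {seg.size} "
                f"points < m + 1 = {m + 1}")
        offsets.append(np.arange(offset, offset + seg.size - m, dtype=np.int64))
        offset += seg.size
    data = np.concatenate(segset.segments)
    starts = np.concatenate(offsets)
    return data, starts


def count_pattern_pairs(
    segset: SegmentSet, m: int, tol: float
) -> tuple[int, int]:
    """Count matching template pairs pooled over all segments.

    Returns ``(B, A)`` where B is the number of unordered pairs of
    m-templates (from any segments, self-pairs excluded) that match
    component-wise within ``tol`` (Chebyshev distance, inclusive), and A the
    number of pairs whose (m+1)-extensions match. ``A <= B`` always.
    """
    if not tol > 0:
        raise EntropyError(f"tolerance must be > 0, got {tol}")
    data, starts = _template_layout(segset, m)
    return count_pairs(data, starts, m, tol)


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with the match counts that produced it.

    ``value`` is NaN when undefined (A == 0 or B == 0); the counts are kept
    so callers can decide how to treat undefined replicates.
    """

    value: float
    B: int
    A: int
    tolerance: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))

    def __float__(self) -> float:
        return float(self.value)


def sample_entropy(
    segset: SegmentSet,
    params: EntropyParams | None = None,
    tol: float | None = None,
    sd: float | None = None,
) -> SampEnResult:
    """Sample entropy ``ln(B/A)`` of a (possibly segmented) series.

    If ``tol`` is not given it is derived as ``params.r * SD`` with SD from
    the pooled native-scale samples (or ``sd`` under the external policy).
    Returns a :class:`SampEnResult`; the value is NaN if no (m+1)-pattern
    pair matched (A == 0), rather than infinity.
    """
    params = params or EntropyParams()
    if tol is None:
        tol = params.r * _native_sd(segset, params, sd)
    if not tol > 0:
        raise EntropyError(f"tolerance must be > 0, got {tol}")
    B, A = count_pattern_pairs(segset, params.m, tol)
    value = float(np.log(B / A)) if (A > 0 and B > 0) else float("nan")
    return SampEnResult(value=value, B=int(B), A=int(A), tolerance=float(tol))


def _native_sd(
    segset: SegmentSet, params: EntropyParams, sd: float | None
) -> float:
    if params.sd_policy == "external":
        if sd is None:
            raise EntropyError("sd_policy='external' requires an sd value")
        if not sd > 0:
            raise DegenerateSignalError(f"external SD must be > 0, got {sd}")
        return float(sd)
    value = segset.pooled_sd()
    if not value > 0:
        raise DegenerateSignalError(
            f"unit {segset.unit_id!r} has zero native-scale SD; "
            "no tolerance can be derived")
    return value


@dataclass
class MSEProfile:
    """Per-scale entropy values with the bookkeeping behind them.

    ``entropy`` holds NaN at scales where SampEn is undefined (no matching
    (m+1)-pairs); ``defined`` flags the usable scales. ``tolerance`` is the
    single r*SD value (native scale) reused at every scale.
    """

    unit_id: str
    scales: np.ndarray
    entropy: np.ndarray
    B: np.ndarray
    A: np.ndarray
    n_comparisons: np.ndarray
    tolerance: float
    sd_native: float
    params: EntropyParams = field(default_factory=EntropyParams)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.entropy)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-scale table (one row per scale)."""
        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "scale": self.scales,
                "entropy": self.entropy,
                "B": self.B,
                "A": self.A,
                "n_comparisons": self.n_comparisons,
                "tolerance": self.tolerance,
                "defined": self.defined,
            }
        )


def mse(
    segset: SegmentSet,
    params: EntropyParams | None = None,
    scales: Sequence[int] | None = None,
    sd: float | None = None,
) -> MSEProfile:
    """Multiscale entropy over the requested scales.

    The tolerance ``r * SD`` is fixed once from the native (scale-1) data —
    pooled over all segments under the default policy — and reused at every
    scale. Each scale coarse-grains every segment separately, pools the
    template-pair counts and takes ``ln(B/A)``.
    """
    params = params or EntropyParams()
    if scales is None:
        scales = range(1, segset.max_scale(params.m) + 1)
    scales_arr = np.asarray(list(scales), dtype=np.int64)
    if scales_arr.size == 0:
        raise InvalidScaleError("no scales requested")
    if np.any(scales_arr < 1):
        raise InvalidScaleError("scales must be >= 1")
    limit = segset.max_scale(params.m)
    if np.any(scales_arr > limit):
        raise InvalidScaleError(
            f"requested scale {int(scales_arr.max())} exceeds max scale "
            f"{limit} = floor(n/(m+1)) for n={segset.n}, m={params.m}")
    sd_native = _native_sd(segset, params, sd)
    tol = params.r * sd_native

    entropy = np.full(scales_arr.size, np.nan)
    B = np.zeros(scales_arr.size, dtype=np.int64)
    A = np.zeros(scales_arr.size, dtype=np.int64)
    ncmp = np.zeros(scales_arr.size, dtype=np.int64)
    for i, s in enumerate(scales_arr):
        cg = segset if s == 1 else segset.coarse_grained(int(s))
        b, a = count_pattern_pairs(cg, params.m, tol)
        B[i], A[i] = b, a
        ncmp[i] = sum(seg.size - params.m for seg in cg.segments)
        if a > 0 and b > 0:
            entropy[i] = np.log(b / a)
    return MSEProfile(
        unit_id=segset.unit_id,
        scales=scales_arr,
        entropy=entropy,
        B=B,
        A=A,
        n_comparisons=ncmp,
        tolerance=float(tol),
        sd_native=float(sd_native),
        params=params,
    )


def n_pattern_comparisons(n: int, j: int, m: int) -> int:
    """Data-density bookkeeping: ``(n - m) * j`` templates across segments.

    This is the quantity that makes continuous and segmented estimates
    comparable: a continuous series of ``(n - m) * j + m`` points offers the
    same number of templates as j segments of n points.
    """
    if n < m + 1:
        raise SegmentTooShortError(f"n={n} < m+1={m + 1}")
    if j < 1:
        raise EntropyError(f"j must be >= 1, got {j}")
    return (n - m) * j
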