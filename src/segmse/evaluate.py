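"""Accuracy/precision evaluation harness for SampEn and MSE estimators.

Accuracy (Delta) is the absolute deviation of the ensemble-mean entropy from
the mean of a long-series benchmark ensemble; precision is the SD of the
entropy estimates across replicates. Both are reported per
(segment count j, segment length n, scale) cell, with log10 views, mirroring
heat-map style summaries. Continuous and segmented estimates are compared at
an equal number of pattern comparisons, (n - m) * j.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import (
    EntropyParams,
    SegmentSet,
    max_scale,
    mse,
    sample_entropy,
)
from .noise import simulate_ensemble

__all__ = [
    "EvalGrid",
    "BenchmarkResult",
    "sampen_ensemble",
    "benchmark",
    "draw_segments",
    "equate_continuous_length",
    "run_grid",
]

#: default total-data cap for grid cells, 20 segments of 1024 points
DEFAULT_MAX_TOTAL = 20 * 1024


@dataclass(frozen=True)
class EvalGrid:
    """Grid of (j, n, scale) cells to evaluate against a benchmark.

    Cells are evaluable only when ``scale <= floor(n / (m + 1))`` and
    ``j * n <= max_total_points``; others are emitted flagged, mirroring the
    blank cells of a feasibility heat map.
    """

    j_values: tuple[int, ...] = (10, 20, 40, 80, 160, 320, 640)
    n_values: tuple[int, ...] = (16, 32, 64, 128, 256, 512, 1024)
    scales: tuple[int, ...] = tuple(range(1, 21))
    params: EntropyParams = field(default_factory=EntropyParams)
    replicates: int = 100
    benchmark_length: int = 2 ** 16
    benchmark_replicates: int = 1000
    max_total_points: int = DEFAULT_MAX_TOTAL


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-scale mean and SD of entropy over a long-series ensemble."""

    scales: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_defined: np.ndarray
    replicates: int
    length: int


def sampen_ensemble(
    series: np.ndarray,
    params: EntropyParams | None = None,
) -> np.ndarray:
    """SampEn of every row of an ensemble; NaN where undefined.

    Each series uses its own r * SD tolerance (native scale).
    """
    params = params or EntropyParams()
    series = np.atleast_2d(np.asarray(series, dtype=np.float64))
    out = np.empty(series.shape[0])
    for i, row in enumerate(series):
        out[i] = sample_entropy(
            SegmentSet.from_continuous(row), params).value
    return out


def benchmark(
    kind: str,
    params: EntropyParams | None = None,
    scales: tuple[int, ...] | list[int] = (1,),
    length: int = 2 ** 16,
    replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    apply_highpass: bool = True,
    sampling_rate: float = 1024.0,
) -> BenchmarkResult:
    """Benchmark mean/SD entropy from long continuous series.

    Generates ``replicates`` fresh series of ``length`` points, computes the
    MSE profile of each (tolerance from each series' own SD), and returns
    per-scale means and SDs with undefined replicates dropped and counted.
    """
    params = params or EntropyParams()
    if length < 10_000:
        import warnings

        warnings.warn(
            f"benchmark length {length} < 10000: long series are "
            "recommended for a stable reference", stacklevel=2)
    scales_arr = np.asarray(list(scales), dtype=np.int64)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values = np.full((replicates, scales_arr.size), np.nan)
    for i in range(replicates):
        x = simulate_ensemble(kind, length, 1, seed=rng,
                              sampling_rate=sampling_rate,
                              apply_highpass=apply_highpass)[0]
        prof = mse(SegmentSet.from_continuous(x), params, scales_arr)
        values[i] = prof.entropy
    n_def = np.isfinite(values).sum(axis=0)
    if np.any(n_def == 0):
        bad = scales_arr[n_def == 0]
        raise RuntimeError(
            f"all benchmark replicates undefined at scales {bad.tolist()}")
    return BenchmarkResult(
        scales=scales_arr,
        mean=np.nanmean(values, axis=0),
        sd=np.nanstd(values, axis=0, ddof=1),
        n_defined=n_def,
        replicates=replicates,
        length=length,
    )


def draw_segments(
    series: np.ndarray,
    j: int,
    n: int,
    policy: str = "consecutive",
    rng: np.random.Generator | int | None = None,
    unit_id: str = "unit",
) -> SegmentSet:
    """Parse a continuous series into j segments of n points.

    "consecutive" (default) splits the first j*n samples into j adjacent
    blocks; "random-nonoverlapping" places j non-overlapping windows at
    uniform-random offsets. Both are deterministic given the rng/seed.
    """
    x = np.asarray(series, dtype=np.float64)
    if j < 1 or n < 1:
        raise ValueError("j and n must be >= 1")
    if x.size < j * n:
        raise ValueError(
            f"series has {x.size} points; j*n = {j * n} required")
    if policy == "consecutive":
        segs = x[: j * n].reshape(j, n)
    elif policy == "random-nonoverlapping":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        # sample j non-overlapping windows: choose gaps by stars-and-bars
        slack = x.size - j * n
        cuts = np.sort(rng.integers(0, slack + 1, size=j))
        offsets = cuts + n * np.arange(j)
        segs = np.stack([x[o: o + n] for o in offsets])
    else:
        raise ValueError(f"unknown segment policy: {policy!r}")
    return SegmentSet(list(segs), unit_id=unit_id)


def equate_continuous_length(n: int, j: int, m: int) -> int:
    """Continuous length N with the same template count as j segments of n.

    Solves ``N - m = (n - m) * j``; with j = 1 this returns n itself.
    """
    if n < m + 1:
        raise ValueError(f"n={n} < m+1={m + 1}")
    return (n - m) * j + m


def run_grid(
    grid: EvalGrid,
    kind: str,
    seed: int | np.random.Generator | None = None,
    benchmark_result: BenchmarkResult | None = None,
    apply_highpass: bool = True,
    sampling_rate: float = 1024.0,
) -> pd.DataFrame:
    """Evaluate accuracy/precision over all (j, n, scale) cells of a grid.

    Each replicate draws a fresh noise series of j*n points, splits it into
    consecutive segments, and computes the MSE profile over the evaluable
    scales; accuracy and precision are then taken across replicates against
    the benchmark mean. Returns a tidy frame with one row per cell,
    including flagged non-evaluable cells (NaN metrics).
    """
    params = grid.params
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if benchmark_result is None:
        benchmark_result = benchmark(
            kind, params, scales=grid.scales, length=grid.benchmark_length,
            replicates=grid.benchmark_replicates, seed=rng,
            apply_highpass=apply_highpass, sampling_rate=sampling_rate)
    bench_mean = dict(zip(benchmark_result.scales.tolist(),
                          benchmark_result.mean))
    rows = []
    for j in grid.j_values:
        for n in grid.n_values:
            cell_limit = max_scale(n, params.m) if n >= params.m + 1 else 0
            evaluable_scales = [
                s for s in grid.scales
                if s <= cell_limit and j * n <= grid.max_total_points
            ]
            if evaluable_scales:
                est = np.full((grid.replicates, len(evaluable_scales)),
                              np.nan)
                for rep in range(grid.replicates):
                    # series shorter than the filter pad cannot be filtered
                    x = simulate_ensemble(
                        kind, j * n, 1, seed=rng,
                        sampling_rate=sampling_rate,
                        apply_highpass=apply_highpass and j * n >= 16)[0]
                    segset = draw_segments(x, j, n)
                    prof = mse(segset, params, evaluable_scales)
                    est[rep] = prof.entropy
            for s in grid.scales:
                row = {"kind": kind, "j": j, "n": n, "scale": s}
                if s in evaluable_scales:
                    col = est[:, evaluable_scales.index(s)]
                    defined = np.isfinite(col)
                    n_used = int(defined.sum())
                    if n_used >= 2:
                        acc = abs(np.mean(col[defined]) - bench_mean[s])
                        prec = float(np.std(col[defined], ddof=1))
                    else:
                        acc, prec = np.nan, np.nan
                    row.update(
                        evaluable=True,
                        accuracy=acc,
                        precision=prec,
                        log10_accuracy=np.log10(acc) if acc and acc > 0
                        else np.nan,
                        log10_precision=np.log10(prec) if prec and prec > 0
                        else np.nan,
                        n_replicates=n_used,
                        undefined_fraction=1 - n_used / grid.replicates,
                    )
                else:
                    row.update(
                        evaluable=False, accuracy=np.nan, precision=np.nan,
                        log10_accuracy=np.nan, log10_precision=np.nan,
                        n_replicates=0, undefined_fraction=np.nan,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def median_heatmap(grid_table: pd.DataFrame, metric: str = "accuracy"
                   ) -> pd.DataFrame:
    """Median of a metric across evaluated scales, as a (j x n) pivot."""
    evaluated = grid_table[grid_table["evaluable"]]
    return evaluated.pivot_table(index="j", columns="n", values=metric,
                                 aggfunc="median")
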