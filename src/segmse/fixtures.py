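"""Seeded synthetic datasets for end-to-end testing and demos.

The two-condition fixture emulates the *shape* of a within-subject resting
EEG contrast (eyes-closed vs eyes-open): per subject and channel, segments
of 1/f background noise; in condition A a band-limited (alpha-like)
oscillation of known, subject-varying amplitude is added to a known subset
of channels, so a true effect exists at known cells and detection can be
scored against ground truth. It is synthetic; it does not reproduce real
EEG topography, artifacts, or between-subject spectral differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .entropy import SegmentSet
from .io import write_segments, write_sidecar
from .noise import FilterSpec, NoiseSpec, generate, highpass

__all__ = ["TwoConditionData", "two_condition_data", "make_fixture"]


@dataclass
class TwoConditionData:
    """In-memory two-condition dataset.

    ``conditions[cond][subject][channel]`` is a SegmentSet; ``effect_mask``
    flags the channels carrying the condition-A oscillation.
    """

    conditions: dict[str, list[list[SegmentSet]]]
    effect_mask: np.ndarray
    sampling_rate: float
    oscillation_hz: float
    params: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.conditions["A"])

    @property
    def n_channels(self) -> int:
        return len(self.conditions["A"][0])


def two_condition_data(
    seed: int | np.random.Generator | None = 0,
    n_subjects: int = 19,
    n_channels: int = 12,
    n_segments: int = 20,
    segment_length: int = 256,
    sampling_rate: float = 250.0,
    oscillation_hz: float = 10.0,
    effect_amplitude: float = 1.0,
    amplitude_jitter: float = 0.2,
    effect_fraction: float = 1 / 3,
) -> TwoConditionData:
    """Generate the two-condition dataset (fully seeded).

    Background: 1/f noise per subject x channel x condition, cut into
    ``n_segments`` segments of ``segment_length`` points, standardised and
    high-pass filtered at ``sampling_rate / 2**10``. Condition A adds a
    sinusoid at ``oscillation_hz`` (random phase per segment) with subject
    amplitude ``effect_amplitude * (1 + jitter)`` times the background SD to
    the first ``ceil(effect_fraction * n_channels)`` channels.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_effect = int(np.ceil(effect_fraction * n_channels))
    effect_mask = np.zeros(n_channels, dtype=bool)
    effect_mask[:n_effect] = True

    fspec = FilterSpec(sampling_rate=sampling_rate)
    total = n_segments * segment_length
    t = np.arange(segment_length) / sampling_rate
    conditions: dict[str, list[list[SegmentSet]]] = {"A": [], "B": []}
    for subj in range(n_subjects):
        amp = effect_amplitude * (1 + amplitude_jitter * rng.standard_normal())
        amp = max(amp, 0.0)
        for cond in ("A", "B"):
            row: list[SegmentSet] = []
            for chan in range(n_channels):
                spec = NoiseSpec(kind="one_over_f", length=total,
                                 sampling_rate=sampling_rate)
                x = highpass(generate(spec, rng=rng)[0], fspec)
                segs = x.reshape(n_segments, segment_length).copy()
                if cond == "A" and effect_mask[chan] and amp > 0:
                    phases = rng.uniform(0, 2 * np.pi, size=n_segments)
                    segs += amp * np.sin(
                        2 * np.pi * oscillation_hz * t[None, :]
                        + phases[:, None])
                row.append(SegmentSet(
                    list(segs), sampling_rate=sampling_rate,
                    unit_id=f"s{subj:02d}_c{chan:02d}"))
            conditions[cond].append(row)
    return TwoConditionData(
        conditions=conditions,
        effect_mask=effect_mask,
        sampling_rate=sampling_rate,
        oscillation_hz=oscillation_hz,
        params=dict(
            n_subjects=n_subjects, n_channels=n_channels,
            n_segments=n_segments, segment_length=segment_length,
            effect_amplitude=effect_amplitude,
            amplitude_jitter=amplitude_jitter,
        ),
    )


def make_fixture(
    kind: str,
    seed: int,
    out_dir: str | Path,
    **overrides,
) -> Path:
    """Write a synthetic on-disk dataset; returns the dataset directory.

    kind="two-condition": per-condition manifests (``A/manifest.tsv``,
    ``B/manifest.tsv``) of subject x channel units plus a
    ``ground_truth.tsv`` channel effect mask. kind="grid-demo": one unit of
    white-noise segments for exercising the mse/evaluate commands.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "two-condition":
        data = two_condition_data(seed=seed, **overrides)
        for cond in ("A", "B"):
            flat = [ss for row in data.conditions[cond] for ss in row]
            write_segments(flat, out_dir / cond)
        lines = ["channel\thas_effect"]
        lines += [f"c{c:02d}\t{int(flag)}"
                  for c, flag in enumerate(data.effect_mask)]
        (out_dir / "ground_truth.tsv").write_text("\n".join(lines) + "\n")
        write_sidecar(out_dir / "fixture", {
            "kind": kind, "seed": seed, **data.params})
    elif kind == "grid-demo":
        rng = np.random.default_rng(seed)
        j, n = overrides.pop("j", 10), overrides.pop("n", 128)
        if overrides:
            raise TypeError(f"unknown options {sorted(overrides)}")
        x = generate(NoiseSpec(kind="white", length=j * n), rng=rng)[0]
        segset = SegmentSet(list(x.reshape(j, n)), unit_id="demo")
        write_segments([segset], out_dir)
        write_sidecar(out_dir / "fixture", {"kind": kind, "seed": seed,
                                            "j": j, "n": n})
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return out_dir
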