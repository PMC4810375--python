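"""Plain-text input/output: segment manifests, tidy tables, run configs.

All on-disk formats are delimited text. Segmented data is described by a
tab-separated manifest with columns ``unit_id  segment_index  path  column``;
each referenced file holds one sample per row (extra columns selected by the
``column`` field, ``#`` comment lines and non-numeric header lines skipped).
A single-file dialect with blank-line-separated segment blocks is also
supported. Every CLI run writes a sidecar YAML recording the configuration,
seeds and package version needed to reproduce it.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .entropy import MSEProfile, SegmentSet

__all__ = [
    "DataError",
    "Manifest",
    "RunConfig",
    "read_segments",
    "write_segments",
    "read_segment_blocks",
    "write_profile_table",
    "read_profile_table",
    "write_sidecar",
]

MANIFEST_COLUMNS = ("unit_id", "segment_index", "path", "column")
MANIFEST_VERSION = "1"


class DataError(ValueError):
    """A file could not be parsed or violates the format contract."""


@dataclass(frozen=True)
class Manifest:
    """Parsed segment manifest: one row per (unit, segment) pair."""

    rows: tuple[tuple[str, int, str, int], ...]
    version: str = MANIFEST_VERSION


def _read_numeric_column(path: Path, column: int) -> np.ndarray:
    """One sample per row; '#' comments and non-numeric headers skipped."""
    if not path.exists():
        raise DataError(f"{path}: file not found")
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            cells = text.replace(",", "\t").split()
            if column >= len(cells):
                raise DataError(
                    f"{path}:{lineno}: column {column} missing "
                    f"({len(cells)} columns present)")
            try:
                values.append(float(cells[column]))
            except ValueError:
                if not values:  # tolerate a header line before any data
                    continue
                raise DataError(
                    f"{path}:{lineno}: non-numeric value "
                    f"{cells[column]!r}") from None
    if not values:
        raise DataError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=np.float64)


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: manifest not found")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            cells = text.split("\t")
            if [c.strip() for c in cells[:4]] == list(MANIFEST_COLUMNS):
                continue  # header
            if len(cells) < 4:
                raise DataError(
                    f"{path}:{lineno}: expected 4 tab-separated columns "
                    f"{MANIFEST_COLUMNS}, got {len(cells)}")
            unit_id, seg_idx, seg_path, column = (c.strip() for c in cells[:4])
            try:
                rows.append((unit_id, int(seg_idx), seg_path, int(column)))
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: segment_index and column must be "
                    "integers") from None
    if not rows:
        raise DataError(f"{path}: empty manifest")
    return Manifest(rows=tuple(rows))


def read_segments(
    manifest_path: str | Path,
    allow_unequal: bool = False,
    sampling_rate: float | None = None,
) -> dict[str, SegmentSet]:
    """Load all units of a manifest into SegmentSets.

    Relative segment paths are resolved against the manifest's directory.
    segment_index must be contiguous from 1 within each unit.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    per_unit: dict[str, dict[int, np.ndarray]] = {}
    for unit_id, seg_idx, seg_path, column in manifest.rows:
        p = Path(seg_path)
        if not p.is_absolute():
            p = base / p
        per_unit.setdefault(unit_id, {})[seg_idx] = _read_numeric_column(
            p, column)
    out = {}
    for unit_id, segs in per_unit.items():
        indices = sorted(segs)
        if indices != list(range(1, len(indices) + 1)):
            raise DataError(
                f"unit {unit_id!r}: segment_index must be contiguous from "
                f"1, got {indices}")
        try:
            out[unit_id] = SegmentSet(
                [segs[i] for i in indices], unit_id=unit_id,
                allow_unequal=allow_unequal, sampling_rate=sampling_rate)
        except ValueError as exc:
            raise DataError(f"unit {unit_id!r}: {exc}") from exc
    return out


def write_segments(
    segsets: Mapping[str, SegmentSet] | Iterable[SegmentSet],
    out_dir: str | Path,
    manifest_name: str = "manifest.tsv",
) -> Path:
    """Write SegmentSets as one file per segment plus a manifest.

    Returns the manifest path; read_segments() round-trips the result.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(segsets, Mapping):
        items = list(segsets.values())
    else:
        items = list(segsets)
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for segset in items:
        for i, seg in enumerate(segset.segments, start=1):
            fname = f"{segset.unit_id}_seg{i:04d}.txt"
            np.savetxt(out_dir / fname, seg, fmt="%.17g")
            lines.append(f"{segset.unit_id}\t{i}\t{fname}\t0")
    manifest_path = out_dir / manifest_name
    manifest_path.write_text("\n".join(lines) + "\n")
    return manifest_path


def read_segment_blocks(
    path: str | Path,
    unit_id: str | None = None,
    allow_unequal: bool = False,
) -> SegmentSet:
    """Single-file dialect: segments separated by blank lines."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    blocks: list[list[float]] = []
    current: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if text.startswith("#"):
                continue
            if not text:
                if current:
                    blocks.append(current)
                    current = []
                continue
            try:
                current.append(float(text.split()[0]))
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: non-numeric value {text!r}") from None
    if current:
        blocks.append(current)
    if not blocks:
        raise DataError(f"{path}: no segment blocks found")
    try:
        return SegmentSet(blocks, unit_id=unit_id or path.stem,
                          allow_unequal=allow_unequal)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_profile_table(
    profiles: Iterable[MSEProfile], path: str | Path
) -> Path:
    """Tidy per-scale output: unit_id, scale, entropy, B, A, ..."""
    path = Path(path)
    table = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_profile_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """Flat, serialisable record of one analysis run's settings.

    Round-trips losslessly through a plain-text YAML mapping; unknown keys
    are rejected on load so stale configs fail loudly.
    """

    m: int = 2
    r: float = 0.5
    scales: str = "1:20"
    sd_policy: str = "pooled"
    seed: int = 0
    replicates: int = 100
    kind: str = "white"
    length: int = 2 ** 14
    sampling_rate: float = 1024.0
    highpass: bool = True
    j_values: str = "10,20,40,80,160,320,640"
    n_values: str = "16,32,64,128,256,512,1024"
    out: str = ""

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.__dict__, sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise DataError(f"{path}: config not found")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise DataError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(
                f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def parse_scales(text: str) -> list[int]:
    """Parse a scale list: '1:20' (inclusive range) or '1,2,5'."""
    text = text.strip()
    try:
        if ":" in text:
            lo, hi = text.split(":")
            lo, hi = int(lo), int(hi)
            if lo < 1 or hi < lo:
                raise ValueError
            return list(range(lo, hi + 1))
        return [int(t) for t in text.split(",") if t.strip()]
    except ValueError:
        raise DataError(f"cannot parse scales {text!r}; use 'lo:hi' or "
                        "a comma list") from None


def write_sidecar(out_path: str | Path, payload: dict[str, Any]) -> Path:
    """Write a reproducibility sidecar next to an output file."""
    from . import __version__

    out_path = Path(out_path)
    sidecar = out_path.with_name(out_path.name + ".run.yaml")
    record = {"segmse_version": __version__, **payload}
    sidecar.write_text(yaml.safe_dump(record, sort_keys=True))
    return sidecar
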