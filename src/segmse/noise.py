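"""Synthetic noise ensembles: Gaussian white noise and 1/f (pink) noise.

These are the study signals of the simulation harness. 1/f noise is
synthesised by spectrally shaping white Gaussian noise: the rFFT of a white
series is multiplied by ``f ** (-alpha/2)`` (alpha = 1 for pink noise), the
DC bin is zeroed, and the result is transformed back. Each series is
standardised to zero mean and unit SD and may then be high-pass filtered
with a zero-phase 4th-order Butterworth filter (cutoff = sampling_rate /
2**10) so that the low-frequency content is equated across series lengths —
without this, short 1/f series systematically under-represent slow
fluctuations and hence under-estimate the SD that scales the entropy
tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = ["NoiseSpec", "FilterSpec", "generate", "highpass",
           "simulate_ensemble"]

#: frequency-cutoff divisor for the standard high-pass: cutoff = fs / 2**10
CUTOFF_DIVISOR = 2 ** 10


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of a noise ensemble.

    kind : "white" (flat spectrum) or "one_over_f" (power ~ 1/f^alpha).
    spectral_exponent : alpha; defaults to 0 for white, 1 for one_over_f.
    sampling_rate : Hz; only sets the physical scale of filter cutoffs.
    """

    kind: str
    length: int
    replicates: int = 1
    sampling_rate: float = 1024.0
    spectral_exponent: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def alpha(self) -> float:
        if self.spectral_exponent is not None:
            return float(self.spectral_exponent)
        return 1.0 if self.kind == "one_over_f" else 0.0


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase high-pass Butterworth filter.

    The default cutoff, ``sampling_rate / 2**10``, keeps spectral power at
    the low end of the spectrum constant across signal lengths.
    """

    sampling_rate: float = 1024.0
    order: int = 4
    cutoff: float | None = None  # Hz; default sampling_rate / 2**10

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        c = self.cutoff_hz
        if not (0 < c < self.sampling_rate / 2):
            raise ValueError(
                f"cutoff {c} Hz outside (0, Nyquist={self.sampling_rate / 2})")

    @property
    def cutoff_hz(self) -> float:
        if self.cutoff is not None:
            return float(self.cutoff)
        return self.sampling_rate / CUTOFF_DIVISOR

    def sos(self) -> np.ndarray:
        return _signal.butter(
            self.order, self.cutoff_hz, btype="highpass",
            fs=self.sampling_rate, output="sos")


def generate(spec: NoiseSpec, rng: np.random.Generator | None = None
             ) -> np.ndarray:
    """Generate an ensemble of noise series, shape (replicates, length).

    Deterministic given ``spec.seed`` (or an explicit ``rng``). Every series
    is standardised to zero mean and unit sample SD.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal((spec.replicates, spec.length))
    if spec.alpha == 0:
        x = w
    else:
        spectrum = np.fft.rfft(w, axis=-1)
        f = np.fft.rfftfreq(spec.length, d=1.0 / spec.sampling_rate)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-spec.alpha / 2.0)
        spectrum *= shape
        x = np.fft.irfft(spectrum, n=spec.length, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / sd


def highpass(series: np.ndarray, fspec: FilterSpec) -> np.ndarray:
    """Apply the zero-phase (forward-backward) high-pass filter.

    Accepts a single series or an ensemble (last axis = time). Removes the
    DC component exactly in the limit; leaves the passband untouched.
    """
    x = np.asarray(series, dtype=np.float64)
    sos = fspec.sos()
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= max(padlen, 3 * fspec.order):
        raise ValueError(
            f"series of length {x.shape[-1]} too short for stable "
            f"zero-phase filtering (need > {max(padlen, 3 * fspec.order)})")
    return _signal.sosfiltfilt(sos, x, axis=-1)


def simulate_ensemble(
    kind: str,
    length: int,
    replicates: int,
    seed: int | np.random.Generator | None = None,
    sampling_rate: float = 1024.0,
    apply_highpass: bool = True,
    spectral_exponent: float | None = None,
) -> np.ndarray:
    """Standardised (and by default high-pass-filtered) noise ensemble.

    Convenience wrapper used throughout the evaluation harness; returns an
    array of shape (replicates, length).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    spec = NoiseSpec(kind=kind, length=length, replicates=replicates,
                     sampling_rate=sampling_rate,
                     spectral_exponent=spectral_exponent)
    x = generate(spec, rng=rng)
    if apply_highpass:
        x = highpass(x, FilterSpec(sampling_rate=sampling_rate))
    return x
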