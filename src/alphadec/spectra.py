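"""Epoched signals and smoothed log power spectral densities.

This module turns multichannel resting-state EEG epochs into the smoothed
log10 power spectra the decomposition stage consumes: amplitude-based epoch
rejection (strict +/-90 uV rule, with subject-level exclusion when more than
half of the epochs are contaminated) followed by Welch-style averaging of
zero-padded modified periodograms at 0.25 Hz resolution on 2-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "EpochedSignal",
    "PowerSpectrum",
    "InputError",
    "ProcessingError",
    "reject_epochs",
    "welch_psd",
    "default_freq_grid",
]

#: Default analysis band (Hz) and bin spacing of the smoothed spectrum.
FREQ_LO = 2.0
FREQ_HI = 40.0
FREQ_RES = 0.25

#: Amplitude threshold (uV) beyond which an epoch counts as artifactual.
ARTIFACT_THRESHOLD_UV = 90.0

#: Fraction of rejected epochs above which the whole recording is dropped.
SUBJECT_REJECTION_FRACTION = 0.5


class InputError(ValueError):
    """Raised when inputs violate a precondition (empty signal, bad grid)."""


class ProcessingError(RuntimeError):
    """Raised when a processing step cannot produce output (e.g. no epochs left)."""


def default_freq_grid(lo: float = FREQ_LO, hi: float = FREQ_HI,
                      res: float = FREQ_RES) -> np.ndarray:
    """Evenly spaced frequency grid [lo, hi] inclusive at resolution ``res``."""
    n = int(round((hi - lo) / res))
    grid = lo + res * np.arange(n + 1)
    return grid


@dataclass
class EpochedSignal:
    """Fixed-length epochs of a single channel, in microvolts.

    ``samples`` has shape (n_epochs, n_samples); ``fs`` is the sampling rate
    in Hz.  All epochs share the same length, so ``epoch_length`` is implied
    by the array shape.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InputError("samples must be 2-D (n_epochs, n_samples)")
        if self.fs < 100:
            raise InputError(f"sampling rate {self.fs} Hz too low (need >= 100 Hz)")

    @property
    def n_epochs(self) -> int:
        return self.samples.shape[0]

    @property
    def epoch_length(self) -> float:
        """Epoch duration in seconds."""
        return self.samples.shape[1] / self.fs


@dataclass
class PowerSpectrum:
    """A power spectral density on an evenly spaced frequency grid.

    ``power`` is stored in log10 units when ``scale_tag == "log"`` (the
    working convention of the whole pipeline) and in linear units otherwise.
    """

    freqs: np.ndarray
    power: np.ndarray
    scale_tag: str = "log"
    n_epochs_used: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise InputError("freqs and power must have matching shapes")
        if self.freqs.ndim != 1 or self.freqs.size < 3:
            raise InputError("need a 1-D grid with at least 3 bins")
        if np.any(np.diff(self.freqs) <= 0):
            raise InputError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.power)):
            raise InputError("power must be finite at every bin")
        if self.scale_tag not in ("log", "linear"):
            raise InputError(f"unknown scale_tag {self.scale_tag!r}")

    def to_linear(self) -> "PowerSpectrum":
        if self.scale_tag == "linear":
            return self
        return PowerSpectrum(self.freqs, 10.0 ** self.power, "linear",
                             self.n_epochs_used, dict(self.meta))

    def to_log(self) -> "PowerSpectrum":
        if self.scale_tag == "log":
            return self
        if np.any(self.power <= 0):
            raise ProcessingError("non-positive linear power cannot be log-transformed")
        return PowerSpectrum(self.freqs, np.log10(self.power), "log",
                             self.n_epochs_used, dict(self.meta))

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def reject_epochs(sig: EpochedSignal,
                  threshold: float = ARTIFACT_THRESHOLD_UV):
    """Flag epochs containing high-amplitude artifacts.

    An epoch is rejected iff any sample lies strictly beyond the
    threshold (> +90 uV or < -90 uV); a sample at exactly +/-threshold
    does not count as an artifact.  The subject is marked for exclusion
    when the rejected fraction exceeds 0.5.

    Returns
    -------
    kept : bool array (n_epochs,)
    subject_excluded : bool
    rejection_fraction : float
    """
    if sig.n_epochs < 1:
        raise InputError("signal contains no epochs")
    peak = np.max(np.abs(sig.samples), axis=1)
    kept = peak <= threshold
    frac = 1.0 - kept.mean()
    excluded = bool(frac > SUBJECT_REJECTION_FRACTION)
    return kept, excluded, float(frac)


def welch_psd(sig: EpochedSignal, kept: np.ndarray | None = None,
              resolution: float = FREQ_RES,
              freq_range: tuple[float, float] = (FREQ_LO, FREQ_HI),
              window: str = "hamming") -> PowerSpectrum:
    """Average modified periodograms of the kept epochs into a log10 PSD.

    Each epoch is tapered (Hamming by default), zero padded so that the bin
    spacing equals ``resolution`` (2 s epochs padded to 4 s give 0.25 Hz),
    and its one-sided periodogram is averaged with the others.  Output is
    restricted to ``freq_range`` and log10 transformed.
    """
    if kept is None:
        kept = np.ones(sig.n_epochs, dtype=bool)
    kept = np.asarray(kept, dtype=bool)
    if kept.shape != (sig.n_epochs,):
        raise InputError("kept mask shape does not match epoch count")
    if not kept.any():
        raise ProcessingError("no epochs left after rejection")

    nfft = int(round(sig.fs / resolution))
    nper = sig.samples.shape[1]
    if nfft < nper:
        raise InputError("requested resolution finer than epoch length allows "
                         "only via truncation; increase resolution or epoch length")
    data = sig.samples[kept]
    freqs, pxx = sp_signal.periodogram(
        data, fs=sig.fs, window=window, nfft=nfft, detrend=False, axis=-1,
        scaling="density")
    mean_pxx = pxx.mean(axis=0)

    lo, hi = freq_range
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    freqs, mean_pxx = freqs[mask], mean_pxx[mask]
    if np.any(mean_pxx <= 0):
        raise ProcessingError("zero power bin encountered; cannot log-transform")
    return PowerSpectrum(freqs, np.log10(mean_pxx), "log",
                         n_epochs_used=int(kept.sum()),
                         meta={"window": window, "resolution": resolution})
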