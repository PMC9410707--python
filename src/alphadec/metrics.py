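"""Per-electrode alpha/aperiodic metrics and subject-level aggregation.

Nine parameters are extracted per electrode from a smoothed log spectrum and
its decomposition: the individual alpha frequency (IAF), total / relative /
aperiodic-adjusted alpha power in both the canonical 8-13 Hz band and an
individualized band [IAF-4, IAF+2] Hz, and the aperiodic intercept and
exponent.  Electrode metrics are averaged over the parieto-occipital cluster
(electrodes whose decomposition fails the R^2 > 0.90 quality gate are left
out of the average), and subjects are excluded when no IAF can be detected
or when any parameter lies beyond 3 sample standard deviations from the
cohort mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .spectra import PowerSpectrum, InputError
from .parameterize import SpectralFit, periodic_spectrum, DEFAULT_MIN_R_SQUARED

__all__ = [
    "AlphaMetrics",
    "SubjectMetrics",
    "METRIC_FIELDS",
    "CANONICAL_BAND",
    "IAF_SEARCH_WINDOW",
    "INDIVIDUAL_BAND_OFFSETS",
    "detect_iaf",
    "band_average",
    "compute_metrics",
    "aggregate_cluster",
    "flag_outliers",
]

CANONICAL_BAND = (8.0, 13.0)
IAF_SEARCH_WINDOW = (7.0, 14.0)
#: Individualized band relative to the IAF: [IAF - 4, IAF + 2] Hz.
INDIVIDUAL_BAND_OFFSETS = (-4.0, 2.0)
FULL_RANGE = (2.0, 40.0)

#: The five posterior electrodes averaged per subject.
DEFAULT_CLUSTER = ("POz", "Oz", "Pz", "PO3", "PO4")


@dataclass
class AlphaMetrics:
    """The extracted parameters for one electrode (or a cluster average)."""

    iaf: float = math.nan
    total_canonical: float = math.nan
    total_individualized: float = math.nan
    relative_canonical: float = math.nan
    relative_individualized: float = math.nan
    adjusted_canonical: float = math.nan
    adjusted_individualized: float = math.nan
    aperiodic_intercept: float = math.nan
    aperiodic_exponent: float = math.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_FIELDS = tuple(f.name for f in fields(AlphaMetrics))


@dataclass
class SubjectMetrics:
    """Cluster-aggregated metrics plus exclusion bookkeeping."""

    metrics: AlphaMetrics
    n_electrodes_used: int
    excluded: bool = False
    reason: str | None = None  # {no_iaf, too_many_artifacts, outlier}


def detect_iaf(spectrum: PowerSpectrum, lo: float = IAF_SEARCH_WINDOW[0],
               hi: float = IAF_SEARCH_WINDOW[1]) -> float | None:
    """Frequency of maximum power in [lo, hi]; None for border maxima.

    A maximum sitting exactly on either border of the search window is
    treated as evidence of no detectable alpha peak (the spectrum is still
    rising or falling there), and None is returned.  Ties break toward the
    lower frequency via argmax.
    """
    if spectrum.scale_tag != "log":
        spectrum = spectrum.to_log()
    freqs, power = spectrum.freqs, spectrum.power
    if freqs[0] > lo + 1e-9 or freqs[-1] < hi - 1e-9:
        raise InputError(f"grid does not cover the IAF window [{lo}, {hi}] Hz")
    sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    wf, wp = freqs[sel], power[sel]
    idx = int(np.argmax(wp))
    if idx == 0 or idx == wf.size - 1:
        return None
    return float(wf[idx])


def band_average(spectrum: PowerSpectrum, band: tuple[float, float],
                 scale: str = "log") -> float:
    """Arithmetic mean of power over a band, endpoints inclusive.

    ``scale="log"`` averages the stored log10 values; ``scale="linear"``
    back-transforms first and averages linear power.
    """
    if spectrum.scale_tag != "log":
        spectrum = spectrum.to_log()
    lo, hi = band
    sel = (spectrum.freqs >= lo - 1e-9) & (spectrum.freqs <= hi + 1e-9)
    if not sel.any():
        raise InputError(f"band [{lo}, {hi}] Hz contains no grid bins")
    vals = spectrum.power[sel]
    if scale == "linear":
        return float(np.mean(10.0 ** vals))
    if scale != "log":
        raise InputError(f"unknown scale {scale!r}")
    return float(np.mean(vals))


def compute_metrics(spectrum: PowerSpectrum, fit: SpectralFit) -> AlphaMetrics:
    """All nine parameters for one electrode.

    Total measures are log-band means of the measured spectrum; relative
    measures divide linear band power by the linear 2-40 Hz mean; adjusted
    measures are log-band means of the aperiodic-adjusted (periodic)
    spectrum.  When no IAF is detected, the individualized fields stay NaN
    but every canonical and aperiodic field is still produced.
    """
    out = AlphaMetrics()
    out.aperiodic_intercept = fit.aperiodic.offset
    out.aperiodic_exponent = fit.aperiodic.exponent

    adjusted = periodic_spectrum(spectrum, fit)
    full_linear_mean = band_average(spectrum, FULL_RANGE, scale="linear")

    out.total_canonical = band_average(spectrum, CANONICAL_BAND, scale="log")
    out.relative_canonical = (band_average(spectrum, CANONICAL_BAND, scale="linear")
                              / full_linear_mean)
    out.adjusted_canonical = band_average(adjusted, CANONICAL_BAND, scale="log")

    iaf = detect_iaf(spectrum)
    if iaf is not None:
        out.iaf = iaf
        band = (iaf + INDIVIDUAL_BAND_OFFSETS[0], iaf + INDIVIDUAL_BAND_OFFSETS[1])
        out.total_individualized = band_average(spectrum, band, scale="log")
        out.relative_individualized = (band_average(spectrum, band, scale="linear")
                                       / full_linear_mean)
        out.adjusted_individualized = band_average(adjusted, band, scale="log")
    return out


def aggregate_cluster(electrodes: list[tuple[AlphaMetrics, SpectralFit]],
                      min_r2: float = DEFAULT_MIN_R_SQUARED) -> SubjectMetrics:
    """Average metrics over the electrode cluster with fit-quality fallback.

    Electrodes whose decomposition has R^2 <= ``min_r2`` are dropped before
    averaging; remaining fields are averaged parameter-wise, ignoring NaN
    per field (an electrode without an IAF still contributes its canonical
    and aperiodic values).  A subject with no usable electrode is flagged,
    never silently averaged; a subject whose usable electrodes all lack an
    IAF is flagged ``no_iaf``.
    """
    if not electrodes:
        raise InputError("aggregate_cluster needs at least one electrode")
    usable = [m for m, fit in electrodes if fit.r_squared > min_r2]
    if not usable:
        return SubjectMetrics(AlphaMetrics(), 0, excluded=True, reason="no_fit")
    agg = AlphaMetrics()
    for name in METRIC_FIELDS:
        vals = [getattr(m, name) for m in usable]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            setattr(agg, name, float(np.mean(vals)))
    if math.isnan(agg.iaf):
        return SubjectMetrics(agg, len(usable), excluded=True, reason="no_iaf")
    return SubjectMetrics(agg, len(usable))


def flag_outliers(table: pd.DataFrame, k: float = 3.0,
                  columns: tuple[str, ...] | None = None) -> pd.Series:
    """Single-pass 3-sd outlier mask over a cohort metric table.

    A subject is flagged when ANY listed parameter lies beyond
    mean +/- k*sd of the sample for that parameter.  Means and sds are
    computed once on the full table (no iterative re-trimming).
    Zero-variance columns are skipped with a warning.
    """
    if len(table) < 3:
        raise InputError("outlier detection needs at least 3 subjects")
    if columns is None:
        columns = tuple(c for c in METRIC_FIELDS if c in table.columns)
    mask = pd.Series(False, index=table.index)
    for col in columns:
        vals = table[col].astype(float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {col!r} has zero variance; skipped")
            continue
        mu = vals.mean()
        mask |= (vals - mu).abs() > k * sd
    return mask
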