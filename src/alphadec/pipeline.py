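"""End-to-end orchestration: cohort -> spectra -> decomposition -> models.

Glue around the stage modules: simulate every electrode of every subject,
decompose, extract and aggregate metrics, apply the cohort-level outlier
rule, and fit the standardized covariate models whose coefficients the
calibration and the acceptance checks compare against published effect
sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import reject_epochs, welch_psd, ProcessingError
from .parameterize import FitSettings, parameterize_spectrum, FitError
from .metrics import (compute_metrics, aggregate_cluster, flag_outliers,
                      METRIC_FIELDS)
from .stats import ModelSpec, fit_outcome_model, gelman_scale, zscore
from . import synth

__all__ = ["run_cohort_pipeline", "fit_covariate_models", "OUTCOMES"]

OUTCOMES = synth.CALIBRATION_OUTCOMES


def run_cohort_pipeline(cohort: pd.DataFrame, preset: "synth.GenerativePreset",
                        seed: int, settings: FitSettings | None = None,
                        mode: str = "spectrum",
                        duration: float = 190.0, fs: float = 500.0) -> pd.DataFrame:
    """Per-subject aggregated metrics for a sampled cohort.

    ``mode="spectrum"`` synthesizes smoothed spectra directly (model curve
    plus bin noise); ``mode="timeseries"`` synthesizes raw signals and runs
    them through epoch rejection and Welch averaging first.  Subjects are
    flagged excluded for missing IAF, inadequate fits, excessive epoch
    rejection (time-series mode), or the single-pass 3-sd outlier rule.
    """
    settings = settings or FitSettings()
    rows = []
    for i, (_, subj) in enumerate(cohort.iterrows()):
        params = {p: subj[f"true_{p}"] for p in synth.PARAM_NAMES}
        electrodes = []
        rejected = False
        for e in range(preset.n_electrodes):
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), 2, i, e)))
            if mode == "spectrum":
                spec = synth.generate_spectrum(params, preset, rng)
            elif mode == "timeseries":
                sig = synth.generate_timeseries(
                    params, preset, duration, fs,
                    seed=int(rng.integers(0, 2 ** 31)))
                kept, subject_excluded, _ = reject_epochs(sig)
                if subject_excluded:
                    rejected = True
                    break
                try:
                    spec = welch_psd(sig, kept)
                except ProcessingError:
                    rejected = True
                    break
            else:
                raise ValueError(f"unknown mode {mode!r}")
            try:
                fit = parameterize_spectrum(spec, settings)
            except FitError:
                continue
            electrodes.append((compute_metrics(spec, fit), fit))

        if rejected or not electrodes:
            record = {name: np.nan for name in METRIC_FIELDS}
            record.update(n_electrodes_used=0, excluded=True,
                          reason="too_many_artifacts")
        else:
            sm_ = aggregate_cluster(electrodes, min_r2=settings.min_r_squared)
            record = sm_.metrics.as_dict()
            record.update(n_electrodes_used=sm_.n_electrodes_used,
                          excluded=sm_.excluded, reason=sm_.reason)
        rows.append(record)

    table = pd.DataFrame(rows, index=cohort.index)
    ok = ~table["excluded"]
    if ok.sum() >= 3:
        outlier = flag_outliers(table.loc[ok], k=3.0)
        idx = outlier.index[outlier]
        table.loc[idx, "excluded"] = True
        table.loc[idx, "reason"] = "outlier"
    return table


def fit_covariate_models(metrics_table: pd.DataFrame, cohort: pd.DataFrame,
                         interval_level: float = 0.95) -> dict:
    """Standardized covariate coefficients recovered from a simulated cohort.

    Three model families, mirroring the maturation analysis:

    * ``outcome ~ age + gender`` for each of the six individualized
      outcomes, with outcome and age scaled to sd 0.5 and gender as a raw
      0/1 dummy -> "age" and "gender" coefficient maps;
    * ``adjusted ~ fa_left + icv + age + gender`` with numeric variables
      scaled to sd 0.5 -> "fa" coefficient;
    * ``adjusted ~ flanker_score + age + gender`` with plain z-scored
      numerics -> "score" coefficient.
    """
    merged = pd.concat([cohort.reset_index(drop=True),
                        metrics_table.reset_index(drop=True)], axis=1)
    data = merged.loc[~merged["excluded"]].copy()

    results = {"age": {}, "gender": {}, "fa": {}, "score": {}}
    for outcome in OUTCOMES:
        d = pd.DataFrame({
            "y": gelman_scale(data[outcome]),
            "age": gelman_scale(data["age"]),
            "gender": data["gender"].astype(float),
        })
        res = fit_outcome_model(
            ModelSpec("y", ["age", "gender"], interval_level=interval_level), d)
        results["age"][outcome] = res.coefficient("age")
        results["gender"][outcome] = res.coefficient("gender")

    d = pd.DataFrame({
        "y": gelman_scale(data["adjusted_individualized"]),
        "fa_left": gelman_scale(data["fa_left"]),
        "icv": gelman_scale(data["icv"]),
        "age": gelman_scale(data["age"]),
        "gender": data["gender"].astype(float),
    })
    res = fit_outcome_model(
        ModelSpec("y", ["fa_left", "icv", "age", "gender"],
                  interval_level=interval_level), d)
    results["fa"]["adjusted_individualized"] = res.coefficient("fa_left")

    d = pd.DataFrame({
        "y": zscore(data["adjusted_individualized"]),
        "flanker_score": zscore(data["flanker_score"]),
        "age": zscore(data["age"]),
        "gender": data["gender"].astype(float),
    })
    res = fit_outcome_model(
        ModelSpec("y", ["flanker_score", "age", "gender"],
                  interval_level=interval_level), d)
    results["score"]["adjusted_individualized"] = res.coefficient("flanker_score")
    return results
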