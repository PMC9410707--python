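# alphadec

Periodic/aperiodic decomposition of resting-state EEG alpha activity,
with a calibrated synthetic-cohort generator for end-to-end verification.

## The problem

Developmental EEG studies ask how the dominant posterior alpha rhythm
changes as the brain matures.  Conventional readouts confound distinct
mechanisms: *total* band power mixes the oscillation with the 1/f-like
aperiodic background; *relative* band power is additionally distorted by
power changes in other bands; and fixed 8–13 Hz band limits miss the
slower alpha peaks of young children.  The remedy is to decompose the log
power spectrum

```
P(F) = b − χ·log10 F + Σₙ hₙ exp(−(F − cₙ)²/2wₙ²) + ε
```

into an aperiodic component (offset `b`, exponent `χ`) plus Gaussian
peaks, detect each subject's individual alpha frequency (IAF), and
measure alpha power in the individualized band [IAF−4, IAF+2] Hz both
from the raw spectrum and from the aperiodic-adjusted spectrum.  This
package implements that chain for researchers who want the decomposition,
the metric definitions, the exclusion rules and the standardized
regression models as tested, reusable parts:

* `alphadec.spectra` — 2 s epoching, strict ±90 μV artifact rejection
  (subject dropped above 50% rejected), Welch averaging of zero-padded
  periodograms at 0.25 Hz on 2–40 Hz;
* `alphadec.parameterize` — robust aperiodic fitting, iterative Gaussian
  peak extraction with a 2-sd threshold, a joint refit polish, and an
  R² > 0.90 quality gate;
* `alphadec.metrics` — IAF detection (7–14 Hz, border maxima rejected),
  the nine per-electrode parameters, parieto-occipital cluster averaging
  with fit-quality fallback, single-pass 3-sd outlier exclusion;
* `alphadec.stats` — mean-0/sd-0.5 scaling, OLS and Cauchy-prior MCMC
  backends, effective-number-of-tests (Šidák/Bonferroni) multiplicity
  correction, posterior→prior sequential updating;
* `alphadec.synth` — cohort generator whose covariate effects on the
  latent spectral parameters are *calibrated* so that the coefficients
  recovered by the full pipeline match published developmental effect
  sizes (packaged preset `hbn_main`);
* `alphadec.confounds` — noise-free scenarios demonstrating the biases of
  relative and canonical-band measures.

## Worked example

```python
import numpy as np
from alphadec import (load_preset, sample_cohort, generate_spectrum,
                      parameterize_spectrum, compute_metrics)

preset = load_preset("hbn_main")
cohort = sample_cohort(preset, n=5, seed=7)
subj = cohort.iloc[0]
params = {p: subj[f"true_{p}"] for p in
          ("offset", "exponent", "iaf", "alpha_level", "alpha_width",
           "theta_level")}
spec = generate_spectrum(params, preset, seed=0)
fit = parameterize_spectrum(spec)
m = compute_metrics(spec, fit)
print(f"offset {fit.aperiodic.offset:.3f}  exponent "
      f"{fit.aperiodic.exponent:.3f}  R2 {fit.r_squared:.4f}")
print(f"IAF {m.iaf:.2f} Hz  adjusted alpha {m.adjusted_individualized:.3f}")
```

prints

```
offset 0.496  exponent 1.081  R2 0.9955
IAF 10.50 Hz  adjusted alpha 0.316
```

i.e. the decomposition recovers this subject's generative background
(true offset 0.452, exponent 1.052) from the noisy spectrum, finds the
alpha peak near the true 10.67 Hz, and reports the mean
aperiodic-adjusted log power in the individualized band
[IAF−4, IAF+2] = [6.5, 12.5] Hz.

A full cohort analysis is two more calls:

```python
from alphadec import run_cohort_pipeline, fit_covariate_models
table = run_cohort_pipeline(cohort, preset, seed=7)      # metrics + exclusions
results = fit_covariate_models(table, cohort)            # standardized betas
```

`results["age"]` then holds the standardized age coefficient per outcome
(IAF, total/relative/adjusted individualized alpha, aperiodic intercept
and exponent).

There is also a thin CLI: `alphadec simulate --preset hbn_main --n 2000
--seed 42 --out cohort_dir`, `alphadec decompose psd.csv`,
`alphadec confound --scenario exponent_shift --levels 1.0:2.0:0.25`.

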