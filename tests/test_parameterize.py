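import numpy as np
import pytest
from scipy.optimize import curve_fit

from alphadec.spectra import PowerSpectrum
from alphadec.parameterize import (FitSettings, fit_aperiodic_simple,
                                   fit_aperiodic_robust, extract_peaks,
                                   parameterize_spectrum, periodic_spectrum,
                                   aperiodic_model, gaussian_model)


def direct_joint_fit(spectrum, n_peaks):
    """Independent oracle: one-shot nonlinear least squares of the full
    parametric model (aperiodic + n_peaks Gaussians) with deterministic
    multi-start initialization.  No greedy iteration, no flattening."""
    freqs, power = spectrum.freqs, spectrum.power

    def model(f, *theta):
        out = aperiodic_model(f, theta[0], theta[1])
        for k in range(2, len(theta), 3):
            out = out + gaussian_model(f, *theta[k:k + 3])
        return out

    slope0 = -(power[-1] - power[0]) / (np.log10(freqs[-1]) - np.log10(freqs[0]))
    base = [power[0] + slope0 * np.log10(freqs[0]), slope0]
    center_sets = {
        0: [[]],
        1: [[10.0], [6.0], [12.0]],
        2: [[4.0, 10.0], [6.0, 10.0], [8.0, 12.0]],
    }[n_peaks]
    best = None
    for centers in center_sets:
        p0 = list(base)
        lo = [-np.inf, -np.inf]
        hi = [np.inf, np.inf]
        for c in centers:
            p0 += [c, 0.5, 1.5]
            lo += [freqs[0], 0.0, 0.3]
            hi += [freqs[-1], 3.0, 12.0]
        try:
            popt, _ = curve_fit(model, freqs, power, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
        except RuntimeError:
            continue
        sse = np.sum((power - model(freqs, *popt)) ** 2)
        if best is None or sse < best[0]:
            best = (sse, popt)
    assert best is not None
    popt = best[1]
    peaks = sorted(
        [tuple(popt[k:k + 3]) for k in range(2, len(popt), 3)])
    return popt[0], popt[1], peaks


class TestAperiodicFit:
    def test_pure_aperiodic_recovered_exactly(self, make_spectrum):
        fit = fit_aperiodic_robust(make_spectrum(offset=1.0, exponent=1.5))
        assert fit.offset == pytest.approx(1.0, abs=1e-3)
        assert fit.exponent == pytest.approx(1.5, abs=1e-3)

    def test_flat_spectrum_gives_zero_exponent(self, grid):
        spec = PowerSpectrum(grid, np.full(grid.size, 0.7), "log")
        fit = fit_aperiodic_robust(spec)
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)
        assert fit.offset == pytest.approx(0.7, abs=1e-9)

    def test_robust_fit_resists_large_peak(self, make_spectrum):
        # a naive single-pass fit is dragged up by the alpha peak; the
        # two-pass masked fit must not be
        spec = make_spectrum(offset=1.0, exponent=1.5,
                             peaks=[(10.0, 1.0, 2.0)])
        naive = fit_aperiodic_simple(spec.freqs, spec.power)
        robust = fit_aperiodic_robust(spec)
        assert abs(robust.exponent - 1.5) < 0.05
        assert abs(naive.exponent - 1.5) > 2 * abs(robust.exponent - 1.5)


class TestPeakExtraction:
    def test_exact_single_gaussian(self, grid):
        flat = PowerSpectrum(grid, gaussian_model(grid, 10.0, 0.8, 1.5), "log")
        peaks = extract_peaks(flat)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.center == pytest.approx(10.0, abs=1e-2)
        assert pk.height == pytest.approx(0.8, abs=1e-2)
        assert pk.width == pytest.approx(1.5, abs=1e-2)

    def test_two_peaks_taller_extracted_first(self, grid):
        flat = gaussian_model(grid, 6.0, 0.5, 1.0) + \
            gaussian_model(grid, 10.0, 0.8, 1.0)
        flat_iter = flat.copy()
        # greedy order property: the first guess is the 10 Hz peak
        first = grid[np.argmax(flat_iter)]
        assert first == pytest.approx(10.0, abs=0.25)
        peaks = extract_peaks(PowerSpectrum(grid, flat, "log"))
        assert len(peaks) == 2
        centers = sorted(p.center for p in peaks)
        assert centers[0] == pytest.approx(6.0, abs=0.1)
        assert centers[1] == pytest.approx(10.0, abs=0.1)

    def test_peak_count_monotone_in_min_height(self, grid):
        rng = np.random.default_rng(11)
        n_low, n_high = [], []
        for _ in range(50):
            noise = rng.normal(0, 0.05, grid.size)
            flat = PowerSpectrum(grid, noise, "log")
            n_low.append(len(extract_peaks(flat, FitSettings())))
            n_high.append(len(extract_peaks(
                flat, FitSettings(min_peak_height=0.1))))
        assert np.mean(n_high) <= np.mean(n_low)

    def test_empty_output_for_featureless_residual(self, grid):
        flat = PowerSpectrum(grid, np.zeros(grid.size), "log")
        assert extract_peaks(flat) == []


class TestFullDecomposition:
    def test_noiseless_round_trip(self, make_spectrum):
        spec = make_spectrum(offset=1.0, exponent=1.2,
                             peaks=[(10.0, 0.7, 1.5)])
        fit = parameterize_spectrum(spec)
        assert fit.aperiodic.offset == pytest.approx(1.0, abs=0.05)
        assert fit.aperiodic.exponent == pytest.approx(1.2, abs=0.05)
        alpha = max(fit.peaks, key=lambda p: p.height)
        assert alpha.center == pytest.approx(10.0, abs=0.25)
        assert alpha.height == pytest.approx(0.7, abs=0.05)
        assert alpha.width == pytest.approx(1.5, abs=0.3)
        assert fit.r_squared > 0.999

    def test_model_is_aperiodic_plus_peaks(self, make_spectrum):
        spec = make_spectrum(peaks=[(9.0, 0.6, 1.2)], noise_sd=0.03)
        fit = parameterize_spectrum(spec)
        reconstructed = fit.aperiodic.curve(spec.freqs) + \
            fit.peak_curve(spec.freqs)
        assert np.max(np.abs(reconstructed - fit.model_spectrum)) < 1e-9

    def test_deterministic(self, make_spectrum):
        spec = make_spectrum(peaks=[(9.5, 0.6, 1.2), (4.0, 0.3, 1.0)],
                             noise_sd=0.05, seed=3)
        f1 = parameterize_spectrum(spec)
        f2 = parameterize_spectrum(spec)
        assert f1.aperiodic == f2.aperiodic
        assert f1.peaks == f2.peaks
        assert np.array_equal(f1.model_spectrum, f2.model_spectrum)

    def test_noisy_fit_quality_stays_high(self, make_spectrum):
        r2 = []
        for seed in range(200):
            spec = make_spectrum(offset=0.8, exponent=1.5,
                                 peaks=[(9.5, 0.6, 1.2), (4.0, 0.35, 1.0)],
                                 noise_sd=0.05, seed=seed)
            r2.append(parameterize_spectrum(spec).r_squared)
        assert np.median(r2) > 0.97

    def test_quality_gate_flag(self, make_spectrum, grid):
        good = parameterize_spectrum(make_spectrum(peaks=[(10, 0.6, 1.2)]))
        assert good.adequate
        rng = np.random.default_rng(0)
        junk = PowerSpectrum(grid, rng.normal(0, 1.0, grid.size), "log")
        bad = parameterize_spectrum(junk)
        assert bad.r_squared <= 0.90 and not bad.adequate

    def test_recovery_error_monotone_in_noise(self, make_spectrum):
        errs = []
        for noise in (0.0, 0.02, 0.05, 0.1):
            e = []
            for seed in range(40):
                spec = make_spectrum(offset=0.8, exponent=1.5,
                                     peaks=[(9.5, 0.6, 1.2)],
                                     noise_sd=noise, seed=seed)
                fit = parameterize_spectrum(spec)
                e.append(abs(fit.aperiodic.exponent - 1.5))
            errs.append(np.mean(e))
        assert errs == sorted(errs)


class TestPeriodicSpectrum:
    def test_pure_aperiodic_gives_zero(self, make_spectrum):
        spec = make_spectrum(offset=1.0, exponent=1.5)
        fit = parameterize_spectrum(spec)
        per = periodic_spectrum(spec, fit)
        assert np.max(np.abs(per.power)) < 0.02

    def test_reconstruction_identity(self, make_spectrum):
        # data = final aperiodic curve + periodic spectrum, exactly
        spec = make_spectrum(peaks=[(10.0, 0.7, 1.5)], noise_sd=0.03)
        fit = parameterize_spectrum(spec)
        per = periodic_spectrum(spec, fit)
        assert np.allclose(fit.aperiodic.curve(spec.freqs) + per.power,
                           spec.power, atol=1e-12)

    def test_peak_height_recovered_at_center(self, make_spectrum):
        spec = make_spectrum(offset=1.0, exponent=1.2,
                             peaks=[(10.0, 0.7, 1.5)])
        fit = parameterize_spectrum(spec)
        per = periodic_spectrum(spec, fit)
        at_center = per.power[np.argmin(np.abs(per.freqs - 10.0))]
        assert at_center == pytest.approx(0.7, abs=0.05)


class TestOracleEquivalence:
    def test_agrees_with_direct_joint_fit(self, make_spectrum):
        """Dual-route check: the iterative decomposition and a one-shot
        global fit of the full parametric model must agree on noiseless
        spectra."""
        rng = np.random.default_rng(123)
        for _ in range(15):
            truth = dict(offset=rng.uniform(0.2, 1.5),
                         exponent=rng.uniform(0.8, 2.2),
                         center=rng.uniform(8.0, 12.0),
                         height=rng.uniform(0.3, 0.9),
                         width=rng.uniform(0.8, 2.0))
            spec = make_spectrum(offset=truth["offset"],
                                 exponent=truth["exponent"],
                                 peaks=[(truth["center"], truth["height"],
                                         truth["width"])])
            fit = parameterize_spectrum(spec)
            o_off, o_exp, o_peaks = direct_joint_fit(spec, 1)
            assert fit.aperiodic.offset == pytest.approx(o_off, abs=0.05)
            assert fit.aperiodic.exponent == pytest.approx(o_exp, abs=0.05)
            alpha = max(fit.peaks, key=lambda p: p.height)
            assert alpha.center == pytest.approx(o_peaks[0][0], abs=0.25)
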