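"""Decay fitting: exact recovery, chi-squared calibration, model selection."""

import numpy as np
import pytest

from granuvisc.decay_fit import (
    DecayHistogram,
    LowSignalError,
    fit_decay,
    fit_image,
    mean_lifetime,
    select_components,
)
from granuvisc.flim_synth import OpticalConfig, make_phantom, render_tcspc

N_BINS = 256
DT = 50.0 / 256.0
EDGES = np.arange(N_BINS + 1) * DT
CENTERS = (np.arange(N_BINS) + 0.5) * DT


def exp_bin_counts(taus, amps):
    """Independent oracle: bin-integrated multi-exponential, unit bin width in
    'initial intensity' units (A = counts per bin at t = 0)."""
    taus, amps = np.atleast_1d(taus), np.atleast_1d(amps)
    out = np.zeros(N_BINS)
    for tau, amp in zip(taus, amps):
        out += amp * (tau / DT) * (np.exp(-EDGES[:-1] / tau) - np.exp(-EDGES[1:] / tau))
    return out


def poisson_hist(taus, amps, n_photons, rng):
    mu = exp_bin_counts(taus, amps)
    mu *= n_photons / mu.sum()
    return DecayHistogram(rng.poisson(mu).astype(float), CENTERS), mu


class TestFitDecay:
    def test_noiseless_single_exponential_is_exact(self):
        hist = DecayHistogram(exp_bin_counts(3.0, 1000.0), CENTERS)
        fit = fit_decay(hist, 1, irf_handling="none")
        assert fit.lifetimes[0] == pytest.approx(3.0, rel=1e-6)
        assert fit.chi2_red == pytest.approx(0.0, abs=1e-9)
        assert fit.amplitudes[0] == pytest.approx(1000.0, rel=1e-5)

    def test_scale_equivariance_noiseless(self):
        base = exp_bin_counts(2.4, 500.0)
        f1 = fit_decay(DecayHistogram(base, CENTERS), 1)
        f2 = fit_decay(DecayHistogram(base * 8.0, CENTERS), 1)
        assert f2.lifetimes[0] == pytest.approx(f1.lifetimes[0], rel=1e-6)
        assert f2.amplitudes[0] == pytest.approx(8.0 * f1.amplitudes[0], rel=1e-5)

    def test_two_component_recovery_and_oracle_ssr(self):
        rng = np.random.default_rng(0)
        hist, _ = poisson_hist([1.5, 4.0], [0.7e5, 0.3e5], 1e5 * 2.05, rng)
        fit = fit_decay(hist, 2, irf_handling="none")
        assert fit.lifetimes[0] == pytest.approx(1.5, abs=0.1)
        assert fit.lifetimes[1] == pytest.approx(4.0, abs=0.15)
        # dense-grid oracle under the fit's own final weights
        from granuvisc.decay_fit import _bases, _solve_amplitudes

        model = _bases(EDGES, fit.lifetimes, 0.0, 0.0) @ fit.amplitudes
        w = 1.0 / np.maximum(model, 0.5)
        _, fit_ssr = _solve_amplitudes(
            _bases(EDGES, fit.lifetimes, 0.0, 0.0), hist.counts, w
        )
        grid = np.geomspace(0.5, 7.0, 60)
        best = np.inf
        for i, t1 in enumerate(grid):
            for t2 in grid[i + 1 :]:
                _, ssr = _solve_amplitudes(
                    _bases(EDGES, np.array([t1, t2]), 0.0, 0.0), hist.counts, w
                )
                best = min(best, ssr)
        assert fit_ssr <= best * 1.01

    def test_chi2_calibrated_on_replicates(self):
        rng = np.random.default_rng(7)
        chis = [
            fit_decay(poisson_hist([1.5, 4.0], [0.7, 0.3], 1e4, rng)[0], 2).chi2_red
            for _ in range(40)
        ]
        assert 0.85 <= np.mean(chis) <= 1.15

    def test_gaussian_irf_model_matches_generator(self):
        optics = OpticalConfig()
        phantom, truth = make_phantom("nonCF", 1, frame=(24, 24), seed=1)
        img = render_tcspc(phantom, truth, optics=optics,
                           photons_per_granule_pixel=20000, seed=2)
        r, c = np.argwhere(truth.granule_label_map > 0)[0]
        hist = DecayHistogram(img.counts[:, r, c].astype(float), optics.bin_centers,
                              irf_fwhm=optics.irf_fwhm, irf_center=optics.irf_center)
        fit = fit_decay(hist, 1, irf_handling="gaussian")
        assert fit.lifetimes[0] == pytest.approx(truth.lifetime_map[r, c], rel=0.02)
        assert 0.7 <= fit.chi2_red <= 1.4

    def test_low_signal_raises(self):
        hist = DecayHistogram(np.zeros(N_BINS), CENTERS)
        with pytest.raises(LowSignalError):
            fit_decay(hist, 1)

    def test_estimator_consistency_sd_shrinks_with_photons(self):
        rng = np.random.default_rng(11)
        sds = []
        for n in (1e3, 1e4, 1e5):
            taus = [
                fit_decay(poisson_hist(3.0, 1.0, n, rng)[0], 1).lifetimes[0]
                for _ in range(25)
            ]
            assert np.mean(taus) == pytest.approx(3.0, abs=0.15)
            sds.append(np.std(taus))
        # SD should fall roughly like 1/sqrt(n): a decade in photons gives
        # about a 3.2x drop; allow a broad band at 25 replicates
        assert sds[0] / sds[1] == pytest.approx(np.sqrt(10), rel=0.6)
        assert sds[1] / sds[2] == pytest.approx(np.sqrt(10), rel=0.6)


class TestSelectComponents:
    def test_single_exponential_selects_one(self):
        rng = np.random.default_rng(1)
        hist, _ = poisson_hist(3.0, 1.0, 1e4, rng)
        assert select_components(hist, max_M=2).n_components == 1

    def test_two_component_data_selects_two(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            hist, _ = poisson_hist([1.5, 4.5], [0.6, 0.4], 1e5, rng)
            if select_components(hist, max_M=2).n_components == 2:
                hits += 1
        assert hits >= 18

    def test_misspecified_single_fit_inflates_chi2(self):
        rng = np.random.default_rng(3)
        hist, _ = poisson_hist([1.5, 4.5], [0.5, 0.5], 1e5, rng)
        forced = fit_decay(hist, 1)
        selected = select_components(hist, max_M=2)
        assert forced.chi2_red > 3.0 * selected.chi2_red

    def test_flagged_when_no_m_suffices(self):
        rng = np.random.default_rng(4)
        # three well-separated components but max_M=1: nothing fits
        hist, _ = poisson_hist([0.8, 3.0, 7.0], [0.4, 0.4, 0.2], 1e6, rng)
        fit = select_components(hist, max_M=1)
        assert fit.flagged


class TestMeanLifetime:
    def test_single_component_any_weighting(self):
        hist = DecayHistogram(exp_bin_counts(3.0, 500.0), CENTERS)
        fit = fit_decay(hist, 1)
        assert mean_lifetime(fit, "amplitude") == pytest.approx(3.0, rel=1e-5)
        assert mean_lifetime(fit, "intensity") == pytest.approx(3.0, rel=1e-5)

    def test_hand_computed_weightings(self):
        from granuvisc.decay_fit import DecayFit

        fit = DecayFit(
            amplitudes=np.array([1.0, 1.0]),
            lifetimes=np.array([2.0, 4.0]),
            n_components=2,
            chi2_red=1.0,
            mean_lifetime=3.0,
        )
        assert mean_lifetime(fit, "amplitude") == pytest.approx(3.0)
        assert mean_lifetime(fit, "intensity") == pytest.approx(20.0 / 6.0)

    def test_all_zero_amplitudes_undefined(self):
        from granuvisc.decay_fit import DecayFit

        fit = DecayFit(
            amplitudes=np.zeros(1),
            lifetimes=np.array([3.0]),
            n_components=1,
            chi2_red=1.0,
            mean_lifetime=np.nan,
        )
        with pytest.raises(ValueError):
            mean_lifetime(fit)


class TestFitImage:
    def test_all_background_image_has_no_defined_pixels(self):
        optics = OpticalConfig()
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.05, size=(optics.n_time_bins, 16, 16)).astype(np.int32)
        from granuvisc.flim_synth import TCSPCImage

        img = TCSPCImage(counts=counts, optics=optics)
        li = fit_image(img)
        assert li.defined_mask.sum() == 0
        assert li.n_skipped == 256

    def test_single_granule_lifetime_recovered(self):
        curve_tau = 3.5
        # build a phantom whose granule maps exactly to 3.5 ns
        from granuvisc.rotor_calibration import default_calibration

        curve = default_calibration()
        eta = curve.viscosity(curve_tau)
        phantom, truth = make_phantom(
            [(eta, 1e-6, 1.0)], 1, frame=(24, 24), seed=1
        )
        img = render_tcspc(phantom, truth, photons_per_granule_pixel=1000, seed=2)
        li = fit_image(img)
        vals = li.mean_lifetime[li.defined_mask]
        assert np.median(vals) == pytest.approx(3.5, abs=0.1)

    def test_binning_reduces_lifetime_scatter(self):
        phantom, truth = make_phantom("nonCF", 1, frame=(24, 24), seed=3)
        img = render_tcspc(phantom, truth, photons_per_granule_pixel=300, seed=4)
        li0 = fit_image(img, binning=0)
        li1 = fit_image(img, binning=1)
        core = truth.granule_label_map > 0
        sd0 = np.nanstd(np.where(li0.defined_mask & core, li0.mean_lifetime, np.nan))
        sd1 = np.nanstd(np.where(li1.defined_mask & core, li1.mean_lifetime, np.nan))
        assert sd1 <= sd0

    def test_min_counts_floor_enforced(self, small_scene):
        _, _, img = small_scene
        with pytest.raises(ValueError):
            fit_image(img, min_counts=10)
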