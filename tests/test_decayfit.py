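"""Decay aggregation and Poisson-MLE fitting tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimcell import (
    AcquisitionConfig,
    DecayCurve,
    DecaySpec,
    FitOptions,
    aggregate_roi_decay,
    chi2_reduced,
    compute_tau_m,
    fit_biexp,
    fit_mono,
    make_irf,
    simulate_decay_histogram,
)
from flimcell.core import FLIMStack, LabelMask
from flimcell.decayfit import _poisson_nll
from flimcell.errors import (
    DegenerateFitError,
    InsufficientSignalError,
    UndefinedMeanError,
    UnknownROIError,
)
from flimcell.model import decay_shape


class TestAggregateROI:
    def _stack_from_histograms(self, cfg, pixel_hist):
        data = np.broadcast_to(pixel_hist, (2, 3, cfg.n_bins)).copy()
        return FLIMStack(data=data, config=cfg)

    def test_two_identical_pixels_double_the_histogram(self, cfg, rng):
        hist = rng.poisson(50.0, cfg.n_bins)
        stack = self._stack_from_histograms(cfg, hist)
        labels = np.zeros((2, 3), int)
        labels[0, 0] = labels[0, 1] = 4
        curve = aggregate_roi_decay(stack, LabelMask(labels), (4, "cytoplasm"))
        np.testing.assert_array_equal(curve.counts, 2 * hist)

    def test_union_of_disjoint_rois_is_binwise_sum(self, cfg, rng):
        data = rng.poisson(20.0, (4, 4, cfg.n_bins))
        stack = FLIMStack(data=data, config=cfg)
        labels = np.zeros((4, 4), int)
        labels[:2] = 1
        labels[2:] = 2
        c1 = aggregate_roi_decay(stack, LabelMask(labels), (1, "cytoplasm"))
        c2 = aggregate_roi_decay(stack, LabelMask(labels), (2, "cytoplasm"))
        union = LabelMask(np.where(labels > 0, 9, 0))
        cu = aggregate_roi_decay(stack, union, (9, "cytoplasm"))
        np.testing.assert_array_equal(cu.counts, c1.counts + c2.counts)

    def test_unknown_label_raises(self, cfg):
        stack = FLIMStack(np.zeros((2, 2, cfg.n_bins)), cfg)
        with pytest.raises(UnknownROIError):
            aggregate_roi_decay(stack, LabelMask(np.zeros((2, 2), int)), (3, "cytoplasm"))

    def test_phantom_budget_matches_manifest(self, nadh_spec):
        cfg = AcquisitionConfig(seed=21, dark_count_fraction=0.0)
        from flimcell import render_phantom_scene

        scene = render_phantom_scene(
            2, cfg, {"cytoplasm": nadh_spec, "nucleus": nadh_spec},
            shape=(128, 128), sample=False,
        )
        from flimcell import split_nucleus_cytoplasm

        split = split_nucleus_cytoplasm(scene.cell_mask, scene.nucleus_mask)
        for lab in scene.cell_mask.object_labels:
            curve = aggregate_roi_decay(
                scene.stacks["main"], split.cytoplasm, (int(lab), "cytoplasm")
            )
            assert curve.total_photons == pytest.approx(
                scene.compartment_budget(int(lab), "cytoplasm"), rel=1e-9
            )


class TestFitMono:
    def test_noiseless_roundtrip(self, cfg_nodark):
        irf = make_irf(cfg_nodark)
        curve = simulate_decay_histogram(
            DecaySpec((1.0,), (1.0,)), cfg_nodark, 1e5, sample=False
        )
        fit = fit_mono(curve, irf, FitOptions(fit_background=False))
        assert fit.tau == pytest.approx(1.0, abs=1e-6)
        assert fit.converged

    def test_median_recovery_under_poisson_noise(self, cfg, irf):
        """DOX-like 1.0 ns decays at 1e5 photons: the median fitted
        lifetime lands within 2% of truth over 200 replicates."""
        rng = np.random.default_rng(8)
        spec = DecaySpec((1.0,), (1.0,))
        taus = []
        for _ in range(50):
            curve = simulate_decay_histogram(spec, cfg, 1e5, rng=rng)
            taus.append(fit_mono(curve, irf).tau)
        assert np.median(taus) == pytest.approx(1.0, rel=0.02)

    def test_insufficient_signal_rejected(self, cfg, irf):
        curve = simulate_decay_histogram(DecaySpec((1.0,), (1.0,)), cfg, 100)
        with pytest.raises(InsufficientSignalError):
            fit_mono(curve, irf)

    def test_grid_search_oracle_agreement(self, cfg_nodark):
        """Brute-force likelihood scan over tau agrees with the optimizer."""
        irf = make_irf(cfg_nodark)
        rng = np.random.default_rng(13)
        opts = FitOptions(fit_background=False, min_photons_mono=100)
        for _ in range(3):
            tau_true = rng.uniform(0.3, 3.0)
            curve = simulate_decay_histogram(
                DecaySpec((tau_true,), (1.0,)), cfg_nodark, 5000, rng=rng
            )
            counts = curve.counts.astype(float)
            total = counts.sum()
            fit = fit_mono(curve, irf, opts)
            grid = np.arange(0.1, 5.0, 0.001)
            nlls = [
                _poisson_nll(counts, total * decay_shape((t,), (1.0,), irf, cfg_nodark))
                for t in grid
            ]
            best = grid[int(np.argmin(nlls))]
            assert abs(fit.tau - best) <= 0.001

    def test_tail_fit_mode_recovers_lifetime(self, cfg, irf):
        rng = np.random.default_rng(3)
        curve = simulate_decay_histogram(DecaySpec((1.5,), (1.0,)), cfg, 2e5, rng=rng)
        fit = fit_mono(curve, irf, FitOptions(tail_fit=True))
        assert fit.tau == pytest.approx(1.5, rel=0.05)


class TestFitBiexp:
    def test_noiseless_roundtrip_at_nadh_baseline(self, cfg_nodark, nadh_spec):
        irf = make_irf(cfg_nodark)
        curve = simulate_decay_histogram(nadh_spec, cfg_nodark, 1e6, sample=False)
        fit = fit_biexp(curve, irf, FitOptions(fit_background=False))
        assert fit.tau1 == pytest.approx(0.38, abs=1e-4)
        assert fit.tau2 == pytest.approx(2.7, abs=1e-4)
        assert fit.a1 == pytest.approx(77.0, abs=1e-4)
        assert fit.converged

    def test_degenerate_single_component_input(self, cfg, irf):
        rng = np.random.default_rng(4)
        curve = simulate_decay_histogram(
            DecaySpec((0.38, 2.7), (1.0, 0.0)), cfg, 1e5, rng=rng
        )
        fit = fit_biexp(curve, irf)
        assert ("identifiability" in fit.flags) or fit.a2 < 2.0
        assert fit.tau_m == pytest.approx(fit.tau1, rel=0.1)

    def test_components_always_ordered(self, cfg, irf, nadh_spec):
        rng = np.random.default_rng(6)
        for _ in range(5):
            curve = simulate_decay_histogram(nadh_spec, cfg, 2e4, rng=rng)
            fit = fit_biexp(curve, irf)
            assert fit.tau1 < fit.tau2
            assert fit.a1 + fit.a2 == 100.0
            assert fit.tau1 <= fit.tau_m <= fit.tau2

    def test_coarse_grid_oracle_on_downsampled_curve(self, nadh_spec):
        """On a 64-bin rebinned curve, the optimizer's likelihood beats the
        best point of a 3-parameter grid."""
        cfg64 = AcquisitionConfig(seed=2, n_bins=64, dark_count_fraction=0.0)
        irf64 = make_irf(cfg64)
        rng = np.random.default_rng(17)
        curve = simulate_decay_histogram(nadh_spec, cfg64, 5e4, rng=rng)
        counts = curve.counts.astype(float)
        total = counts.sum()
        fit = fit_biexp(curve, irf64, FitOptions(fit_background=False))
        fit_nll = _poisson_nll(
            counts,
            total * (fit.amplitude / total)
            * decay_shape((fit.tau1, fit.tau2), (fit.a1 / 100, fit.a2 / 100), irf64, cfg64),
        )
        best = np.inf
        for t1 in np.arange(0.2, 0.62, 0.05):
            for t2 in np.arange(2.0, 3.45, 0.2):
                for p in np.arange(0.5, 0.96, 0.05):
                    nll = _poisson_nll(
                        counts,
                        total * decay_shape((t1, t2), (p, 1 - p), irf64, cfg64),
                    )
                    best = min(best, nll)
        assert fit_nll <= best + 1e-6

    def test_recovery_precision_improves_with_photons(self, cfg, irf, nadh_spec):
        def tau1_sd(photons, n=25):
            rng = np.random.default_rng(99)
            vals = [
                fit_biexp(
                    simulate_decay_histogram(nadh_spec, cfg, photons, rng=rng), irf
                ).tau1
                for _ in range(n)
            ]
            return np.std(vals)

        assert tau1_sd(1e6) < tau1_sd(1e5)


class TestTauM:
    @pytest.mark.parametrize(
        "tau1, tau2, a1, a2, expected",
        [
            (0.5, 2.0, 100.0, 0.0, 0.5),
            (1.0, 3.0, 50.0, 50.0, 2.0),
            (0.38, 2.7, 77.0, 23.0, 0.9136),
        ],
    )
    def test_known_values(self, tau1, tau2, a1, a2, expected):
        assert compute_tau_m(tau1, tau2, a1, a2) == pytest.approx(expected, abs=1e-12)

    def test_zero_amplitudes_undefined(self):
        with pytest.raises(UndefinedMeanError):
            compute_tau_m(0.5, 2.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        tau1=st.floats(0.1, 1.0),
        gap=st.floats(0.5, 4.0),
        a1=st.floats(1.0, 98.0),
        step=st.floats(0.1, 1.0),
    )
    def test_monotone_decreasing_in_free_fraction(self, tau1, gap, a1, step):
        """A larger free-NAD(P)H fraction always lowers the mean lifetime."""
        tau2 = tau1 + gap
        lo = compute_tau_m(tau1, tau2, a1, 100.0 - a1)
        hi = compute_tau_m(tau1, tau2, min(a1 + step, 99.9), 100.0 - min(a1 + step, 99.9))
        assert hi < lo


class TestChi2:
    def test_exact_model_gives_zero(self, cfg):
        model = np.full(cfg.n_bins, 25.0)
        assert chi2_reduced(model.copy(), model, n_params=1) == 0.0

    def test_low_expectation_bins_excluded(self, cfg):
        model = np.full(cfg.n_bins, 0.5)
        model[:10] = 100.0
        counts = model.copy()
        value, n_exc, dof = chi2_reduced(counts, model, 2, return_detail=True)
        assert n_exc == cfg.n_bins - 10
        assert dof == 8

    def test_all_bins_excluded_is_degenerate(self, cfg):
        tiny = np.full(cfg.n_bins, 0.01)
        with pytest.raises(DegenerateFitError):
            chi2_reduced(tiny.copy(), tiny, 2)

    def test_calibration_on_correctly_specified_fits(self, cfg, irf):
        """Pearson reduced chi-square averages 1 when the model is right."""
        rng = np.random.default_rng(10)
        spec = DecaySpec((1.0,), (1.0,))
        chis = [
            fit_mono(simulate_decay_histogram(spec, cfg, 1e5, rng=rng), irf).chi2_reduced
            for _ in range(60)
        ]
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_discriminates_misspecified_mono_fit(self, cfg, irf, nadh_spec):
        rng = np.random.default_rng(11)
        chis = [
            fit_mono(
                simulate_decay_histogram(nadh_spec, cfg, 1e5, rng=rng), irf
            ).chi2_reduced
            for _ in range(10)
        ]
        assert min(chis) > 1.2
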