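import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qnmrfit import (
    AdjustmentSettings,
    DistortionSpec,
    SignatureModel,
    adjust_intensities,
    adjust_phase,
    allocation_weights,
    decompose_residual,
    denoise_residual,
    median_smooth,
    run_adjustment,
    simulate_sample,
)
from tests.conftest import make_peak_signature


def naive_sliding_median(v, w):
    """Brute-force O(n·w) oracle with the same reflect-padded edges."""
    half = w // 2
    padded = np.concatenate([v[half:0:-1], v, v[-2 : -half - 2 : -1]])
    return np.array([np.median(padded[i : i + w]) for i in range(v.size)])


class TestDenoise:
    def test_zero_input_zero_output(self):
        assert np.array_equal(denoise_residual(np.zeros(1024)), np.zeros(1024))

    def test_removes_white_noise_energy(self):
        """Monte-Carlo: ≥ 90 % of pure-noise energy removed (20 seeds, n = 4096)."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(4096)
            d = denoise_residual(x)
            ratios.append(float(d @ d) / float(x @ x))
        assert np.mean(ratios) <= 0.10

    def test_preserves_tall_spike(self):
        """A 100σ spike survives soft thresholding within 20 %."""
        rng = np.random.default_rng(3)
        sigma = 1.0
        x = rng.standard_normal(4096) * sigma
        x[2048] += 100.0 * sigma
        d = denoise_residual(x)
        assert d[2048] == pytest.approx(100.0, rel=0.2)

    def test_unknown_wavelet_listed(self):
        with pytest.raises(ValueError, match="supported"):
            denoise_residual(np.zeros(256), wavelet="nosuch9")

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="2\\^levels"):
            denoise_residual(np.zeros(16), levels=6)


class TestMedianSmooth:
    def test_constant_unchanged(self):
        v = np.full(500, 3.7)
        assert np.array_equal(median_smooth(v, 31), v)

    @pytest.mark.parametrize("w", [3, 7, 15, 51])
    def test_matches_naive_oracle_exactly(self, w, rng):
        v = rng.standard_normal(300)
        assert np.array_equal(median_smooth(v, w), naive_sliding_median(v, w))

    def test_narrow_spike_removed_exactly(self):
        """Root-signal property: a spike narrower than w/2 vanishes to baseline."""
        v = np.zeros(400)
        v[200:205] = 9.0  # 5-point rectangle, window 21
        out = median_smooth(v, 21)
        assert np.array_equal(out, np.zeros(400))

    def test_even_width_coerced_up(self, rng):
        v = rng.standard_normal(100)
        assert np.array_equal(median_smooth(v, 10), median_smooth(v, 11))

    def test_width_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            median_smooth(np.zeros(50), 51)

    def test_multistage_equals_sequential_passes(self, rng):
        v = rng.standard_normal(400)
        assert np.array_equal(
            median_smooth(v, [5, 11]), median_smooth(median_smooth(v, 5), 11)
        )


class TestDecomposition:
    def test_zero_residual_all_zero(self):
        d = decompose_residual(np.zeros(1024), filter_widths=(31,))
        assert np.all(d.misfit == 0) and np.all(d.baseline == 0) and np.all(d.noise == 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_exact_reconstruction(self, seed):
        """r_m + r_b + r_n = r to machine precision for arbitrary input."""
        r = np.random.default_rng(seed).standard_normal(2048)
        d = decompose_residual(r, filter_widths=(21, 51))
        np.testing.assert_allclose(d.misfit + d.baseline + d.noise, r, atol=1e-12)

    def test_misphased_peak_baseline_has_sharp_transition(self, misphased_peak):
        """Median filtering of the misphased-fit residual creates a sharp
        sign transition in r_b at the peak position."""
        _, sig, spec = misphased_peak
        res = SignatureModel(spec, [sig], baseline_order=0).fit()
        d = decompose_residual(res.residual, filter_widths=(161,))
        i0 = int(np.argmax(res.fitted))
        rb = d.baseline
        window = rb[i0 - 400 : i0 + 400]
        # opposite-sign plateaus on the two sides, jump comparable to the range
        jump = np.max(np.abs(np.diff(window)))
        assert np.sign(np.median(window[:300])) != np.sign(np.median(window[-300:]))
        assert jump > 0.2 * np.ptp(rb)


class TestAllocationWeights:
    def test_single_component_all_ones(self, rng):
        Z = np.abs(rng.standard_normal((50, 1)))
        W = allocation_weights(Z, np.array([2.0]))
        assert np.array_equal(W, np.ones((50, 1)))

    def test_rows_sum_to_one(self, rng):
        Z = np.abs(rng.standard_normal((200, 3)))
        W = allocation_weights(Z, np.array([1.0, 2.0, 0.5]))
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(W >= 0)

    def test_equal_model_values_split_evenly(self):
        Z = np.ones((4, 2))
        W = allocation_weights(Z, np.array([1.0, 1.0]))
        np.testing.assert_allclose(W, 0.5)

    def test_negative_products_clipped(self):
        Z = np.array([[1.0, 1.0], [1.0, 1.0]])
        W = allocation_weights(Z, np.array([1.0, -1.0]))
        np.testing.assert_allclose(W[:, 0], 1.0)
        np.testing.assert_allclose(W[:, 1], 0.0)

    def test_all_zero_rows_fall_back_uniform(self):
        Z = np.zeros((3, 2))
        Z[0] = [1.0, 3.0]
        W = allocation_weights(Z, np.array([1.0, 1.0]))
        np.testing.assert_allclose(W[1:], 0.5)


class TestAdjustIntensities:
    @pytest.fixture
    def fitted(self, misphased_peak):
        _, sig, spec = misphased_peak
        return SignatureModel(spec, [sig], baseline_order=0).fit()

    def test_zero_misfit_preserves_intensities(self, fitted):
        d = decompose_residual(np.zeros(fitted.data.size), filter_widths=(21,))
        W = allocation_weights(fitted.model_matrix.signature_columns,
                               fitted.signature_intensities)
        c = adjust_intensities(fitted, d, W)
        np.testing.assert_array_equal(c, fitted.signature_intensities)

    def test_single_component_closed_form(self, fitted):
        d = decompose_residual(fitted.residual, filter_widths=(161,))
        W = np.ones((fitted.data.size, 1))
        c = adjust_intensities(fitted, d, W)
        Z1 = fitted.model_matrix.signature_columns[:, 0]
        expected = fitted.signature_intensities[0] + d.misfit.sum() / Z1.sum()
        assert c[0] == pytest.approx(expected, rel=1e-12)

    def test_conservation_identity_random(self, params, rng):
        """Σ_k c̃_k·Σ_iẐ_ik = Σ_k ĉ_k·Σ_iẐ_ik + Σ_i r_m,i on random inputs."""
        sigs = [
            make_peak_signature(params, 10.0, 1.0, "a"),
            make_peak_signature(params, 14.0, 3.0, "b"),
        ]
        _, spec = simulate_sample(
            [(sigs[0], 0.4), (sigs[1], 0.6)],
            DistortionSpec(gaussian_broadening=2.0, snr=200.0, seed=11),
            params,
        )
        fit = SignatureModel(spec, sigs, baseline_order=0).fit()
        d = decompose_residual(fit.residual, filter_widths=(81,))
        W = allocation_weights(fit.model_matrix.signature_columns,
                               fit.signature_intensities)
        c = adjust_intensities(fit, d, W)
        col = fit.model_matrix.signature_columns.sum(axis=0)
        lhs = float(c @ col)
        rhs = float(fit.signature_intensities @ col) + float(d.misfit.sum())
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestAdjustPhase:
    def test_recovers_injected_phase(self, misphased_peak):
        """0.25 rad zero-order error recovered within 0.02 rad (noiseless)."""
        _, sig, spec = misphased_peak
        fit = SignatureModel(spec, [sig], baseline_order=0).fit()
        adj, diag = adjust_phase(
            fit, AdjustmentSettings(schedule_fwhm=(16.0,), optimize_phi1=False)
        )
        assert adj.params.phi0 == pytest.approx(0.25, abs=0.02)
        stage = diag["stages"][0]
        assert stage["rb_norm2_after"] <= stage["rb_norm2_before"]

    def test_fixed_point_when_already_optimal(self, misphased_peak):
        _, sig, spec = misphased_peak
        fit = SignatureModel(spec, [sig], baseline_order=0).fit()
        settings = AdjustmentSettings(schedule_fwhm=(16.0,), optimize_phi1=False)
        adj, _ = adjust_phase(fit, settings)
        again, _ = adjust_phase(adj, settings)
        assert abs(again.params.phi0 - adj.params.phi0) < 1e-3

    def test_reduces_to_least_squares_without_smoothing(self, misphased_peak):
        """wm → 0 and denoising off: argmin ‖r_b‖² = argmin ‖r‖² over phase."""
        from scipy.optimize import minimize_scalar

        _, sig, spec = misphased_peak
        fit = SignatureModel(spec, [sig], baseline_order=0).fit()
        adj, _ = adjust_phase(
            fit,
            AdjustmentSettings(schedule_fwhm=(0.0,), denoise=False, optimize_phi1=False),
        )
        Z = fit.model_matrix.values

        def ls_obj(p):
            y = spec.real_at_phase(p, 0.0)
            c = np.linalg.lstsq(Z, y, rcond=None)[0]
            r = y - Z @ c
            return float(r @ r)

        opt = minimize_scalar(ls_obj, bounds=(-0.1, 0.5), method="bounded",
                              options={"xatol": 1e-10})
        assert adj.params.phi0 == pytest.approx(opt.x, abs=1e-3)

    def test_rb_norm_falls_while_residual_may_rise(self, misphased_peak):
        _, sig, spec = misphased_peak
        fit = SignatureModel(spec, [sig], baseline_order=0).fit()
        settings = AdjustmentSettings(schedule_fwhm=(16.0,), optimize_phi1=False)
        from qnmrfit.adjustment import _rb_norm2

        fwhm = fit.mean_fwhm_points()
        w = int(np.ceil(16 * fwhm)) | 1
        before = _rb_norm2(fit, fit.params.phi0, fit.params.phi1, settings, (w,))
        adj, _ = adjust_phase(fit, settings)
        after = _rb_norm2(fit, adj.params.phi0, adj.params.phi1, settings, (w,))
        assert after < before


class TestRunAdjustment:
    def test_perfect_model_is_identity(self, single_peak):
        """Perfectly modelled noiseless data: c̃ = ĉ = truth, phase unchanged."""
        _, sig, spec = single_peak
        fit = SignatureModel(spec, [sig], baseline_order=0).fit()
        adj = run_adjustment(
            fit, AdjustmentSettings(schedule_fwhm=(10.0,), final_fwhm=100.0)
        )
        assert adj.phase[0] == pytest.approx(0.0, abs=5e-3)
        assert adj.intensities[0] == pytest.approx(1.0, rel=1e-4)
        assert adj.intensities_ls[0] == pytest.approx(1.0, rel=1e-4)

    def test_misspecified_mixture_improves(self, params_large):
        """Gaussian-broadened two-species mixture: adjusted intensities closer
        to truth than plain least squares."""
        sigs = [
            make_peak_signature(params_large, 20.0, 1.0, "a"),
            make_peak_signature(params_large, 40.0, 3.0, "b", protons=1),
        ]
        truth = np.array([0.35, 0.65])
        _, spec = simulate_sample(
            [(sigs[0], truth[0]), (sigs[1], truth[1])],
            DistortionSpec(
                gaussian_broadening=0.5 * sigs[0].mean_fwhm_hz(),
                phase_error=(0.05, 0.0),
                snr=500.0,
                seed=5,
            ),
            params_large,
        )
        fit = SignatureModel(spec, sigs, baseline_order=1).fit()
        adj = run_adjustment(
            fit, AdjustmentSettings(schedule_fwhm=(10.0, 100.0), final_fwhm=400.0)
        )
        x_ls = fit.mole_fractions()
        x_adj = adj.mole_fractions()
        assert np.abs(x_adj - truth).max() < np.abs(x_ls - truth).max()

    def test_final_baseline_within_noise_level(self, params_large):
        """After adjustment the residual baseline stays within a small multiple
        of the noise floor."""
        sig = make_peak_signature(params_large)
        _, spec = simulate_sample(
            [(sig, 1.0)],
            DistortionSpec(phase_error=(0.1, 0.0), snr=200.0, seed=9),
            params_large,
        )
        noise_sigma = np.max(np.abs(spec.real_values)) / 200.0
        fit = SignatureModel(spec, [sig], baseline_order=1).fit()
        adj = run_adjustment(
            fit, AdjustmentSettings(schedule_fwhm=(10.0, 100.0), final_fwhm=400.0)
        )
        assert np.ptp(adj.decomposition.baseline) < 4.0 * noise_sigma

    def test_weights_row_stochastic_in_pipeline(self, params):
        sigs = [
            make_peak_signature(params, 8.0, 1.0, "a"),
            make_peak_signature(params, 8.0, 3.0, "b"),
        ]
        _, spec = simulate_sample(
            [(sigs[0], 0.5), (sigs[1], 0.5)],
            DistortionSpec(gaussian_broadening=1.0, snr=300.0, seed=2),
            params,
        )
        fit = SignatureModel(spec, sigs, baseline_order=1).fit()
        adj = run_adjustment(
            fit, AdjustmentSettings(schedule_fwhm=(10.0,), final_fwhm=100.0)
        )
        np.testing.assert_allclose(adj.weights.sum(axis=1), 1.0, atol=1e-12)
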