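import numpy as np
import pytest

from qnmrfit import (
    DistortionSpec,
    FitParams,
    Peak,
    Signature,
    SignatureModel,
    build_model_matrix,
    simulate_sample,
    solve_intensities,
    varpro_objective,
)
from qnmrfit.model import RankDeficientWarning
from tests.conftest import make_peak_signature


class TestSolveIntensities:
    def test_recovers_consistent_system(self, rng):
        Z = rng.standard_normal((200, 5))
        c0 = rng.standard_normal(5)
        c, flag = solve_intensities(Z, Z @ c0)
        assert not flag
        assert np.allclose(c, c0, rtol=1e-9)

    def test_orthogonal_data_gives_zero(self):
        Z = np.zeros((10, 2))
        Z[:5, 0] = 1.0
        Z[5:, 1] = 1.0
        y = np.array([1.0, -1.0] * 5)
        y[::2] *= [1, 1, 1, 1, -1]  # make y orthogonal to both columns
        y = np.array([1, -1, 1, -1, 0, 1, -1, 1, -1, 0], float)
        c, _ = solve_intensities(Z, y)
        assert np.allclose(c, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        Z = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        c, _ = solve_intensities(Z, y)
        oracle = np.linalg.solve(Z.T @ Z, Z.T @ y)  # dense normal equations
        assert np.allclose(c, oracle, atol=1e-8, rtol=1e-8)

    def test_rank_deficient_warns_minimum_norm(self, rng):
        base = rng.standard_normal(30)
        Z = np.column_stack([base, base])  # exactly collinear
        y = rng.standard_normal(30)
        with pytest.warns(RankDeficientWarning):
            c, flag = solve_intensities(Z, y)
        assert flag
        assert c[0] == pytest.approx(c[1])  # minimum-norm splits evenly

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError, match="underdetermined"):
            solve_intensities(rng.standard_normal((3, 5)), np.zeros(3))


class TestVarproObjective:
    def test_zero_in_column_space(self, params_large):
        """Projector kernel: y built exactly from Z gives a vanishing objective."""
        from qnmrfit.spectra import Spectrum

        sig = make_peak_signature(params_large)
        Z = build_model_matrix([sig], 1, params_large.frequency_grid(), params_large)
        y = Z.values @ np.array([2.5, 1e-12])
        spec = Spectrum(params_large.frequency_grid(), y, y.astype(complex),
                        (0.0, 0.0), params_large)
        obj = varpro_objective(FitParams.zero(1), spec, [sig], baseline_order=1)
        assert obj <= 1e-12 * float(y @ y)

    def test_equals_explicit_fit_residual(self, misphased_peak):
        p, sig, spec = misphased_peak
        theta = FitParams(np.array([0.001]), np.array([1.1]))
        obj = varpro_objective(theta, spec, [sig], baseline_order=1)
        Z = build_model_matrix([sig], 1, spec.frequency, p,
                               theta.shift_offsets, theta.width_scales)
        y = spec.real_at_phase(0.0, 0.0)
        c, _ = solve_intensities(Z, y)
        r = y - Z.values @ c
        assert obj == pytest.approx(float(r @ r), rel=1e-12)

    def test_invariant_to_signature_rescaling(self, misphased_peak):
        """A global rescale of b_p is absorbed by the linear solve."""
        p, sig, spec = misphased_peak
        scaled = Signature(
            "peak",
            tuple(Peak(q.chemical_shift, q.decay_rate, 7.3 * q.relative_intensity)
                  for q in sig.peaks),
            1,
        )
        theta = FitParams.zero(1)
        a = varpro_objective(theta, spec, [sig], 0)
        b = varpro_objective(theta, spec, [scaled], 0)
        assert a == pytest.approx(b, rel=1e-9)


class TestFitModel:
    def test_zero_noise_recovery(self, params_large):
        """Data generated exactly from the model: θ̂ = θ*, near-zero objective."""
        sigs = [
            make_peak_signature(params_large, 24.0, 1.0, "a"),
            make_peak_signature(params_large, 30.0, 3.0, "b"),
        ]
        truth = FitParams(np.array([0.004, -0.003]), np.array([1.15, 0.9]))
        Z = build_model_matrix(sigs, 0, params_large.frequency_grid(), params_large,
                               truth.shift_offsets, truth.width_scales)
        c0 = np.array([2.0, 1.0])
        y = Z.values @ c0
        from qnmrfit.spectra import Spectrum

        spec = Spectrum(params_large.frequency_grid(), y, y.astype(complex),
                        (0.0, 0.0), params_large)
        res = SignatureModel(spec, sigs, baseline_order=0).fit(ftol=1e-14, gtol=1e-14)
        assert np.allclose(res.params.shift_offsets, truth.shift_offsets, atol=1e-6)
        assert np.allclose(res.params.width_scales, truth.width_scales, atol=1e-5)
        assert np.allclose(res.signature_intensities, c0, rtol=1e-6)
        assert res.objective <= 1e-16 * float(y @ y)

    def test_misphased_peak_bias_and_antisymmetric_tails(self, misphased_peak):
        """A 0.25 rad phase error left in the data biases the fitted position
        and leaves antisymmetric residual tails around the peak."""
        p, sig, spec = misphased_peak
        res = SignatureModel(spec, [sig], baseline_order=0).fit()
        assert res.params.shift_offsets[0] != pytest.approx(0.0, abs=1e-5)
        assert res.objective > 1e-6 * float(res.data @ res.data)
        i0 = int(np.argmax(res.fitted))
        k = 200
        left = res.residual[i0 - k : i0]
        right = res.residual[i0 + 1 : i0 + k + 1][::-1]
        # tails are predominantly antisymmetric: r(-δ) ≈ -r(+δ)
        corr = float(left @ right) / (np.linalg.norm(left) * np.linalg.norm(right))
        assert corr < -0.7

    def test_basin_stability_from_perturbed_starts(self, params_large):
        """Two perturbed starts on a well-separated 2-species spectrum agree."""
        sigs = [
            make_peak_signature(params_large, 24.0, 1.0, "a"),
            make_peak_signature(params_large, 24.0, 3.0, "b"),
        ]
        _, spec = simulate_sample(
            [(sigs[0], 0.3), (sigs[1], 0.7)],
            DistortionSpec(gaussian_broadening=0.3 * sigs[0].mean_fwhm_hz(),
                           snr=1000.0, seed=7),
            params_large,
        )
        model = SignatureModel(spec, sigs, baseline_order=1)
        r1 = model.fit(start=FitParams(np.array([0.002, -0.002]), np.array([1.2, 0.85])))
        r2 = model.fit(start=FitParams(np.array([-0.002, 0.002]), np.array([0.9, 1.2])))
        assert np.allclose(r1.params.shift_offsets, r2.params.shift_offsets, atol=1e-4)
        assert np.allclose(r1.params.width_scales, r2.params.width_scales, atol=1e-3)

    def test_gradient_vanishes_at_optimum(self, misphased_peak):
        p, sig, spec = misphased_peak
        model = SignatureModel(spec, [sig], baseline_order=0)
        res = model.fit()
        f0 = res.objective
        scale = float(res.data @ res.data)
        fwhm_ppm = sig.mean_fwhm_hz() / p.spectrometer_frequency
        for dp in (
            FitParams(res.params.shift_offsets + 1e-6 * fwhm_ppm, res.params.width_scales),
            FitParams(res.params.shift_offsets, res.params.width_scales * (1 + 1e-6)),
        ):
            # central-difference slope must be tiny relative to the data scale
            assert abs(model.objective(dp) - f0) < 1e-8 * scale

    def test_monotone_improvement(self, misphased_peak):
        p, sig, spec = misphased_peak
        model = SignatureModel(spec, [sig], baseline_order=0)
        start = FitParams(np.array([0.01]), np.array([1.5]))
        res = model.fit(start=start)
        assert res.objective <= model.objective(start)

    def test_deterministic(self, misphased_peak):
        _, sig, spec = misphased_peak
        model = SignatureModel(spec, [sig], baseline_order=1)
        a, b = model.fit(), model.fit()
        assert a.objective == b.objective
        assert np.array_equal(a.intensities, b.intensities)

    def test_summary_mentions_species_and_phase(self, misphased_peak):
        _, sig, spec = misphased_peak
        res = SignatureModel(spec, [sig]).fit()
        text = res.summary()
        assert "peak" in text and "phi0" in text and "objective" in text
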