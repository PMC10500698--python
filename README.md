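# qnmrfit

Model-based quantitative NMR (qNMR) with residual-driven phase and intensity
adjustment.

## The problem

Quantitative ¹H NMR estimates the mole fractions of known species in a
mixture from the intensities of their spectral responses.  Model-based
methods fit a parametric model — each species a fixed-ratio sum of
Lorentzian lines — and read concentrations off the fitted intensities.  They
resolve overlapping peaks that defeat classical peak integration, but they
are brittle: real peaks deviate from ideal Lorentzians (field inhomogeneity,
higher-order J-coupling, non-exponential decay, residual phase error), the
least-squares fit cannot absorb the deviation, and the concentration
estimates come out biased even on spectra that look easy.

`qnmrfit` implements the least-squares fit *and* an adjustment stage that
recovers the signal the fit leaves behind in the residual, in the spirit of
peak integration (which is nearly lineshape-invariant).  It is aimed at
routine mixture analysis — reaction monitoring, quality control — where the
species present are known and their ideal signatures are available.

## The model and the adjustment

The real spectrum on the frequency grid `f` is modelled as `x = Z c`, where
the columns of `Z` hold the K species signatures

    z_k(f) = Σ_p b_p · u_p(f | f_p, α_p),
    u_p(f) = α_p Δt / ((2π(f − f_p))² + α_p²)      (FWHM = α_p/π Hz),

plus `L` polynomial baseline columns (`L = 1`, a constant, by default).  The
peak ratios `b_p` within one species are fixed by the molecule; each species
gets one free chemical-shift offset and one width scale, collected with the
phase in the nonlinear parameter vector θ.  Fitting minimises `‖y − Zc‖²`
with the intensities eliminated in closed form (`ĉ = Z⁺y`, variable
projection).  Signature tables can be written by hand, loaded from CSV/JSON,
or computed from a minimal spin Hamiltonian (shifts + J couplings), which
makes multiplets field-dependent as they are in reality.

The adjustment stage then decomposes the post-fit residual exactly,

    r = y − Ẑĉ = r_m + r_b + r_n,

with `r_n = r − Dr` (D: sym8 wavelet soft-thresholding), `r_b = SDr`
(S: multistage sliding median), and the misfit term `r_m = Dr − SDr`.  Two
corrections follow:

* **Phasing** — minimise `‖r_b(φ0, φ1)‖²` instead of `‖r‖²`.  A mis-phased
  peak leaves antisymmetric residual tails that the median filter turns into
  a sharp step in `r_b`, so this criterion locates the true phase where
  plain least squares compensates silently with biased positions and
  intensities.  Filter widths start above 10·FWHM and widen to 400·FWHM.
* **Intensities** — reallocate the misfit to the components in proportion to
  the local model value, `W_ik = Ẑ_ik ĉ_k / Σ_k Ẑ_ik ĉ_k`, giving

      c̃_k = ĉ_k + (Σ_i W_ik r_m,i) / (Σ_i Ẑ_ik),

  which reduces to `c̃ = ĉ` when the fit is perfect and otherwise restores
  the area a peak integral would have counted.

Mole fractions use the integral-per-proton convention,
`x_k ∝ c̃_k · area(z_k)/protons_k`, and accuracy is scored as
`RMSE_s = √((1/K) Σ_k (x_est − x_ref)²)` per sample, averaged over samples.

## Worked example

```python
import numpy as np
from qnmrfit import (AcquisitionParams, AdjustmentSettings, DistortionSpec,
                     Peak, Signature, SignatureModel, simulate_sample)

params = AcquisitionParams(dwell_time=1e-4, n_points=8192,
                           spectrometer_frequency=400.0)
alpha = 8 * params.frequency_step * np.pi          # FWHM = 8 grid points
species = [
    Signature("singlet", (Peak(1.0, alpha, 1.0),), proton_count=1),
    Signature("doublet", (Peak(2.40, 1.6 * alpha, 1.0),
                          Peak(2.56, 1.6 * alpha, 1.0)), proton_count=2),
]
truth = (0.3, 0.7)
_, spectrum = simulate_sample(            # broadened, mis-phased, noisy
    [(species[0], truth[0]), (species[1], truth[1])],
    DistortionSpec(gaussian_broadening=0.5 * species[0].mean_fwhm_hz(),
                   phase_error=(0.05, 0.0), snr=500.0, seed=7),
    params,
)

fit = SignatureModel(spectrum, species, baseline_order=1).fit()
print(fit.summary())
adj = fit.adjust(AdjustmentSettings(schedule_fwhm=(10.0, 100.0), final_fwhm=400.0))
print(adj.summary())
print("LS fractions:      ", np.round(fit.mole_fractions(), 4))
print("adjusted fractions:", np.round(adj.mole_fractions(), 4))
```

Output:

```
Signature model fit (variable projection least squares)
  n = 8192, K = 2, L = 1
  objective ||r||^2 = 1.382213e-13
  phase: phi0 = +0.00000 rad, phi1 = +0.000e+00 rad/Hz
  converged: True (70 evaluations)
  singlet          c= 0.30715  dshift=+0.00074 ppm  width x1.1414
  doublet          c= 0.708338  dshift=+0.00100 ppm  width x1.0619
  baseline^0        c=-1.64621e-10
Residual adjustment
  phase: phi0 = +0.05524 rad, phi1 = -2.505e-06 rad/Hz
  final |rb| peak-to-peak = 1.871e-10, ||rm||_1 = 3.642e-06
  singlet          c_LS= 0.30715  c_adj= 0.302409
  doublet          c_LS= 0.708338  c_adj= 0.70165
LS fractions:       [0.3025 0.6975]
adjusted fractions: [0.3012 0.6988]
```

The least-squares fit absorbs the Gaussian broadening into inflated widths
and still misses the true fractions (0.3/0.7) by 2.5 × 10⁻³; the adjustment
recovers most of the injected 0.05 rad phase error and halves the error in
the fractions.

A command-line interface wraps the same pipeline:

```sh
qnmrfit simulate --config sim.json --out-dir data/
qnmrfit quantify --input data/manifest.json --signatures sigs.csv --out-dir out/
qnmrfit report   --input out/report.json
```

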