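# Methods

This note records the model, the numerical choices, and the design decisions
behind `qnmrfit`, in the spirit of a statistical package's model
documentation.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and conventions

An FID `y_T[m]`, sampled at dwell time Δt for n points, is transformed as

    Y = Δt · FFT(y_T with its first point halved),

on the ascending grid `f ∈ [−1/(2Δt), 1/(2Δt))` Hz.  The half-point
correction removes the constant offset that rectangular truncation of the
sampled exponential otherwise places in every channel; it is a documented
toggle (default on).  The phased real spectrum is
`y = Re{Y · e^{−i(φ0 + φ1 f)}}` with the first-order pivot at f = 0 (the
centre of the spectrum).  A `Spectrum` always stores the unrotated complex
values plus the cumulative phase record, so re-phasing is exact and
invertible — a requirement of the phase-adjustment stage, which re-phases
thousands of times per fit.

The Lorentzian normalisation is `u_p(f) = α_p Δt/((2π(f−f_p))² + α_p²)`:
FWHM = α_p/π Hz, height Δt/α_p, area Δt/2, and `u_p = Re{Δt/(α_p +
2πi(f−f_p))}`.  With this pairing, a time-domain term `b_p Δt ·
e^{2πif_pt−α_pt}` transforms to `b_p u_p` exactly (up to O((αΔt)²)
discretisation), which is what the synthetic generator exploits.  All
quantification is ratio-based, so the global constant is immaterial; it is
fixed only so absolute intensities are well defined.  Chemical shifts map to
Hz as `f_p = B0(δ_p − f0)` with B0 in MHz and f0 the spectral offset in ppm.

Baseline columns are powers `f̂^{l−1}` of the frequency normalised to
[−1, 1] — the same polynomial space as raw powers, but conditioned; L = 1
(one constant column) is the working default.

## Fitting

Intensities are always eliminated in closed form through a rank-revealing
SVD solve (`lstsq`; condition numbers above 1e10 flag the result and fall
back to the minimum-norm solution), and the nonlinear search runs on the
variable-projection functional only.  Free parameters are one shift offset
(ppm) and one width scale per species — preserving the constraint that peak
ratios within a species are fixed — plus optionally (φ0, φ1).  Internally
every parameter is rescaled to order one (shifts in units of the mean FWHM,
φ1 in rad across half the spectral width) and the objective is normalised by
‖y‖², so the optimizer's tolerances are meaningful at any intensity scale.
The default optimizer is bounded L-BFGS-B with numerical gradients
(ftol 1e−10, gtol 1e−12, configurable); bounds default to ±0.2 ppm on
shifts, [0.2, 5] on width scales, ±0.5 rad on φ0.  Intensities are
unconstrained in sign.  Fits are deterministic given identical inputs and
options; non-convergence returns the best iterate, flagged.

## Residual decomposition

The decomposition is defined constructively so that it is an exact identity
for every input:

    r_n := r − Dr,   r_b := SDr,   r_m := Dr − SDr,   r = r_m + r_b + r_n.

D is wavelet soft-thresholding: sym8, depth `floor(log2 n) − 4`, per-level
universal thresholds `σ̂_j √(2 ln n_j)` with σ̂_j the MAD/0.6745 estimate
from that level's detail coefficients.  A zero threshold (noise-free level)
leaves the level untouched.  S is a sequence of sliding-median passes with
increasing odd widths; edges are handled by reflection (without repeating
the edge sample).  The median is computed by a skiplist rolling median over
a reflect-padded array — O(n log w), which matters for the 400·FWHM windows
of the final stage — and is verified against a brute-force sliding median
in the tests.

## Phase adjustment

The phase is fine-tuned by minimising ‖r_b(φ0, φ1)‖² with the signature
shifts/widths frozen at the least-squares fit and intensities re-solved at
every trial phase.  The cost is piecewise-constant in places (medians), so
the optimiser is derivative-free: a coarse grid over φ0 (default ±0.5 rad,
21 points) followed by Nelder–Mead refinement of the enabled parameters.
The width schedule defaults to (10, 50, 100)·FWHM for optimisation and
400·FWHM for the final decomposition, each stage warm-starting the next;
widths of 0 mean "no smoothing", in which limit (with denoising off) the
criterion provably reduces to the least-squares phase optimum — this
reduction is asserted in the tests.  Whether shifts/widths should be
re-refined after the phase update is genuinely open; it is exposed as a
`refit` flag (default off, one alternation cycle when on).  Minimising
‖r_b‖ may slightly increase ‖r‖ — only the baseline norm is penalised.

## Allocation and intensity adjustment

The misfit is reallocated by `W_ik = Ẑ_ik ĉ_k / Σ_k Ẑ_ik ĉ_k` over the K
signature columns only (baseline columns are bookkeeping, not species).
Negative products are clipped before row-normalisation; rows where every
model value is at or below a floor are 0/0 and fall back to uniform 1/K —
defensible because `r_m` is noise-free by construction, so those points
contribute negligibly; both events are logged.  The update
`c̃_k = ĉ_k + (Σ_i W_ik r_m,i)/(Σ_i Ẑ_ik)` conserves
`Σ_k c̃_k Σ_i Ẑ_ik = Σ_k ĉ_k Σ_i Ẑ_ik + Σ_i r_m,i` (asserted to 1e−9
relative) and preserves ĉ exactly at zero misfit.

## Spin systems

Signatures can be generated from isotropic shifts and scalar J couplings by
dense diagonalisation of `H/2π = Σ ν_i I_z,i + Σ J_ij I_i·I_j` in the 2^N
product basis (N ≤ 10; equivalent groups expanded literally, e.g. CH₃ as
three equal-shift spins).  Transition intensities are `|⟨b|ΣI⁻|a⟩|²`
normalised by the sum rule Tr{I⁺I⁻} = N·2^{N−1} so they total the spin
count; lines below 1e−6 of the strongest are pruned.  Relaxation is not
modelled: a single user-supplied decay rate is attached to every transition.

## Synthetic data

The generator emulates the distortions that break the Lorentzian
assumption in practice: a Gaussian time-domain envelope
`exp(−(πσ_g t)²/(4 ln 2))` parameterised so σ_g is the *added Gaussian FWHM
in Hz* (Voigt lineshape); complex second/third-order decay terms
`exp(−β₂t² − β₃t³)` (complex values give asymmetric peaks); residual
zero/first-order phase errors applied to the complex spectrum; a constant
baseline offset; and complex Gaussian frequency-domain noise calibrated so
that (tallest peak height)/(real-spectrum noise std) equals the requested
SNR — the common NMR usage.  Species amplitudes are chosen so the
integral-per-proton mole fractions equal the requested ones, and the stored
FID is the exact inverse transform of the distorted spectrum, keeping both
domains consistent.  Datasets derive per-sample seeds from a master seed via
`SeedSequence([master, index])` and record everything in a JSON manifest;
regeneration is byte-identical.

What the generator does *not* emulate: t1-noise and other coherent
artefacts, solvent signals, temperature drift between samples, and
correlated (non-white) noise.  Passing tests therefore demonstrate the
mechanics and the de-biasing behaviour under controlled misspecification,
not performance on any particular instrument's data.

## Study designs and problem sizes

The canned studies in `qnmrfit.studies` use n = 16384 with 20-point FWHM
for the single-peak phase studies and n = 8192 with ~8-point FWHM for the
mixture study — large enough that discretisation is far below the effects
measured, small enough that the full suite runs in about two minutes on one
core.  The single-peak intensity-bias result was checked to be insensitive
to n and to the window/FWHM ratio over 41–819 FWHM windows.

The improvement study deliberately uses *heterogeneous* species (a narrow
singlet, a 1.6× wider doublet, a 2.4× wider 1:2:1 triplet): when every
species has the same lineshape, a common symmetric distortion biases all
intensities by the same factor and cancels in mole fractions, leaving plain
least squares nearly unbiased and nothing for the adjustment to recover.
Species with different widths and multiplicities — the regime the method
targets — are biased differently, and the reallocation corrects them.
Mixtures span mole fractions 0.02–0.95 including near-boundary
compositions.

## Closed-form check of the phase-bias curve

For an infinite window the least-squares fit of a zero-phase absorption
Lorentzian (free position, width, intensity) to the same peak rotated by φ
has an exact solution (from the Lorentzian overlap integrals): the best
shift is FWHM·tan(φ/2), the width is unchanged, and the fitted intensity is
cos²(φ/2).  The relative intensity
error is therefore sin²(φ/2) — an even function of φ, while the shift error
is odd — and the package reproduces these to discretisation accuracy.  At
φ = 0.4 rad the error is sin²(0.2) ≈ 3.95 %; the often-quoted round figure
of "about 5 %" corresponds to φ ≈ 0.45 rad on the same curve.

## Known limitations

* The residual decomposition is ill-posed by nature; the D/S operators here
  are one defensible choice, and spectra with structured baselines or
  coloured noise may need different settings (`AdjustmentSettings` exposes
  all of them).
* The proportional allocation rule can misdirect misfit between strongly
  overlapped species; occasional per-sample degradation is expected even
  when the average improves.
* No uncertainty quantification is provided for the fitted or adjusted
  intensities.
* JCAMP-DX support covers uncompressed AFFN XYDATA and two-page NTUPLES
  records only; ASDF-compressed files are rejected explicitly rather than
  guessed at.  Real-only spectra read from disk cannot be re-phased, so the
  adjustment stage needs either the FID or an in-memory complex spectrum.
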