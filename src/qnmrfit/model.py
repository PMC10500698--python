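"""Least-squares signature fitting with variable projection (VARPRO).

The model spectrum is ``x = Z(θ)c``: the matrix ``Z`` holds the K species
signatures (evaluated at the nonlinear parameters θ — per-species chemical
shift offsets and width scales, plus optional zero/first-order phase of the
data) and L polynomial baseline columns.  Fitting minimises ``‖y − Zc‖²``.
For any θ, the intensities have the closed-form least-squares solution
``ĉ = Z⁺y``, so the nonlinear search runs over the variable-projection
functional ``‖(I − ZZ⁺)y‖²`` only — the paper-standard nested formulation,
which is also better conditioned than the joint problem.

Usage follows the Model/Results idiom::

    model = SignatureModel(spectrum, signatures, baseline_order=1)
    res = model.fit()
    res.summary()
    adj = res.adjust()          # residual-adjustment stage (see adjustment.py)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .signatures import ModelMatrix, Signature, build_model_matrix
from .spectra import Spectrum

__all__ = [
    "FitParams",
    "SignatureModel",
    "SignatureFitResults",
    "solve_intensities",
    "varpro_objective",
]

COND_MAX = 1e10


class RankDeficientWarning(UserWarning):
    """Model matrix numerically rank deficient; minimum-norm solution used."""


@dataclass(frozen=True)
class FitParams:
    """Nonlinear fit parameters θ.

    shift_offsets : ppm, one per signature (added to all its peaks)
    width_scales  : dimensionless, one per signature (multiplies all α_p)
    phi0, phi1    : zero-order (rad) and first-order (rad·Hz⁻¹) phase of the data
    """

    shift_offsets: np.ndarray
    width_scales: np.ndarray
    phi0: float = 0.0
    phi1: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift_offsets", np.atleast_1d(np.asarray(self.shift_offsets, float)))
        object.__setattr__(self, "width_scales", np.atleast_1d(np.asarray(self.width_scales, float)))
        if self.shift_offsets.shape != self.width_scales.shape:
            raise ValueError("shift_offsets and width_scales must have equal length")

    @classmethod
    def zero(cls, K: int) -> "FitParams":
        return cls(np.zeros(K), np.ones(K))


def solve_intensities(Z: ModelMatrix | np.ndarray, y: np.ndarray, cond_max: float = COND_MAX):
    """Closed-form intensity estimate ``ĉ = argmin_c ‖y − Zc‖²``.

    Solved with a rank-revealing SVD solve (`numpy.linalg.lstsq`), never by
    inverting the normal equations.  If the condition number exceeds
    ``cond_max`` a :class:`RankDeficientWarning` is raised and the
    minimum-norm solution is returned.

    Returns
    -------
    c : ndarray, length K+L
    rank_deficient : bool
    """
    A = Z.values if isinstance(Z, ModelMatrix) else np.asarray(Z, float)
    y = np.asarray(y, float)
    if A.shape[0] < A.shape[1]:
        raise ValueError(f"underdetermined system: n={A.shape[0]} < K+L={A.shape[1]}")
    c, _, rank, sv = np.linalg.lstsq(A, y, rcond=1.0 / cond_max)
    rank_deficient = rank < A.shape[1] or (sv[-1] > 0 and sv[0] / sv[-1] > cond_max)
    if rank_deficient:
        warnings.warn(
            f"model matrix numerically rank deficient (rank {rank} of {A.shape[1]}); "
            "minimum-norm intensities returned",
            RankDeficientWarning,
            stacklevel=2,
        )
    return c, rank_deficient


def varpro_objective(
    theta: FitParams,
    spectrum: Spectrum,
    sigs: list[Signature],
    baseline_order: int = 1,
) -> float:
    """Variable-projection functional ``‖y − Z ĉ(θ)‖²`` at the given θ.

    ``y`` is the real part of the complex spectrum rotated by θ's phase
    (falling back to the stored real values when only those exist and the
    phase equals the spectrum's record).
    """
    y = _real_data(spectrum, theta.phi0, theta.phi1)
    Z = build_model_matrix(
        sigs, baseline_order, spectrum.frequency, spectrum.params,
        theta.shift_offsets, theta.width_scales,
    )
    c, _ = solve_intensities(Z, y)
    r = y - Z.values @ c
    return float(r @ r)


def _real_data(spectrum: Spectrum, phi0: float, phi1: float) -> np.ndarray:
    if spectrum.complex_values is not None:
        return spectrum.real_at_phase(phi0, phi1)
    if (phi0, phi1) != spectrum.phase:
        raise ValueError("cannot re-phase a real-only spectrum")
    return spectrum.real_values


@dataclass
class FitBounds:
    """Box bounds for the free parameters (per-signature arrays broadcast)."""

    shift_ppm: float = 0.2
    width_scale: tuple[float, float] = (0.2, 5.0)
    phi0: tuple[float, float] = (-0.5, 0.5)
    phi1_halfwidth: float = 0.5  # rad across half the spectral width


class SignatureModel:
    """Parametric signature model of a 1D spectrum, fitted by VARPRO least squares.

    Parameters
    ----------
    spectrum : Spectrum
        The data; the complex spectrum must be present if ``fit_phase``.
    signatures : list of Signature
        Known species signatures (fixed intra-signature intensity ratios).
    baseline_order : int
        Number L of polynomial baseline columns; L = 1 (constant offset)
        is the default used throughout.
    fit_phase : bool
        Include (φ0, φ1) among the free parameters.  Off by default: the
        residual-adjustment stage provides the preferred phase criterion.
    bounds : FitBounds, optional
    """

    def __init__(
        self,
        spectrum: Spectrum,
        signatures: list[Signature],
        baseline_order: int = 1,
        fit_phase: bool = False,
        fit_shifts: bool = True,
        fit_widths: bool = True,
        bounds: FitBounds | None = None,
    ) -> None:
        if len(signatures) < 1:
            raise ValueError("need at least one signature")
        self.spectrum = spectrum
        self.signatures = list(signatures)
        self.baseline_order = int(baseline_order)
        self.fit_phase = bool(fit_phase)
        self.fit_shifts = bool(fit_shifts)
        self.fit_widths = bool(fit_widths)
        self.bounds = bounds or FitBounds()
        self.K = len(signatures)

    # -- parameter packing ---------------------------------------------------
    # Free parameters are optimised in scaled units of order one: shifts in
    # units of the mean FWHM (in ppm), width scales and phase as-is, phi1 in
    # rad across half the spectral width.

    def _scales(self) -> dict[str, float]:
        fwhm_ppm = float(
            np.mean([s.mean_fwhm_hz() for s in self.signatures])
            / self.spectrum.params.spectrometer_frequency
        )
        return {"shift": fwhm_ppm, "phi1": 2.0 / self.spectrum.params.spectral_width}

    def _pack(self, p: FitParams) -> tuple[np.ndarray, list[tuple[float, float]]]:
        s = self._scales()
        x, bnds = [], []
        b = self.bounds
        if self.fit_shifts:
            x += list(p.shift_offsets / s["shift"])
            bnds += [(-b.shift_ppm / s["shift"], b.shift_ppm / s["shift"])] * self.K
        if self.fit_widths:
            x += list(p.width_scales)
            bnds += [b.width_scale] * self.K
        if self.fit_phase:
            x += [p.phi0, p.phi1 / s["phi1"]]
            bnds += [b.phi0, (-b.phi1_halfwidth, b.phi1_halfwidth)]
        return np.array(x, float), bnds

    def _unpack(self, x: np.ndarray, base: FitParams) -> FitParams:
        s = self._scales()
        i = 0
        shift = base.shift_offsets
        width = base.width_scales
        phi0, phi1 = base.phi0, base.phi1
        if self.fit_shifts:
            shift = x[i : i + self.K] * s["shift"]
            i += self.K
        if self.fit_widths:
            width = x[i : i + self.K]
            i += self.K
        if self.fit_phase:
            phi0 = float(x[i])
            phi1 = float(x[i + 1]) * s["phi1"]
        return FitParams(shift, width, phi0, phi1)

    # -- fitting -------------------------------------------------------------

    def objective(self, theta: FitParams) -> float:
        return varpro_objective(theta, self.spectrum, self.signatures, self.baseline_order)

    def fit(
        self,
        start: FitParams | None = None,
        method: str = "L-BFGS-B",
        ftol: float = 1e-10,
        gtol: float = 1e-12,
        maxiter: int = 500,
    ) -> "SignatureFitResults":
        """Minimise the VARPRO functional from ``start`` (default: zero offsets,
        unit widths, the spectrum's recorded phase).

        Deterministic given identical inputs and options.  On optimizer
        non-convergence the best iterate is returned with
        ``converged = False``.
        """
        if start is None:
            start = FitParams(
                np.zeros(self.K), np.ones(self.K),
                self.spectrum.phase[0], self.spectrum.phase[1],
            )
        x0, bnds = self._pack(start)
        f0 = self.objective(start)

        if x0.size == 0:  # nothing nonlinear to optimise
            return self._results(start, f0, converged=True, n_eval=1, message="no free parameters")

        # optimise the objective relative to ||y||^2 so the optimizer's
        # absolute ftol/gtol are meaningful at any intensity scale
        y0 = _real_data(self.spectrum, start.phi0, start.phi1)
        norm = float(y0 @ y0) or 1.0

        def fun(x: np.ndarray) -> float:
            return self.objective(self._unpack(x, start)) / norm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RankDeficientWarning)
            opt = optimize.minimize(
                fun, x0, method=method, bounds=bnds,
                options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter}
                if method.upper() == "L-BFGS-B"
                else {"maxiter": maxiter, "fatol": ftol, "xatol": 1e-8},
            )
        theta = self._unpack(opt.x, start)
        f_opt = self.objective(theta)
        if f_opt > f0:  # guard monotone improvement
            theta, f_opt = start, f0
        return self._results(
            theta, f_opt, converged=bool(opt.success), n_eval=int(opt.nfev),
            message=str(opt.message),
        )

    def _results(self, theta, objective, converged, n_eval, message):
        y = _real_data(self.spectrum, theta.phi0, theta.phi1)
        Z = build_model_matrix(
            self.signatures, self.baseline_order, self.spectrum.frequency,
            self.spectrum.params, theta.shift_offsets, theta.width_scales,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", RankDeficientWarning)
            c, rank_deficient = solve_intensities(Z, y)
        for w in caught:
            if not issubclass(w.category, RankDeficientWarning):
                warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
        return SignatureFitResults(
            model=self, params=theta, model_matrix=Z, intensities=c, data=y,
            objective=float(objective), converged=converged,
            rank_deficient=rank_deficient, n_eval=n_eval, message=message,
        )


@dataclass
class SignatureFitResults:
    """Outcome of a VARPRO fit; residual identity ``r = y − Zĉ`` holds as stored."""

    model: SignatureModel
    params: FitParams
    model_matrix: ModelMatrix
    intensities: np.ndarray
    data: np.ndarray
    objective: float
    converged: bool
    rank_deficient: bool
    n_eval: int
    message: str
    fitted: np.ndarray = field(init=False)
    residual: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fitted = self.model_matrix.values @ self.intensities
        self.residual = self.data - self.fitted

    @property
    def signature_intensities(self) -> np.ndarray:
        """ĉ restricted to the K signature columns (baseline excluded)."""
        return self.intensities[: self.model.K]

    def mean_fwhm_hz(self) -> float:
        return float(
            np.mean(
                [
                    s.mean_fwhm_hz(w)
                    for s, w in zip(self.model.signatures, self.params.width_scales)
                ]
            )
        )

    def mean_fwhm_points(self) -> float:
        return self.mean_fwhm_hz() / self.model.spectrum.params.frequency_step

    def mole_fractions(self) -> np.ndarray:
        from .quantify import mole_fractions

        return mole_fractions(
            self.signature_intensities, self.model.signatures,
            self.model.spectrum.params.dwell_time,
        )

    def adjust(self, settings=None):
        """Run the residual-adjustment stage (phase fine-tuning + misfit
        reallocation) on this fit; see :func:`qnmrfit.adjustment.run_adjustment`."""
        from .adjustment import run_adjustment

        return run_adjustment(self, settings)

    def summary(self) -> str:
        rows = []
        for k, s in enumerate(self.model.signatures):
            rows.append(
                f"  {s.species_name:<16s} c={self.intensities[k]: .6g}  "
                f"dshift={self.params.shift_offsets[k]:+.5f} ppm  "
                f"width x{self.params.width_scales[k]:.4f}"
            )
        for l in range(self.model.baseline_order):
            rows.append(f"  baseline^{l:<8d} c={self.intensities[self.model.K + l]: .6g}")
        lines = [
            "Signature model fit (variable projection least squares)",
            f"  n = {self.data.size}, K = {self.model.K}, L = {self.model.baseline_order}",
            f"  objective ||r||^2 = {self.objective:.6e}"
            + ("  [rank-deficient]" if self.rank_deficient else ""),
            f"  phase: phi0 = {self.params.phi0:+.5f} rad, "
            f"phi1 = {self.params.phi1:+.3e} rad/Hz",
            f"  converged: {self.converged} ({self.n_eval} evaluations)",
        ] + rows
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.model.spectrum.frequency,
                "data": self.data,
                "fitted": self.fitted,
                "residual": self.residual,
            }
        )

    def plot(self, ax=None):
        """Data, fit and residual against the ppm axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ppm = self.model.spectrum.ppm
        ax.plot(ppm, self.data, lw=0.8, label="data")
        ax.plot(ppm, self.fitted, lw=0.8, label="fit")
        ax.plot(ppm, self.residual, lw=0.6, label="residual")
        ax.invert_xaxis()
        ax.set_xlabel("chemical shift (ppm)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax

    def with_phase(self, phi0: float, phi1: float) -> "SignatureFitResults":
        """Re-evaluate this fit at a new absolute phase (intensities re-solved,
        shifts/widths kept)."""
        theta = replace(self.params, phi0=float(phi0), phi1=float(phi1))
        obj = self.model.objective(theta)
        return self.model._results(
            theta, obj, converged=self.converged, n_eval=self.n_eval,
            message="re-phased",
        )
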