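"""Lorentzian peaks, species signatures, and the model matrix.

A species' signature spectrum is a fixed-ratio combination of Lorentzian
peaks,

    z_k(f) = Σ_p b_p · u_p(f | f_p, α_p),

where the relative intensities ``b_p`` are set by the molecule's atomic
composition and never vary during fitting; only a global scale, a common
chemical-shift offset and a common width scale are free.  The adopted peak
normalisation is

    u_p(f) = α_p Δt / ((2π(f − f_p))² + α_p²),

i.e. the real part of ``Δt / (α_p + 2πi(f − f_p))``: FWHM = α_p/π Hz, peak
height Δt/α_p, area Δt/2.  Quantification uses intensity ratios, so the
constant is immaterial but fixed for absolute work.

The model matrix Z stacks one column per species signature plus ``L``
polynomial baseline columns ``f^{l−1}`` (L = 1 gives a single constant
column, the default used throughout).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import AcquisitionParams

__all__ = [
    "Peak",
    "Signature",
    "ModelMatrix",
    "lorentzian",
    "signature_spectrum",
    "build_model_matrix",
    "read_signatures",
    "write_signatures",
]


@dataclass(frozen=True)
class Peak:
    """One Lorentzian line: position δ_p (ppm), decay rate α_p (s⁻¹), weight b_p."""

    chemical_shift: float
    decay_rate: float
    relative_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not self.decay_rate > 0:
            raise ValueError(f"decay_rate must be > 0, got {self.decay_rate}")
        if self.relative_intensity < 0:
            raise ValueError("relative_intensity must be >= 0")

    @property
    def fwhm_hz(self) -> float:
        return self.decay_rate / np.pi


@dataclass(frozen=True)
class Signature:
    """Peak table of one chemical species.

    ``proton_count`` is used only when converting fitted intensities to mole
    fractions (integral-per-proton convention); the peak weights ``b_p`` are
    stored as given and not normalised internally.
    """

    species_name: str
    peaks: tuple[Peak, ...]
    proton_count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if len(self.peaks) < 1:
            raise ValueError(f"signature {self.species_name!r} has no peaks")
        if self.proton_count < 1:
            raise ValueError("proton_count must be a positive integer")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def mean_fwhm_hz(self, width_scale: float = 1.0) -> float:
        return float(np.mean([p.decay_rate for p in self.peaks])) * width_scale / np.pi

    def area_per_unit_intensity(self, dt: float) -> float:
        """Integral of z_k at unit intensity: (Δt/2)·Σ_p b_p (width-invariant)."""
        return 0.5 * dt * sum(p.relative_intensity for p in self.peaks)


@dataclass
class ModelMatrix:
    """n×(K+L) design matrix: K signature columns then L baseline columns."""

    values: np.ndarray
    column_roles: list[str]
    grid: np.ndarray
    n_signatures: int
    baseline_order: int

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if m != self.n_signatures + self.baseline_order:
            raise ValueError("column count does not match K + L")
        sig_cols = self.values[:, : self.n_signatures]
        if self.n_signatures and np.any(np.all(sig_cols == 0.0, axis=0)):
            raise ValueError("model matrix contains an all-zero signature column")

    @property
    def signature_columns(self) -> np.ndarray:
        return self.values[:, : self.n_signatures]

    @property
    def baseline_columns(self) -> np.ndarray:
        return self.values[:, self.n_signatures :]


def lorentzian(grid: np.ndarray, f_p: float, alpha_p: float, dt: float) -> np.ndarray:
    """Absorption Lorentzian u_p on a Hz grid; FWHM = α_p/π, height Δt/α_p."""
    if not alpha_p > 0:
        raise ValueError(f"alpha_p must be > 0, got {alpha_p}")
    d = 2.0 * np.pi * (np.asarray(grid, dtype=float) - f_p)
    return alpha_p * dt / (d * d + alpha_p * alpha_p)


def complex_lorentzian(grid: np.ndarray, f_p: float, alpha_p: float, dt: float) -> np.ndarray:
    """Complex line Δt/(α_p + 2πi(f − f_p)); real part equals ``lorentzian``."""
    if not alpha_p > 0:
        raise ValueError(f"alpha_p must be > 0, got {alpha_p}")
    return dt / (alpha_p + 2j * np.pi * (np.asarray(grid, dtype=float) - f_p))


def signature_spectrum(
    sig: Signature,
    grid: np.ndarray,
    params: AcquisitionParams,
    shift_offset: float = 0.0,
    width_scale: float = 1.0,
) -> np.ndarray:
    """Evaluate Σ_p b_p·u_p with all of the signature's peaks shifted by
    ``shift_offset`` ppm and widths scaled by ``width_scale``.

    Peaks whose centre falls outside the grid still contribute their tails;
    a warning (not an error) flags the truncation.
    """
    if not width_scale > 0:
        raise ValueError("width_scale must be > 0")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    f_lo, f_hi = grid[0], grid[-1]
    for p in sig.peaks:
        f_p = float(params.ppm_to_hz(p.chemical_shift + shift_offset))
        if not (f_lo <= f_p <= f_hi):
            warnings.warn(
                f"peak of {sig.species_name!r} at {f_p:.1f} Hz lies outside the "
                f"grid [{f_lo:.1f}, {f_hi:.1f}]; contribution truncated",
                stacklevel=2,
            )
        out += p.relative_intensity * lorentzian(
            grid, f_p, p.decay_rate * width_scale, params.dwell_time
        )
    return out


def complex_signature_spectrum(
    sig: Signature,
    grid: np.ndarray,
    params: AcquisitionParams,
    shift_offset: float = 0.0,
    width_scale: float = 1.0,
) -> np.ndarray:
    """Complex-valued counterpart of ``signature_spectrum`` (for simulation)."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros(grid.shape, dtype=complex)
    for p in sig.peaks:
        f_p = float(params.ppm_to_hz(p.chemical_shift + shift_offset))
        out += p.relative_intensity * complex_lorentzian(
            grid, f_p, p.decay_rate * width_scale, params.dwell_time
        )
    return out


def baseline_basis(grid: np.ndarray, order: int) -> np.ndarray:
    """Polynomial baseline columns f̂^{l−1}, l = 1…L, with f̂ = f/max|f|.

    The normalisation keeps higher-order columns well conditioned; it spans
    the same polynomial space as raw powers of f.  L = 1 is a single ones
    column.
    """
    grid = np.asarray(grid, dtype=float)
    scale = np.max(np.abs(grid)) or 1.0
    return np.column_stack([(grid / scale) ** l for l in range(order)])


def build_model_matrix(
    sigs: list[Signature],
    baseline_order: int,
    grid: np.ndarray,
    params: AcquisitionParams,
    shift_offsets: np.ndarray | None = None,
    width_scales: np.ndarray | None = None,
) -> ModelMatrix:
    """Assemble Z: one column per signature (evaluated at the given per-species
    shift offsets and width scales) followed by ``baseline_order`` polynomial
    baseline columns."""
    if len(sigs) < 1:
        raise ValueError("need at least one signature")
    if baseline_order < 0:
        raise ValueError("baseline_order must be >= 0")
    names = [s.species_name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate species names in {names}")
    K = len(sigs)
    shift_offsets = np.zeros(K) if shift_offsets is None else np.asarray(shift_offsets, float)
    width_scales = np.ones(K) if width_scales is None else np.asarray(width_scales, float)
    cols = [
        signature_spectrum(s, grid, params, shift_offsets[k], width_scales[k])
        for k, s in enumerate(sigs)
    ]
    if baseline_order:
        cols.append(baseline_basis(grid, baseline_order))
    values = np.column_stack(cols)
    roles = names + [f"baseline^{l}" for l in range(baseline_order)]
    return ModelMatrix(
        values=values,
        column_roles=roles,
        grid=np.asarray(grid, float),
        n_signatures=K,
        baseline_order=baseline_order,
    )


# ---------------------------------------------------------------------------
# Signature tables on disk: CSV with columns
# species, delta_ppm, alpha_per_s, b_rel, protons — or the same records in JSON.

def write_signatures(sigs: list[Signature], path) -> None:
    rows = [
        {
            "species": s.species_name,
            "delta_ppm": p.chemical_shift,
            "alpha_per_s": p.decay_rate,
            "b_rel": p.relative_intensity,
            "protons": s.proton_count,
        }
        for s in sigs
        for p in s.peaks
    ]
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def read_signatures(path) -> list[Signature]:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    required = {"species", "delta_ppm", "alpha_per_s", "b_rel", "protons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signature table {path} lacks columns {sorted(missing)}")
    sigs = []
    for name, grp in df.groupby("species", sort=False):
        peaks = [
            Peak(row.delta_ppm, row.alpha_per_s, row.b_rel)
            for row in grp.itertuples()
        ]
        sigs.append(
            Signature(str(name), tuple(peaks), int(grp["protons"].iloc[0]))
        )
    return sigs
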