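"""Time- and frequency-domain containers for 1D NMR data.

The free induction decay (FID) is the complex time-domain signal recorded by
the spectrometer; its discrete Fourier transform, after zero/first-order
phase correction, is the real absorption spectrum that quantification
operates on.

DFT convention
--------------
``compute_spectrum`` forms the complex spectrum as ``Δt · FFT(fid)`` on an
ascending frequency grid spanning ``[−1/(2Δt), 1/(2Δt))`` Hz, after halving
the first FID point (standard half-point correction, suppresses the constant
offset the rectangular truncation otherwise induces; toggleable).  With this
scaling a unit-amplitude decaying exponential transforms to the complex
Lorentzian ``1/(α + 2πi(f−f_p))``.  Quantification uses intensity ratios, so
the global constant is immaterial; it is fixed here for absolute work.

Phasing is stored, not baked in: a ``Spectrum`` retains the unrotated complex
values together with the cumulative phase record ``(φ0, φ1)``, and its real
part is always ``Re{C · e^{−i(φ0 + φ1 f)}}`` with ``f`` in Hz and the
first-order pivot at ``f = 0`` (centre of the spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "FID",
    "Spectrum",
    "compute_spectrum",
    "phase_rotate",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata needed to map an FID onto a frequency/ppm axis.

    Parameters
    ----------
    dwell_time : float
        Sampling interval Δt of the FID in seconds; the spectral width is
        1/Δt Hz.
    n_points : int
        Number of complex time-domain points (≥ 8).
    spectrometer_frequency : float
        Operating (Larmor) frequency B0 in MHz; converts ppm to Hz.
    spectral_offset : float
        Offset f0 of the carrier in ppm; a resonance at δ ppm appears at
        ``B0·(δ − f0)`` Hz.
    """

    dwell_time: float
    n_points: int
    spectrometer_frequency: float
    spectral_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.dwell_time > 0:
            raise ValueError(f"dwell_time must be > 0, got {self.dwell_time}")
        if int(self.n_points) != self.n_points or self.n_points < 8:
            raise ValueError(f"n_points must be an integer >= 8, got {self.n_points}")
        if not self.spectrometer_frequency > 0:
            raise ValueError("spectrometer_frequency must be > 0 MHz")

    @property
    def spectral_width(self) -> float:
        """Spectral width 1/Δt in Hz."""
        return 1.0 / self.dwell_time

    @property
    def frequency_step(self) -> float:
        """Grid spacing 1/(nΔt) in Hz."""
        return 1.0 / (self.n_points * self.dwell_time)

    def frequency_grid(self) -> np.ndarray:
        """Ascending frequency axis in Hz, ``min(f) = −1/(2Δt)``."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time

    def hz_to_ppm(self, f_hz: np.ndarray | float) -> np.ndarray | float:
        """δ = f/B0 + f0 (higher ppm at higher frequency)."""
        return np.asarray(f_hz) / self.spectrometer_frequency + self.spectral_offset

    def ppm_to_hz(self, delta_ppm: np.ndarray | float) -> np.ndarray | float:
        """f_p = B0·(δ_p − f0)."""
        return self.spectrometer_frequency * (np.asarray(delta_ppm) - self.spectral_offset)


@dataclass(frozen=True)
class FID:
    """A complex free induction decay plus its acquisition parameters."""

    samples: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=complex)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size != self.params.n_points:
            raise ValueError(
                f"FID length {samples.size} does not match params.n_points "
                f"{self.params.n_points}"
            )

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class Spectrum:
    """A frequency-domain spectrum with retained complex values and phase record.

    ``real_values`` is always consistent with ``complex_values`` rotated by
    the current ``phase``; re-phasing is therefore exact and loss-free.
    ``complex_values`` may be ``None`` for real-only data read from disk, in
    which case re-phasing is impossible.
    """

    frequency: np.ndarray
    real_values: np.ndarray
    complex_values: np.ndarray | None
    phase: tuple[float, float]
    params: AcquisitionParams

    @property
    def n(self) -> int:
        return self.real_values.size

    @property
    def ppm(self) -> np.ndarray:
        return np.asarray(self.params.hz_to_ppm(self.frequency))

    def power(self) -> float:
        """Continuous-normalised total power ``Σ|Y|²·df`` of the complex spectrum."""
        if self.complex_values is None:
            raise ValueError("complex values unavailable for a real-only spectrum")
        return float(np.sum(np.abs(self.complex_values) ** 2) * self.params.frequency_step)

    def real_at_phase(self, phi0: float, phi1: float) -> np.ndarray:
        """Real part of the complex spectrum rotated by absolute ``(φ0, φ1)``.

        Cheap inner-loop primitive for phase optimisation; does not mutate
        the spectrum.
        """
        if self.complex_values is None:
            raise ValueError(
                "complex values unavailable; recompute the spectrum from the FID"
            )
        rot = np.exp(-1j * (phi0 + phi1 * self.frequency))
        return (self.complex_values * rot).real

    def to_frame(self) -> pd.DataFrame:
        """(f Hz, δ ppm, y) triples as a DataFrame."""
        return pd.DataFrame(
            {"frequency_hz": self.frequency, "ppm": self.ppm, "intensity": self.real_values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_spectrum(
    fid: FID,
    phi0: float = 0.0,
    phi1: float = 0.0,
    half_point_correction: bool = True,
) -> Spectrum:
    """Fourier-transform an FID into a phased real spectrum.

    Parameters
    ----------
    fid : FID
        Complex time-domain data.
    phi0, phi1 : float
        Zero-order phase in rad and first-order phase in rad·Hz⁻¹, applied
        as ``e^{−i(φ0 + φ1 f)}`` against the Hz axis.
    half_point_correction : bool
        Halve the first FID point before the transform (default on).

    Returns
    -------
    Spectrum
        With the unrotated complex spectrum retained and the phase recorded.
    """
    samples = np.asarray(fid.samples, dtype=complex)
    if not np.all(np.isfinite(samples.real)) or not np.all(np.isfinite(samples.imag)):
        bad = int(np.flatnonzero(~np.isfinite(samples.real) | ~np.isfinite(samples.imag))[0])
        raise ValueError(f"FID contains non-finite samples (first at index {bad})")
    if half_point_correction:
        samples = samples.copy()
        samples[0] *= 0.5
    dt = fid.params.dwell_time
    complex_spectrum = np.fft.fftshift(np.fft.fft(samples)) * dt
    grid = fid.params.frequency_grid()
    spec = Spectrum(
        frequency=grid,
        real_values=np.empty(0),
        complex_values=complex_spectrum,
        phase=(float(phi0), float(phi1)),
        params=fid.params,
    )
    spec.real_values = spec.real_at_phase(phi0, phi1)
    return spec


def phase_rotate(spectrum: Spectrum, phi0: float, phi1: float) -> Spectrum:
    """Apply an additional zero/first-order phase rotation to a spectrum.

    The returned spectrum's phase record is the sum of the old and new
    angles; because the unrotated complex spectrum is retained, rotating by
    ``(a, b)`` and then ``(−a, −b)`` restores the original exactly.
    """
    if spectrum.complex_values is None:
        raise ValueError(
            "cannot re-phase a real-only spectrum; recompute it from the FID"
        )
    total0 = spectrum.phase[0] + float(phi0)
    total1 = spectrum.phase[1] + float(phi1)
    new = replace(spectrum, phase=(total0, total1))
    new.real_values = new.real_at_phase(total0, total1)
    return new
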