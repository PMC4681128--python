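"""Wavenumber grid for spectral-domain OCT.

All spectral quantities live on a uniform wavenumber axis k (rad/µm); depths are
in µm. Wavelength <-> wavenumber conversions are exact (k = 2π/λ), never the
small-bandwidth linearisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


def wavelength_to_wavenumber(wavelength_um: float | np.ndarray) -> float | np.ndarray:
    """k = 2π/λ, with λ in µm and k in rad/µm."""
    return TWO_PI / np.asarray(wavelength_um, dtype=float)


def wavelength_fwhm_to_k_fwhm(center_um: float, fwhm_um: float) -> float:
    """Exact width of the k interval spanned by [λc − Δλ/2, λc + Δλ/2].

    Δk = 2π Δλ / (λc² − Δλ²/4); reduces to 2π Δλ/λc² for narrow bands.
    """
    if fwhm_um <= 0:
        raise ValueError("FWHM must be positive")
    return TWO_PI * fwhm_um / (center_um**2 - fwhm_um**2 / 4.0)


@dataclass(frozen=True)
class KGrid:
    """Uniform wavenumber sampling grid plus the source-spectrum parameters.

    Parameters
    ----------
    k_values : ndarray
        Strictly increasing, uniformly spaced wavenumber axis in rad/µm.
    center_wavelength : float
        Source center wavelength in µm (~0.84 for the systems modelled here).
    fwhm_bandwidth : float
        Source spectral FWHM in µm of wavelength (~0.05–0.06).
    """

    k_values: np.ndarray
    center_wavelength: float
    fwhm_bandwidth: float

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=float)
        object.__setattr__(self, "k_values", k)
        if k.ndim != 1 or k.size < 16:
            raise ValueError("k grid needs at least 16 samples on a 1-D axis")
        dk = np.diff(k)
        if np.any(dk <= 0):
            raise ValueError("k_values must be strictly increasing")
        mean_dk = dk.mean()
        if np.max(np.abs(dk - mean_dk)) > 1e-9 * mean_dk:
            raise ValueError("k_values must be uniformly spaced (linear-in-k grid)")
        if self.center_wavelength <= 0 or self.fwhm_bandwidth <= 0:
            raise ValueError("source center wavelength and FWHM must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def samples(self) -> int:
        return int(self.k_values.size)

    @property
    def k_min(self) -> float:
        return float(self.k_values[0])

    @property
    def k_max(self) -> float:
        return float(self.k_values[-1])

    @property
    def span(self) -> float:
        """Total sampled wavenumber range in rad/µm."""
        return self.k_max - self.k_min

    @property
    def dk(self) -> float:
        return self.span / (self.samples - 1)

    @property
    def center_k(self) -> float:
        return float(wavelength_to_wavenumber(self.center_wavelength))

    @property
    def pixel_pitch_z(self) -> float:
        """Depth sampling interval π/(k span), µm per depth pixel."""
        return float(np.pi / self.span)

    @property
    def n_depth(self) -> int:
        """Depth pixels in the retained positive-frequency half."""
        return self.samples // 2

    @property
    def max_depth(self) -> float:
        """Unambiguous imaging depth in µm."""
        return self.n_depth * self.pixel_pitch_z

    # -- source -------------------------------------------------------------

    @property
    def source_fwhm_k(self) -> float:
        return wavelength_fwhm_to_k_fwhm(self.center_wavelength, self.fwhm_bandwidth)

    def source_spectrum(self) -> np.ndarray:
        """Gaussian power spectrum S(k), peak 1 at the source center."""
        sigma = self.source_fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((self.k_values - self.center_k) / sigma) ** 2)

    @classmethod
    def from_source(
        cls,
        center_wavelength: float = 0.840,
        fwhm_bandwidth: float = 0.060,
        samples: int = 512,
        span_factor: float = 3.0,
    ) -> "KGrid":
        """Grid centered on the source, spanning ``span_factor`` source FWHMs in k."""
        k0 = wavelength_to_wavenumber(center_wavelength)
        half = 0.5 * span_factor * wavelength_fwhm_to_k_fwhm(center_wavelength, fwhm_bandwidth)
        k = np.linspace(k0 - half, k0 + half, samples)
        return cls(k_values=k, center_wavelength=center_wavelength, fwhm_bandwidth=fwhm_bandwidth)
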