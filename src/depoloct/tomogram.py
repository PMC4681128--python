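"""Complex tomogram reconstruction from two-channel spectral interferograms.

A Fourier-domain PS-OCT measurement provides, per lateral position x, the real
spectral interferograms s₁(k) and s₂(k) of the two orthogonal polarization
channels. The complex depth profiles follow by inverse Fourier transform along
k; the positive-depth half of the transform carries the usable image. Windowing
the spectrum with G(k_β, Δk) before the transform yields the per-sub-band
fields E₁,₂^β(z) used by the spectral depolarization metric.

Conventions
-----------
* The transform is the unitary (``norm="ortho"``) inverse DFT along the k axis,
  so Parseval's theorem holds without scale factors.
* Depth index 0 is zero delay; the positive-frequency half (``samples // 2``
  pixels) is retained by default, with pitch π/(k span) µm per pixel. The grid
  is assumed linear in k already — λ→k resampling is an acquisition-side step;
  pass pre-resampled spectra (a user-supplied resampler can be applied to
  ``RawSpectra.data`` before calling into this module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft

from .grid import KGrid, wavelength_fwhm_to_k_fwhm, wavelength_to_wavenumber

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RawSpectra:
    """Two-channel real spectral interferogram stack.

    ``data`` is indexed ``(channel, frame, a_line, k_sample)`` with exactly two
    polarization channels. ``meta`` carries free-form acquisition annotations;
    ``pixel_pitch_x_um`` there sets the lateral pitch of reconstructions.
    """

    data: np.ndarray
    grid: KGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError("data must be 4-D: (channel, frame, a_line, k_sample)")
        if d.shape[0] != 2:
            raise ValueError("exactly two polarization channels are required")
        if d.shape[-1] != self.grid.samples:
            raise ValueError("k_sample axis length must equal grid.samples")
        if not np.all(np.isfinite(d)):
            raise ValueError("spectral data contains non-finite values")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_alines(self) -> int:
        return self.data.shape[2]

    @property
    def pixel_pitch_x(self) -> float:
        return float(self.meta.get("pixel_pitch_x_um", 1.0))


@dataclass
class SpectralWindowSpec:
    """Sub-band window bank: N_β windows of common bandwidth Δk.

    ``centers`` are the band-center wavenumbers k_β (rad/µm); ``fwhm`` is the
    bandwidth Δk shared by all bands (FWHM for Gaussian windows, full width for
    rectangular ones). ``normalize_energy`` scales each window to unit L2 norm
    so bands with unequal source power contribute comparably.
    """

    centers: np.ndarray
    fwhm: float
    shape: str = "gaussian"
    normalize_energy: bool = True

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.centers, dtype=float))
        if c.ndim != 1 or c.size < 1:
            raise ValueError("centers must be a non-empty 1-D sequence")
        if self.fwhm <= 0:
            raise ValueError("window bandwidth must be positive")
        if self.shape not in ("gaussian", "rectangular"):
            raise ValueError("shape must be 'gaussian' or 'rectangular'")
        self.centers = c

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    @classmethod
    def from_wavelength(
        cls,
        centers_um: Sequence[float],
        fwhm_um: float,
        shape: str = "gaussian",
        normalize_energy: bool = True,
    ) -> "SpectralWindowSpec":
        """Build from band centers/width given in wavelength (µm), converted exactly."""
        centers_um = np.asarray(centers_um, dtype=float)
        k_centers = wavelength_to_wavenumber(centers_um)
        k_fwhm = wavelength_fwhm_to_k_fwhm(float(np.mean(centers_um)), fwhm_um)
        return cls(centers=k_centers, fwhm=k_fwhm, shape=shape,
                   normalize_energy=normalize_energy)

    @classmethod
    def default_three_band(cls) -> "SpectralWindowSpec":
        """Three Gaussian bands at 820/840/860 nm with 20 nm FWHM."""
        return cls.from_wavelength([0.820, 0.840, 0.860], 0.020, shape="gaussian")

    @classmethod
    def tiled(cls, grid: KGrid, n_bands: int, shape: str = "rectangular",
              normalize_energy: bool = False) -> "SpectralWindowSpec":
        """``n_bands`` contiguous equal-width windows tiling the full grid."""
        if n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        width = grid.span / n_bands
        centers = grid.k_min + width * (np.arange(n_bands) + 0.5)
        return cls(centers=centers, fwhm=width, shape=shape,
                   normalize_energy=normalize_energy)


@dataclass
class JonesField:
    """Complex two-component field per pixel.

    ``e1``/``e2`` are congruent complex arrays indexed
    ``(band, frame, z, x)``; singleton band/frame axes are kept so every
    downstream operation sees one canonical layout.
    """

    e1: np.ndarray
    e2: np.ndarray
    pixel_pitch_z: float
    pixel_pitch_x: float = 1.0

    def __post_init__(self) -> None:
        e1 = np.asarray(self.e1, dtype=complex)
        e2 = np.asarray(self.e2, dtype=complex)
        if e1.shape != e2.shape:
            raise ValueError("e1 and e2 must be congruent in shape")
        if e1.ndim != 4:
            raise ValueError("fields are stored as (band, frame, z, x)")
        self.e1, self.e2 = e1, e2

    @property
    def n_bands(self) -> int:
        return self.e1.shape[0]

    @property
    def n_frames(self) -> int:
        return self.e1.shape[1]

    @property
    def shape(self) -> tuple:
        return self.e1.shape

    def intensity(self) -> np.ndarray:
        return np.abs(self.e1) ** 2 + np.abs(self.e2) ** 2


def preprocess_spectra(raw: RawSpectra) -> RawSpectra:
    """Remove DC and fixed-pattern terms by subtracting the mean A-line.

    Per channel and frame the mean spectrum across A-lines is subtracted from
    every A-line; a term common to all lateral positions (reference-arm DC,
    fixed-pattern noise) is annihilated while speckle-varying signal survives.
    """
    centered = raw.data - raw.data.mean(axis=2, keepdims=True)
    return RawSpectra(data=centered, grid=raw.grid, meta=dict(raw.meta))


def _apply_apodization(data: np.ndarray, apodization: np.ndarray | None) -> np.ndarray:
    if apodization is None:
        return data
    apod = np.asarray(apodization, dtype=float)
    if apod.ndim != 1 or apod.size != data.shape[-1]:
        raise ValueError("apodization length must equal the number of k samples")
    return data * apod


def reconstruct(
    raw: RawSpectra,
    apodization: np.ndarray | None = None,
    depth: str = "positive",
) -> JonesField:
    """Inverse Fourier transform of s₁,₂(k) along k -> complex depth profiles.

    Parameters
    ----------
    raw : RawSpectra
        (Preprocessed) spectra.
    apodization : ndarray, optional
        Real window over the full band, length ``grid.samples``.
    depth : {"positive", "full"}
        ``"positive"`` (default) keeps the positive-frequency half
        (``samples // 2`` depth pixels, index 0 = zero delay); ``"full"`` keeps
        the entire transform, for energy accounting.

    The transform is unitary, so with ``depth="full"`` the total output energy
    equals the energy of the apodized input spectra (Parseval).
    """
    if depth not in ("positive", "full"):
        raise ValueError("depth must be 'positive' or 'full'")
    spectra = _apply_apodization(raw.data, apodization)
    profiles = scipy.fft.ifft(spectra, axis=-1, norm="ortho")
    if depth == "positive":
        profiles = profiles[..., : raw.grid.n_depth]
    # (channel, frame, a_line, z) -> (frame, z, a_line)
    e1 = np.transpose(profiles[0], (0, 2, 1))[np.newaxis]
    e2 = np.transpose(profiles[1], (0, 2, 1))[np.newaxis]
    return JonesField(e1=e1, e2=e2, pixel_pitch_z=raw.grid.pixel_pitch_z,
                      pixel_pitch_x=raw.pixel_pitch_x)


def make_windows(spec: SpectralWindowSpec, grid: KGrid) -> np.ndarray:
    """Evaluate the window bank on the grid -> array ``(n_bands, samples)``.

    Gaussian windows use σ = FWHM/(2√(2 ln 2)); rectangular windows are 1 on
    [k_β − Δk/2, k_β + Δk/2) and 0 outside. Gaussian windows are truncated at
    the grid edge without reshaping; unit-L2 normalization is applied when
    ``normalize_energy`` is set.
    """
    k = grid.k_values
    windows = np.empty((spec.n_bands, grid.samples), dtype=float)
    for b, center in enumerate(spec.centers):
        if not (grid.k_min <= center <= grid.k_max):
            raise ValueError(
                f"band center {center:.4f} rad/µm lies outside the sampled grid "
                f"[{grid.k_min:.4f}, {grid.k_max:.4f}]"
            )
        if spec.shape == "gaussian":
            sigma = spec.fwhm * _FWHM_TO_SIGMA
            if center - 3 * sigma < grid.k_min or center + 3 * sigma > grid.k_max:
                warnings.warn(
                    f"band {b}: Gaussian window extends more than 3σ beyond the grid "
                    "and is truncated", stacklevel=2)
            w = np.exp(-0.5 * ((k - center) / sigma) ** 2)
        else:
            half = 0.5 * spec.fwhm
            tol = 1e-9 * grid.span
            if center - half < grid.k_min - tol or center + half > grid.k_max + tol:
                warnings.warn(
                    f"band {b}: rectangular window extends beyond the grid and is "
                    "truncated", stacklevel=2)
            inside = (k >= center - half) & (k < center + half)
            if center + half >= grid.k_max - tol:
                inside[-1] = True  # topmost sample belongs to the last tile
            w = inside.astype(float)
        if spec.normalize_energy:
            norm = np.sqrt(np.sum(w**2))
            if norm > 0:
                w = w / norm
        windows[b] = w
    return windows


def reconstruct_subbands(
    raw: RawSpectra,
    spec: SpectralWindowSpec,
    depth: str = "positive",
) -> JonesField:
    """Per-sub-band reconstruction E₁,₂^β(z) = FT⁻¹[G(k_β, Δk)·s₁,₂(k)].

    Band b of the output is exactly ``reconstruct`` applied with window b as
    apodization; the band axis has length N_β.
    """
    windows = make_windows(spec, raw.grid)
    bands_e1, bands_e2 = [], []
    for w in windows:
        jf = reconstruct(raw, apodization=w, depth=depth)
        bands_e1.append(jf.e1[0])
        bands_e2.append(jf.e2[0])
    return JonesField(
        e1=np.stack(bands_e1), e2=np.stack(bands_e2),
        pixel_pitch_z=raw.grid.pixel_pitch_z, pixel_pitch_x=raw.pixel_pitch_x,
    )
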