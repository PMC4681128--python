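"""Jones -> Stokes conversion and reflectivity-based validity masking.

From the channel amplitudes A₁,₂ = |e₁,₂| and the phase difference
ΔΦ = arg(e₁·conj(e₂)), the Stokes vector of a pixel is

    [I, Q, U, V] = [A₁² + A₂², A₁² − A₂², 2A₁A₂ cos ΔΦ, 2A₁A₂ sin ΔΦ].

The ΔΦ sign convention (e₁ leading) fixes which circular handedness carries
positive V; it is applied consistently everywhere. A pixel derived from a
single Jones vector is fully polarized: I² = Q² + U² + V².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tomogram import JonesField


@dataclass
class StokesField:
    """I, Q, U, V per pixel, indexed (band, frame, z, x); arbitrary intensity units."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.i, self.q, self.u, self.v)]
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("i, q, u, v must be congruent in shape")
        if arrs[0].ndim != 4:
            raise ValueError("Stokes fields are stored as (band, frame, z, x)")
        self.i, self.q, self.u, self.v = arrs

    @property
    def n_bands(self) -> int:
        return self.i.shape[0]

    @property
    def n_frames(self) -> int:
        return self.i.shape[1]

    @property
    def shape(self) -> tuple:
        return self.i.shape


@dataclass
class ValidityMask:
    """Boolean validity per B-scan pixel, from a reflectivity threshold (dB over noise floor)."""

    mask: np.ndarray
    threshold_db: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D (z, x) array")
        self.mask = m


def jones_to_stokes(field: JonesField) -> StokesField:
    """Per-pixel Stokes vector from the two complex channel amplitudes.

    U and V are evaluated as 2·Re/Im(e₁·conj(e₂)), which is algebraically
    2A₁A₂cosΔΦ / 2A₁A₂sinΔΦ under ΔΦ = arg(e₁·conj(e₂)). A zero-amplitude
    pixel yields the zero vector.
    """
    e1, e2 = field.e1, field.e2
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
        raise ValueError("Jones field contains non-finite values")
    p1 = np.abs(e1) ** 2
    p2 = np.abs(e2) ** 2
    cross = e1 * np.conj(e2)
    return StokesField(i=p1 + p2, q=p1 - p2, u=2.0 * cross.real, v=2.0 * cross.imag)


def normalize_stokes(s: StokesField, valid: np.ndarray | None = None) -> StokesField:
    """Divide q, u, v by i on valid pixels; flag the rest with NaN.

    ``valid`` broadcasts against the field shape; pixels with i <= 0 are always
    invalid (NaN in the output, never a propagated number). On valid pixels the
    output intensity is identically 1, making the call idempotent.
    """
    ok = s.i > 0
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ok, s.q / s.i, np.nan)
        u = np.where(ok, s.u / s.i, np.nan)
        v = np.where(ok, s.v / s.i, np.nan)
    i = np.where(ok, 1.0, np.nan)
    return StokesField(i=i, q=q, u=u, v=v)


def build_mask(intensity: np.ndarray, threshold_db: float = 15.0) -> ValidityMask:
    """Validity mask from a reflectivity B-scan.

    The noise floor is estimated as the median intensity of the deepest 10% of
    pixels (bottom rows of the B-scan, assumed signal-free); a pixel is valid
    where its intensity exceeds the floor by more than ``threshold_db``.
    """
    if threshold_db < 0:
        raise ValueError("threshold_db must be >= 0")
    img = np.asarray(intensity, dtype=float)
    if img.ndim != 2:
        raise ValueError("intensity must be a 2-D (z, x) B-scan")
    nz = img.shape[0]
    tail = max(1, int(np.ceil(0.1 * nz)))
    floor = float(np.median(img[nz - tail:]))
    floor = max(floor, np.finfo(float).tiny)
    mask = img >= floor * 10.0 ** (threshold_db / 10.0)
    if not mask.any():
        warnings.warn("all pixels fall below the reflectivity threshold; mask is empty",
                      stacklevel=2)
    return ValidityMask(mask=mask, threshold_db=float(threshold_db))
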