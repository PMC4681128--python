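"""Reporting helpers: DOPU histograms, depth profiles, Poincaré-sphere points."""

from __future__ import annotations

import warnings

import numpy as np

from .dopu import DopuMap
from .polarimetry import StokesField


def dopu_histogram(
    dmap: DopuMap,
    region: tuple[int, int, int, int] | None = None,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of valid DOPU values in a rectangular ROI.

    ``region`` is (z0, z1, x0, x1) in pixels (half-open); ``None`` uses the
    whole map. Edges are uniform on [0, 1]; counts cover valid pixels only and
    sum to their number.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    nz, nx = dmap.values.shape
    if region is None:
        region = (0, nz, 0, nx)
    z0, z1, x0, x1 = region
    if not (0 <= z0 < z1 <= nz and 0 <= x0 < x1 <= nx):
        raise ValueError("ROI must lie within the image")
    roi = dmap.values[z0:z1, x0:x1]
    vals = roi[np.isfinite(roi)]
    edges = np.linspace(0.0, 1.0, bins + 1)
    if vals.size == 0:
        warnings.warn("ROI contains no valid pixels; histogram is empty", stacklevel=2)
        return np.zeros(bins, dtype=int), edges
    counts, _ = np.histogram(np.clip(vals, 0.0, 1.0), bins=edges)
    return counts, edges


def depth_profile(
    dmap: DopuMap,
    a_line: int,
    width: int = 1,
) -> np.ndarray:
    """Per-depth mean of valid DOPU values in a lateral window around an A-line.

    The window spans ``width`` columns centered on ``a_line`` (truncated at the
    image border); depths with no valid pixel are NaN.
    """
    nz, nx = dmap.values.shape
    if not 0 <= a_line < nx:
        raise ValueError("a_line index out of range")
    if width < 1:
        raise ValueError("width must be >= 1")
    x0 = max(0, a_line - (width - 1) // 2)
    x1 = min(nx, a_line + width // 2 + 1)
    block = dmap.values[:, x0:x1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(block, axis=1)


def poincare_points(
    s: StokesField,
    pixel: tuple[int, int],
    frame: int = 0,
    intensity_floor: float = 1e-12,
) -> np.ndarray:
    """Per-band normalized (q, u, v) unit vectors at one pixel.

    Bands whose intensity is at or below ``intensity_floor`` × the pixel's peak
    band intensity are dropped. Returns an (n, 3) array; empty with a warning
    if every band is dark.
    """
    z, x = pixel
    i = s.i[:, frame, z, x]
    peak = i.max() if i.size else 0.0
    keep = i > intensity_floor * max(peak, np.finfo(float).tiny)
    if not keep.any():
        warnings.warn("pixel has no band with usable intensity", stacklevel=2)
        return np.empty((0, 3))
    qv = np.stack([s.q[:, frame, z, x], s.u[:, frame, z, x],
                   s.v[:, frame, z, x]], axis=1)[keep]
    pts = qv / i[keep, None]
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return pts / norms
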