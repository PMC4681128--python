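"""The three depolarization estimators: spatial, temporal and spectral DOPU.

The degree of polarization uniformity (DOPU) is the length of the average of
normalized Stokes vectors over an evaluation ensemble: 1 for a single pixel or
any set of parallel states, lower where polarization states decorrelate within
the ensemble. The three estimators differ only in what the ensemble is:

* spatial  — a kernel_x × kernel_z neighborhood within one B-scan,
* temporal — the same pixel across motion-registered repeated frames,
* spectral — the spectral sub-bands of one pixel (sDOPU). Following its
  definition, sDOPU averages the *unnormalized* band Stokes parameters and
  divides by the averaged intensity: √(⟨Q⟩²+⟨U⟩²+⟨V⟩²)/⟨I⟩; a flag switches
  to normalized-band averaging for sensitivity studies.

Masked (low-reflectivity) pixels are excluded from averages rather than
zero-filled — the divisor is always the count of contributing valid pixels —
and kernels truncate at image borders so no fabricated states enter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage
from scipy import stats

from .polarimetry import StokesField, ValidityMask, build_mask, jones_to_stokes
from .tomogram import RawSpectra, SpectralWindowSpec, make_windows, preprocess_spectra, \
    reconstruct, reconstruct_subbands

_INVALID = np.nan


@dataclass
class DopuMap:
    """B-scan-shaped DOPU values in [0, 1]; invalid pixels carry NaN, never a number."""

    values: np.ndarray
    mask: ValidityMask
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("DOPU map must be 2-D (z, x)")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("valid DOPU values must lie in [0, 1]")
        self.values = v

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ShiftSeries:
    """Per-frame integer (dz, dx) displacements relative to the first frame."""

    shifts: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.shifts, dtype=int)
        if s.ndim != 2 or s.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")
        if tuple(s[0]) != (0, 0):
            raise ValueError("reference frame shift must be (0, 0)")
        self.shifts = s

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _single_bscan(s: StokesField) -> tuple[np.ndarray, ...]:
    if s.n_bands != 1 or s.n_frames != 1:
        raise ValueError("expected a single-band, single-frame Stokes field; "
                         "select the band/frame first")
    return s.i[0, 0], s.q[0, 0], s.u[0, 0], s.v[0, 0]


def _normalized_components(i, q, u, v, valid):
    """Per-pixel normalized (q, u, v), zero-filled at invalid pixels, plus validity."""
    ok = valid & (i > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nq = np.where(ok, q / i, 0.0)
        nu = np.where(ok, u / i, 0.0)
        nv = np.where(ok, v / i, 0.0)
    return nq, nu, nv, ok


def _window_sums(arr: np.ndarray, kernel_z: int, kernel_x: int) -> np.ndarray:
    """Sums over centered kernel_z × kernel_x windows, truncated at borders.

    The window at pixel (z, x) spans rows z−(kz−1)//2 … z+kz//2 and columns
    x−(kx−1)//2 … x+kx//2 (inclusive), clipped to the image.
    """
    nz, nx = arr.shape
    ii = np.zeros((nz + 1, nx + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    z = np.arange(nz)
    x = np.arange(nx)
    z0 = np.clip(z - (kernel_z - 1) // 2, 0, nz)
    z1 = np.clip(z + kernel_z // 2 + 1, 0, nz)
    x0 = np.clip(x - (kernel_x - 1) // 2, 0, nx)
    x1 = np.clip(x + kernel_x // 2 + 1, 0, nx)
    return (ii[np.ix_(z1, x1)] - ii[np.ix_(z0, x1)]
            - ii[np.ix_(z1, x0)] + ii[np.ix_(z0, x0)])


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def spatial_dopu(
    s: StokesField,
    kernel_x: int,
    kernel_z: int,
    mask: ValidityMask,
) -> DopuMap:
    """Spatial DOPU over a centered ``kernel_x × kernel_z`` window.

    Per valid pixel, the per-pixel-normalized (q, u, v) vectors of the valid
    pixels inside the window are averaged and the Euclidean norm of the mean is
    returned. Windows truncate at image borders; a pixel whose window holds
    fewer than two valid pixels keeps its single-pixel value, 1.
    """
    i, q, u, v = _single_bscan(s)
    nz, nx = i.shape
    if kernel_x < 1 or kernel_z < 1:
        raise ValueError("kernel dimensions must be >= 1")
    if kernel_z > nz or kernel_x > nx:
        raise ValueError("kernel must not exceed the B-scan size")
    nq, nu, nv, ok = _normalized_components(i, q, u, v, mask.mask)
    count = _window_sums(ok.astype(float), kernel_z, kernel_x)
    with np.errstate(divide="ignore", invalid="ignore"):
        mq = _window_sums(nq, kernel_z, kernel_x) / count
        mu = _window_sums(nu, kernel_z, kernel_x) / count
        mv = _window_sums(nv, kernel_z, kernel_x) / count
    values = np.sqrt(mq**2 + mu**2 + mv**2)
    values[count < 2] = 1.0  # single-pixel fallback: DOP of one state
    values[~ok] = _INVALID
    return DopuMap(values=values, mask=mask, method="spatial",
                   params={"kernel_x": kernel_x, "kernel_z": kernel_z})


def register_frames(intensity: np.ndarray) -> ShiftSeries:
    """Integer (dz, dx) shift of each frame against the first, by cross-correlation.

    Correlation is computed on mean-subtracted log-intensity via FFT (circular).
    Ties at the correlation maximum are broken toward the smaller displacement
    magnitude, then lexicographically. A zero-variance frame gets shift (0, 0)
    with a warning.
    """
    frames = np.asarray(intensity, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frame, z, x) stack with >= 2 frames")
    nf, nz, nx = frames.shape

    def prep(img):
        eps = max(img.max(), 0.0) * 1e-9 + np.finfo(float).tiny
        g = np.log10(img + eps)
        return g - g.mean()

    ref = prep(frames[0])
    ref_f = scipy.fft.fft2(ref)
    shifts = np.zeros((nf, 2), dtype=int)
    half_z, half_x = nz // 2, nx // 2
    for f in range(1, nf):
        cur = prep(frames[f])
        if not cur.any():
            warnings.warn(f"frame {f} has zero variance; assuming no displacement",
                          stacklevel=2)
            continue
        corr = scipy.fft.ifft2(scipy.fft.fft2(cur) * np.conj(ref_f)).real
        peak = corr.max()
        cand = np.argwhere(corr == peak)
        dz = np.where(cand[:, 0] > half_z, cand[:, 0] - nz, cand[:, 0])
        dx = np.where(cand[:, 1] > half_x, cand[:, 1] - nx, cand[:, 1])
        order = np.lexsort((dx, dz, dz**2 + dx**2))
        shifts[f] = dz[order[0]], dx[order[0]]
    return ShiftSeries(shifts=shifts)


def _frame_masks(masks, n_frames: int, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(masks, ValidityMask):
        return np.broadcast_to(masks.mask, (n_frames, *shape)).copy()
    m = np.asarray(masks, dtype=bool)
    if m.shape == shape:
        return np.broadcast_to(m, (n_frames, *shape)).copy()
    if m.shape != (n_frames, *shape):
        raise ValueError("masks must match the frame stack shape")
    return m.copy()


def temporal_dopu(
    s: StokesField,
    shifts: ShiftSeries,
    masks: ValidityMask | np.ndarray,
) -> DopuMap:
    """Temporal DOPU: per-pixel average of normalized Stokes vectors across frames.

    Frames (and their masks) are aligned to the first frame by the integer
    shifts before averaging; only frames in which the aligned pixel is valid
    contribute, and a pixel valid in fewer than two frames is flagged invalid.
    """
    if s.n_bands != 1:
        raise ValueError("temporal DOPU expects a single-band Stokes field")
    if s.n_frames != shifts.n_frames:
        raise ValueError("frame count of the Stokes field and the shift series differ")
    if s.n_frames < 2:
        raise ValueError("temporal DOPU needs >= 2 frames")
    i, q, u, v = s.i[0], s.q[0], s.u[0], s.v[0]
    nf, nz, nx = i.shape
    mstack = _frame_masks(masks, nf, (nz, nx))
    sq = np.zeros((nz, nx))
    su = np.zeros((nz, nx))
    sv = np.zeros((nz, nx))
    count = np.zeros((nz, nx))
    for f in range(nf):
        roll = (-int(shifts.shifts[f, 0]), -int(shifts.shifts[f, 1]))
        nq, nu, nv, ok = _normalized_components(
            np.roll(i[f], roll, axis=(0, 1)), np.roll(q[f], roll, axis=(0, 1)),
            np.roll(u[f], roll, axis=(0, 1)), np.roll(v[f], roll, axis=(0, 1)),
            np.roll(mstack[f], roll, axis=(0, 1)))
        sq += nq
        su += nu
        sv += nv
        count += ok
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.sqrt(sq**2 + su**2 + sv**2) / count
    values[count < 2] = _INVALID
    out_mask = ValidityMask(mask=count >= 2, threshold_db=getattr(masks, "threshold_db",
                                                                  np.nan))
    return DopuMap(values=values, mask=out_mask, method="temporal",
                   params={"n_frames": nf})


def spectral_dopu(
    s: StokesField,
    mask: ValidityMask,
    normalize_bands: bool = False,
) -> DopuMap:
    """Spectral DOPU (sDOPU) across the band axis of one frame.

    Default follows the definition literally: unweighted means of the
    unnormalized band Stokes parameters, √(⟨Q⟩²+⟨U⟩²+⟨V⟩²)/⟨I⟩. With
    ``normalize_bands`` the per-band vectors are intensity-normalized before
    averaging (norm of the mean, no intensity division).
    """
    if s.n_frames != 1:
        raise ValueError("spectral DOPU expects a single-frame Stokes field; "
                         "select the frame first")
    i, q, u, v = s.i[:, 0], s.q[:, 0], s.u[:, 0], s.v[:, 0]
    if normalize_bands:
        nq, nu, nv, ok = _normalized_components(i, q, u, v, np.ones_like(i, dtype=bool))
        count = ok.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.sqrt(nq.sum(axis=0) ** 2 + nu.sum(axis=0) ** 2
                             + nv.sum(axis=0) ** 2) / count
        invalid = count == 0
    else:
        im = i.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.sqrt(q.mean(axis=0) ** 2 + u.mean(axis=0) ** 2
                             + v.mean(axis=0) ** 2) / im
        invalid = im <= 0
    values[invalid | ~mask.mask] = _INVALID
    return DopuMap(values=values, mask=mask, method="spectral",
                   params={"n_bands": s.n_bands, "normalize_bands": normalize_bands})


# ---------------------------------------------------------------------------
# spectral-window <-> axial-kernel equivalence
# ---------------------------------------------------------------------------

def axial_kernel_from_window(window: np.ndarray, truncate: float = 0.01) -> np.ndarray:
    """Depth-domain kernel profile g: transform magnitude of a spectral window.

    The profile is sampled at the depth-pixel spacing, entries below
    ``truncate`` × peak are zeroed, leading/trailing zeros trimmed, and the
    result normalized to unit sum. The returned length is odd (center pixel =
    kernel origin).
    """
    g = np.abs(scipy.fft.ifft(np.asarray(window, dtype=float)))
    g = scipy.fft.fftshift(g)
    g[g < truncate * g.max()] = 0.0
    nz = np.nonzero(g)[0]
    center = g.size // 2
    half = max(center - nz[0], nz[-1] - center)
    lo, hi = center - half, center + half + 1
    lo = max(lo, 0)
    hi = min(hi, g.size)
    prof = g[lo:hi]
    if prof.size % 2 == 0:  # keep an unambiguous center pixel
        prof = np.append(prof, 0.0)
    return prof / prof.sum()


def weighted_axial_dopu(
    s: StokesField,
    profile: np.ndarray,
    mask: ValidityMask,
    normalize: bool = True,
) -> DopuMap:
    """DOPU with a 1 (x) × g (z) weighted axial kernel.

    With ``normalize`` (default) the per-pixel-normalized vectors are averaged
    with weights g along depth (the package's spatial-DOPU reading); otherwise
    the raw Stokes parameters are g-averaged and divided by the g-averaged
    intensity, the direct axial counterpart of the sub-band average.
    """
    i, q, u, v = _single_bscan(s)
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 1 or prof.size % 2 != 1:
        raise ValueError("kernel profile must be 1-D with odd length")

    def conv_z(arr):
        # centered, border-truncated weighted sum along z
        return scipy.ndimage.correlate1d(arr, prof, axis=0, mode="constant", cval=0.0)

    if normalize:
        nq, nu, nv, ok = _normalized_components(i, q, u, v, mask.mask)
        wsum = conv_z(ok.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.sqrt(conv_z(nq) ** 2 + conv_z(nu) ** 2 + conv_z(nv) ** 2) / wsum
        values[wsum <= 0] = _INVALID
        values[~ok] = _INVALID
    else:
        ok = mask.mask & (i > 0)
        zi = np.where(ok, i, 0.0)
        wi = conv_z(zi)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.sqrt(conv_z(np.where(ok, q, 0.0)) ** 2
                             + conv_z(np.where(ok, u, 0.0)) ** 2
                             + conv_z(np.where(ok, v, 0.0)) ** 2) / wi
        values[(wi <= 0) | ~ok] = _INVALID
    np.clip(values, 0.0, 1.0, out=values)
    return DopuMap(values=values, mask=mask, method="spatial",
                   params={"kernel": "1xg", "g_length": prof.size,
                           "normalize": normalize})


def kernel_equivalence_check(
    raw: RawSpectra,
    spec: SpectralWindowSpec,
    threshold_db: float = 15.0,
) -> dict:
    """Compare sDOPU against spatial DOPU with the transform-equivalent 1×g kernel.

    With many narrow windows tiling the band, averaging Stokes parameters over
    sub-bands corresponds to an axial average under the kernel g, the depth-
    domain transform of the window shape; sDOPU then approximates DOPU with a
    1 (x) × g (z) kernel. Because that correspondence is between *unnormalized*
    Stokes averages (the convention the spectral estimator itself uses), the
    primary comparison map averages raw Stokes parameters under g and divides
    by the g-averaged intensity; the normalized-averaging variant is reported
    alongside. Returns both maps plus per-pixel absolute-difference statistics
    and the Spearman rank correlation on jointly valid pixels.
    """
    pre = preprocess_spectra(raw)
    full = reconstruct(pre)
    stokes_full = jones_to_stokes(full)
    mask = build_mask(full.intensity()[0, 0], threshold_db=threshold_db)

    bands = reconstruct_subbands(pre, spec)
    sdopu = spectral_dopu(jones_to_stokes(bands), mask)

    windows = make_windows(spec, raw.grid)
    profile = axial_kernel_from_window(windows[spec.n_bands // 2])
    axial = weighted_axial_dopu(stokes_full, profile, mask, normalize=False)
    axial_norm = weighted_axial_dopu(stokes_full, profile, mask, normalize=True)

    both = sdopu.valid & axial.valid
    diff = np.abs(sdopu.values[both] - axial.values[both])
    if both.sum() >= 2:
        rho = float(stats.spearmanr(sdopu.values[both], axial.values[both]).statistic)
        rho_norm = float(stats.spearmanr(sdopu.values[both],
                                         axial_norm.values[both]).statistic)
    else:
        rho = rho_norm = np.nan
    return {
        "sdopu": sdopu,
        "axial": axial,
        "axial_normalized": axial_norm,
        "kernel_profile": profile,
        "n_valid": int(both.sum()),
        "mean_abs_diff": float(diff.mean()) if diff.size else np.nan,
        "median_abs_diff": float(np.median(diff)) if diff.size else np.nan,
        "max_abs_diff": float(diff.max()) if diff.size else np.nan,
        "spearman_rho": rho,
        "spearman_rho_normalized": rho_norm,
    }
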