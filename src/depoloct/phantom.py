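"""Coherent-speckle phantom: synthetic two-channel PS-OCT interferograms.

The phantom realizes the Fourier-domain PS-OCT signal model: each A-line's
spectral interferogram is a sum over discrete scatterers,

    s₁,₂(k) = Σ_j a_j √S(k) · Re{ e₁,₂ⱼ(k) · exp(−i(2 k z_j + φ_j)) },

with a Gaussian source spectrum S(k), per-scatterer complex polarization
weights e₁,₂ⱼ(k), random scattering phases φ_j (coherent speckle), additive
Gaussian detection noise, and a small Gaussian lateral PSF coupling scatterers
into neighboring A-lines (lateral speckle correlation).

Depolarization is modelled at the scatterer level, the mechanism attributed to
granule-scale scattering in pigmented tissue, with one knob per flavor:

* ``depol_index`` δ ∈ [0,1] — each scatterer's polarization direction is the
  circular illumination state mixed with an isotropic random direction,
  d = normalize((1−δ)·s₀ + δ·u): δ=0 leaves every scatterer in one state,
  δ=1 scatters states uniformly over the Poincaré sphere (spatial scrambling);
* ``spectral_decorr`` χ ≥ 0 — a per-scatterer k-linear retardance with slope
  drawn from N(0, χ) rad per grid span rotates the state across the spectrum
  (wavelength-dependent scrambling, what the spectral estimator probes);
* ``frame_decorr`` τ ∈ [0,1] — the fraction of each layer's scatterers redrawn
  per frame (temporal scrambling, standing in for out-of-plane motion).

A per-frame rigid (dz, dx) drift program emulates axial/transverse bulk motion
for the frame-registration path. All randomness flows from one seed through
named substreams, so identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import KGrid
from .polarimetry import jones_to_stokes
from .tomogram import RawSpectra, reconstruct

_CIRCULAR_STATE = np.array([0.0, 0.0, 1.0])  # circular illumination on the Poincaré sphere


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous depth layer of the phantom.

    ``z_range`` is the depth interval in µm; ``scatterer_density`` the expected
    scatterer count per A-line within the layer; ``reflectivity`` the mean
    backscattered energy per scatterer (arbitrary units).
    """

    z_range: tuple[float, float]
    scatterer_density: float
    reflectivity: float = 1.0
    depol_index: float = 0.0
    spectral_decorr: float = 0.0
    frame_decorr: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        z0, z1 = self.z_range
        if not z1 > z0 >= 0:
            raise ValueError("z_range must satisfy 0 <= z0 < z1")
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be >= 0")
        if not 0.0 <= self.depol_index <= 1.0:
            raise ValueError("depol_index must lie in [0, 1]")
        if not 0.0 <= self.frame_decorr <= 1.0:
            raise ValueError("frame_decorr must lie in [0, 1]")
        if self.spectral_decorr < 0:
            raise ValueError("spectral_decorr must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; identical spec + seed reproduces bit-identical data."""

    grid: KGrid
    a_lines: int
    layers: tuple[LayerSpec, ...]
    frames: int = 1
    reference_level: float = 1.0
    noise_sigma: float = 0.0
    drift_um: np.ndarray | None = None  # (frames, 2) per-frame (dz, dx), µm
    seed: int = 0
    lateral_psf_sigma: float = 1.5  # A-lines
    pixel_pitch_x: float = 6.0  # µm per A-line

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.a_lines < 4 or self.frames < 1:
            raise ValueError("need >= 4 A-lines and >= 1 frame")
        spans = sorted(l.z_range for l in self.layers)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("layers must not overlap in depth")
        zmax = self.grid.max_depth
        for l in self.layers:
            if l.z_range[1] > zmax:
                raise ValueError(
                    f"layer '{l.name}' extends to {l.z_range[1]:.1f} µm, beyond the "
                    f"unambiguous depth {zmax:.1f} µm")
        if self.drift_um is not None:
            d = np.asarray(self.drift_um, dtype=float)
            if d.shape != (self.frames, 2):
                raise ValueError("drift_um must have shape (frames, 2)")
            object.__setattr__(self, "drift_um", d)

    @property
    def width_um(self) -> float:
        return self.a_lines * self.pixel_pitch_x

    def drift(self) -> np.ndarray:
        if self.drift_um is None:
            return np.zeros((self.frames, 2))
        return self.drift_um


@dataclass
class Scatterers:
    """Flat arrays describing one frame's scatterer realization."""

    z_um: np.ndarray
    x_um: np.ndarray
    amplitude: np.ndarray
    direction: np.ndarray  # (n, 3) unit Poincaré-sphere direction
    ret_slope: np.ndarray  # rad per grid span
    phase: np.ndarray
    layer: np.ndarray
    home: np.ndarray  # A-line index the scatterer was drawn for

    @property
    def n(self) -> int:
        return self.z_um.size

    def jones(self) -> np.ndarray:
        """(n, 2) complex Jones vectors for the unit Poincaré directions."""
        q, u, v = self.direction.T
        a1 = np.sqrt((1.0 + q) / 2.0)
        a2 = np.sqrt(np.clip((1.0 - q) / 2.0, 0.0, None))
        dphi = np.arctan2(v, u)
        return np.stack([a1.astype(complex), a2 * np.exp(-1j * dphi)], axis=1)


@dataclass
class GroundTruth:
    """Programmed truth for validating masks, labels and registration."""

    labels: np.ndarray  # (z, x) layer index, -1 = background
    occupancy: np.ndarray  # (z, x) bool, where backscattered signal truly lives
    shifts_px: np.ndarray  # (frames, 2) programmed integer (dz, dx) pixels
    drift_um: np.ndarray
    layers: tuple[LayerSpec, ...]


# ---------------------------------------------------------------------------
# random draws
# ---------------------------------------------------------------------------

def _stream(spec: PhantomSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=tuple(key)))


def _draw_layer(spec: PhantomSpec, layer_idx: int, rng: np.random.Generator,
                n: int | None = None, homes: np.ndarray | None = None) -> Scatterers:
    layer = spec.layers[layer_idx]
    if homes is None:
        counts = rng.poisson(layer.scatterer_density, size=spec.a_lines)
        homes = np.repeat(np.arange(spec.a_lines), counts)
    n = homes.size
    z = rng.uniform(layer.z_range[0], layer.z_range[1], n)
    x = (homes + rng.uniform(-0.5, 0.5, n)) * spec.pixel_pitch_x
    amplitude = np.sqrt(layer.reflectivity) * rng.rayleigh(scale=1.0 / np.sqrt(2.0), size=n)
    # isotropic directions on the sphere, mixed with the circular input state
    raw = rng.normal(size=(n, 3))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    mix = (1.0 - layer.depol_index) * _CIRCULAR_STATE + layer.depol_index * raw
    norm = np.linalg.norm(mix, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    direction = mix / norm
    # unit normal scaled by chi: the same seed yields the same speckle
    # realization at every decorrelation level (common random numbers)
    slope = rng.normal(0.0, 1.0, n) * layer.spectral_decorr
    phase = rng.uniform(0.0, 2.0 * np.pi, n)
    return Scatterers(z_um=z, x_um=x, amplitude=amplitude, direction=direction,
                      ret_slope=slope, phase=phase,
                      layer=np.full(n, layer_idx, dtype=int), home=homes)


def _concat(parts: list[Scatterers]) -> Scatterers:
    return Scatterers(*[np.concatenate([getattr(p, f.name) for p in parts])
                        for f in dataclasses.fields(Scatterers)])


def sample_scatterers(spec: PhantomSpec) -> Scatterers:
    """Frame-0 scatterer realization: Poisson counts per A-line per layer."""
    parts = [_draw_layer(spec, li, _stream(spec, 0, li))
             for li in range(len(spec.layers))]
    if not parts:
        return Scatterers(z_um=np.empty(0), x_um=np.empty(0), amplitude=np.empty(0),
                          direction=np.empty((0, 3)), ret_slope=np.empty(0),
                          phase=np.empty(0), layer=np.empty(0, dtype=int),
                          home=np.empty(0, dtype=int))
    return _concat(parts)


def _evolve(spec: PhantomSpec, scat: Scatterers, frame: int) -> Scatterers:
    """Redraw fraction τ of each layer's scatterers for the given frame."""
    out = Scatterers(*[np.copy(getattr(scat, f.name))
                       for f in dataclasses.fields(Scatterers)])
    for li, layer in enumerate(spec.layers):
        if layer.frame_decorr <= 0:
            continue
        rng = _stream(spec, 1, li, frame)
        members = np.nonzero(out.layer == li)[0]
        redraw = members[rng.random(members.size) < layer.frame_decorr]
        if redraw.size == 0:
            continue
        fresh = _draw_layer(spec, li, rng, homes=out.home[redraw])
        for f in ("z_um", "x_um", "amplitude", "direction", "ret_slope", "phase"):
            getattr(out, f)[redraw] = getattr(fresh, f)
    return out


# ---------------------------------------------------------------------------
# interferogram synthesis
# ---------------------------------------------------------------------------

def _lateral_weights(spec: PhantomSpec, x_um: np.ndarray) -> np.ndarray:
    """(a_lines, n) Gaussian lateral PSF weights with periodic wrap in x."""
    sigma = spec.lateral_psf_sigma * spec.pixel_pitch_x
    width = spec.width_um
    grid_x = (np.arange(spec.a_lines) + 0.5) * spec.pixel_pitch_x
    d = grid_x[:, None] - x_um[None, :]
    d = (d + width / 2.0) % width - width / 2.0  # periodic distance
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w[np.abs(d) > 4.0 * sigma] = 0.0
    return w


def _frame_interferogram(spec: PhantomSpec, scat: Scatterers,
                         drift: np.ndarray) -> np.ndarray:
    """(2, a_lines, k) real interferograms for one frame's scatterer set."""
    grid = spec.grid
    k = grid.k_values
    z = scat.z_um + drift[0]
    x = (scat.x_um + drift[1]) % spec.width_um
    if np.any(z < 0) or np.any(z >= grid.max_depth):
        bad = np.nonzero((z < 0) | (z >= grid.max_depth))[0]
        raise ValueError(
            f"{bad.size} scatterer(s) beyond the unambiguous depth range "
            f"[0, {grid.max_depth:.1f}) µm after drift; first offender at "
            f"z = {z[bad[0]]:.1f} µm")
    out = np.zeros((2, spec.a_lines, grid.samples))
    if scat.n == 0:
        return out
    sqrt_s = np.sqrt(grid.source_spectrum())
    carrier = np.exp(-1j * (2.0 * np.outer(z, k) + scat.phase[:, None]))
    common = (scat.amplitude[:, None] * sqrt_s[None, :]) * carrier
    jones = scat.jones()
    knorm = (k - grid.center_k) / grid.span
    ret = np.exp(0.5j * np.outer(scat.ret_slope, knorm))
    w = _lateral_weights(spec, x) * np.sqrt(spec.reference_level)
    out[0] = (w @ (common * ret * jones[:, 0:1])).real
    out[1] = (w @ (common / ret * jones[:, 1:2])).real
    return out


def _ground_truth(spec: PhantomSpec, scat: Scatterers) -> GroundTruth:
    grid = spec.grid
    nz, nx = grid.n_depth, spec.a_lines
    pitch_z = grid.pixel_pitch_z
    labels = np.full((nz, nx), -1, dtype=int)
    z_centers = (np.arange(nz) + 0.5) * pitch_z
    for li, layer in enumerate(spec.layers):
        rows = (z_centers >= layer.z_range[0]) & (z_centers < layer.z_range[1])
        labels[rows, :] = li
    # energy splat of the programmed scatterers under the axial/lateral PSFs
    sigma_k = grid.source_fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_idx = sigma_k * np.sqrt(2.0) / grid.dk  # amplitude-spectrum width, samples
    sigma_z_px = max(grid.samples / (2.0 * np.pi * sigma_idx), 0.5)
    sigma_x_px = spec.lateral_psf_sigma
    splat = np.zeros((nz, nx))
    z_px = scat.z_um / pitch_z
    x_px = scat.x_um / spec.pixel_pitch_x - 0.5
    rz = int(np.ceil(4 * sigma_z_px))
    rx = int(np.ceil(4 * sigma_x_px))
    for j in range(scat.n):
        zc, xc = z_px[j], x_px[j]
        z0, z1 = max(0, int(zc) - rz), min(nz, int(zc) + rz + 1)
        xs = (np.arange(int(xc) - rx, int(xc) + rx + 1)) % nx
        zz = np.arange(z0, z1)
        gz = np.exp(-0.5 * ((zz - zc) / sigma_z_px) ** 2)
        dx = np.arange(int(xc) - rx, int(xc) + rx + 1) - xc
        gx = np.exp(-0.5 * (dx / sigma_x_px) ** 2)
        np.add.at(splat, (zz[:, None], xs[None, :]),
                  scat.amplitude[j] ** 2 * np.outer(gz, gx))
    # support = pixels whose programmed backscatter energy lies within 20 dB of
    # the phantom peak (the displayable dynamic range of the emulated system)
    occupancy = splat > 1e-2 * splat.max() if splat.max() > 0 else splat > 0
    drift = spec.drift()
    shifts_px = np.stack([np.round(drift[:, 0] / pitch_z),
                          np.round(drift[:, 1] / spec.pixel_pitch_x)],
                         axis=1).astype(int)
    return GroundTruth(labels=labels, occupancy=occupancy, shifts_px=shifts_px,
                       drift_um=drift, layers=spec.layers)


def synthesize(spec: PhantomSpec) -> tuple[RawSpectra, GroundTruth]:
    """Generate the full raw-spectra stack plus ground truth for the spec."""
    scat0 = sample_scatterers(spec)
    drift = spec.drift()
    data = np.empty((2, spec.frames, spec.a_lines, spec.grid.samples))
    scat = scat0
    for f in range(spec.frames):
        if f > 0:
            scat = _evolve(spec, scat, f)
        frame = _frame_interferogram(spec, scat, drift[f])
        if spec.noise_sigma > 0:
            frame = frame + _stream(spec, 2, f).normal(
                0.0, spec.noise_sigma, frame.shape)
        data[:, f] = frame
    raw = RawSpectra(data=data, grid=spec.grid,
                     meta={"pixel_pitch_x_um": spec.pixel_pitch_x,
                           "phantom_seed": spec.seed})
    return raw, _ground_truth(spec, scat0)


def synthesize_from_scatterers(spec: PhantomSpec, scat: Scatterers) -> RawSpectra:
    """Single-frame interferograms for an explicitly constructed scatterer set."""
    frame = _frame_interferogram(spec, scat, np.zeros(2))
    if spec.noise_sigma > 0:
        frame = frame + _stream(spec, 2, 0).normal(0.0, spec.noise_sigma, frame.shape)
    return RawSpectra(data=frame[:, None], grid=spec.grid,
                      meta={"pixel_pitch_x_um": spec.pixel_pitch_x})


# ---------------------------------------------------------------------------
# SNR calibration and presets
# ---------------------------------------------------------------------------

def noise_sigma_for_snr(spec: PhantomSpec, snr_db: float) -> float:
    """Spectral-noise sigma giving the requested single-pixel SNR.

    One noiseless frame is synthesized and reconstructed; the median
    reconstructed intensity over truly occupied pixels defines the signal
    level, and with the unitary transform the per-depth-pixel noise intensity
    equals the spectral noise variance, so σ = √(I_med · 10^(−SNR/10)).
    """
    quiet = dataclasses.replace(spec, noise_sigma=0.0, frames=1, drift_um=None)
    raw, truth = synthesize(quiet)
    intensity = jones_to_stokes(reconstruct(raw)).i[0, 0]
    if not truth.occupancy.any():
        return 0.0
    med = float(np.median(intensity[truth.occupancy]))
    return float(np.sqrt(med * 10.0 ** (-snr_db / 10.0)))


def with_snr(spec: PhantomSpec, snr_db: float) -> PhantomSpec:
    """Copy of ``spec`` with ``noise_sigma`` set for the requested SNR."""
    return dataclasses.replace(spec, noise_sigma=noise_sigma_for_snr(spec, snr_db))


def two_layer(
    seed: int = 0,
    samples: int = 512,
    a_lines: int = 96,
    frames: int = 1,
    delta: float = 0.8,
    chi: float = 6.0,
    tau: float = 0.0,
    density: float = 15.0,
    snr_db: float = 30.0,
    contiguous: bool = False,
    drift_px: np.ndarray | None = None,
) -> PhantomSpec:
    """Canonical test phantom: a polarization-preserving layer over a depolarizing one.

    The preserving layer has δ = χ = 0; the depolarizing layer's δ/χ/τ are the
    arguments. ``contiguous`` removes the gap between the layers (sharp
    boundary for depth-profile checks). ``drift_px`` programs per-frame rigid
    motion in integer (dz, dx) pixels.
    """
    grid = KGrid.from_source(samples=samples)
    top = (60.0, 220.0) if contiguous else (60.0, 160.0)
    layers = (
        LayerSpec(z_range=top, scatterer_density=density, reflectivity=1.0,
                  name="preserving"),
        LayerSpec(z_range=(220.0, 380.0), scatterer_density=density, reflectivity=1.0,
                  depol_index=delta, spectral_decorr=chi, frame_decorr=tau,
                  name="depolarizing"),
    )
    drift_um = None
    if drift_px is not None:
        drift_px = np.asarray(drift_px, dtype=float)
        drift_um = np.stack([drift_px[:, 0] * grid.pixel_pitch_z,
                             drift_px[:, 1] * 6.0], axis=1)
    spec = PhantomSpec(grid=grid, a_lines=a_lines, frames=frames, layers=layers,
                       drift_um=drift_um, seed=seed)
    return with_snr(spec, snr_db) if snr_db is not None else spec


def retina_like(seed: int = 0, samples: int = 512, a_lines: int = 128,
                frames: int = 1, snr_db: float = 30.0) -> PhantomSpec:
    """Preserving neural-retina-like stack over a thin strongly depolarizing band."""
    grid = KGrid.from_source(samples=samples)
    layers = (
        LayerSpec(z_range=(50.0, 230.0), scatterer_density=15.0, reflectivity=1.0,
                  depol_index=0.05, spectral_decorr=0.5, name="neural"),
        LayerSpec(z_range=(240.0, 280.0), scatterer_density=20.0, reflectivity=2.0,
                  depol_index=0.95, spectral_decorr=8.0, name="rpe"),
    )
    spec = PhantomSpec(grid=grid, a_lines=a_lines, frames=frames, layers=layers,
                       seed=seed)
    return with_snr(spec, snr_db)


def iris_like(seed: int = 0, samples: int = 512, a_lines: int = 128,
              frames: int = 1, snr_db: float = 30.0) -> PhantomSpec:
    """Thin preserving surface over a thick depolarizing pigmented bulk."""
    grid = KGrid.from_source(samples=samples)
    layers = (
        LayerSpec(z_range=(40.0, 70.0), scatterer_density=15.0, reflectivity=1.5,
                  name="surface"),
        LayerSpec(z_range=(70.0, 340.0), scatterer_density=15.0, reflectivity=1.0,
                  depol_index=0.9, spectral_decorr=6.0, frame_decorr=0.3,
                  name="bulk"),
    )
    spec = PhantomSpec(grid=grid, a_lines=a_lines, frames=frames, layers=layers,
                       seed=seed)
    return with_snr(spec, snr_db)


PRESETS = {"two-layer": two_layer, "retina-like": retina_like, "iris-like": iris_like}
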