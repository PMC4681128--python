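import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import depoloct as d

settings.register_profile(
    "repeatable",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


class TwoLayerProducts:
    """Seed-0 default two-layer phantom, reconstructed once per session."""

    def __init__(self) -> None:
        self.spec = d.two_layer(seed=0)
        self.raw, self.truth = d.synthesize(self.spec)
        self.pre = d.preprocess_spectra(self.raw)
        self.full = d.reconstruct(self.pre)
        self.stokes = d.jones_to_stokes(self.full)
        self.mask = d.build_mask(self.stokes.i[0, 0])
        self.band_spec = d.SpectralWindowSpec.default_three_band()
        self.sub = d.reconstruct_subbands(self.pre, self.band_spec)
        self.sub_stokes = d.jones_to_stokes(self.sub)
        self.sdopu = d.spectral_dopu(self.sub_stokes, self.mask)
        self.spatial = d.spatial_dopu(self.stokes, 8, 5, self.mask)

    def layer_values(self, dmap: d.DopuMap, layer: int) -> np.ndarray:
        sel = (self.truth.labels == layer) & dmap.valid
        return dmap.values[sel]


@pytest.fixture(scope="session")
def two_layer_products() -> TwoLayerProducts:
    return TwoLayerProducts()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_jones_field(rng: np.random.Generator, shape: tuple) -> d.JonesField:
    """Random fully-developed-speckle Jones field of the given (b, f, z, x) shape."""
    def cplx():
        return rng.normal(size=shape) + 1j * rng.normal(size=shape)

    return d.JonesField(e1=cplx(), e2=cplx(), pixel_pitch_z=1.0)


def single_scatterer_raw(
    z_um: float = 200.0,
    direction: tuple = (0.0, 0.0, 1.0),
    ret_slope: float = 0.0,
    amplitude: float = 1.0,
    a_lines: int = 32,
    phase: float = 0.0,
    samples: int = 512,
    span_factor: float = 3.0,
) -> tuple[d.RawSpectra, d.PhantomSpec]:
    """Noise-free phantom containing exactly one programmed scatterer."""
    from depoloct.phantom import Scatterers, synthesize_from_scatterers

    grid = d.KGrid.from_source(samples=samples, span_factor=span_factor)
    spec = d.PhantomSpec(grid=grid, a_lines=a_lines, layers=(), seed=0)
    scat = Scatterers(
        z_um=np.array([z_um]),
        x_um=np.array([(a_lines // 2) * spec.pixel_pitch_x]),
        amplitude=np.array([amplitude]),
        direction=np.array([direction], dtype=float),
        ret_slope=np.array([ret_slope]),
        phase=np.array([phase]),
        layer=np.array([0]),
        home=np.array([a_lines // 2]),
    )
    return synthesize_from_scatterers(spec, scat), spec


def stokes_from_directions(directions: np.ndarray,
                           intensities: np.ndarray | None = None) -> d.StokesField:
    """Pure-state Stokes field (nz, 1) built from unit (q,u,v) directions."""
    dirs = np.asarray(directions, dtype=float)
    n = dirs.shape[0]
    inten = np.ones(n) if intensities is None else np.asarray(intensities, dtype=float)
    shape = (1, 1, n, 1)
    return d.StokesField(
        i=inten.reshape(shape),
        q=(inten * dirs[:, 0]).reshape(shape),
        u=(inten * dirs[:, 1]).reshape(shape),
        v=(inten * dirs[:, 2]).reshape(shape),
    )
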