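"""Spatial, temporal and spectral DOPU estimators and frame registration."""

import numpy as np
import pytest

import depoloct as d
from depoloct.dopu import kernel_equivalence_check
from depoloct.phantom import PhantomSpec, LayerSpec

from conftest import random_jones_field, stokes_from_directions
from reference import resultant_length_null

ALL_VALID = lambda nz, nx: d.ValidityMask(mask=np.ones((nz, nx), bool), threshold_db=0.0)


class TestSpatialDopu:
    def test_single_pixel_kernel_is_unity(self, rng):
        s = d.jones_to_stokes(random_jones_field(rng, (1, 1, 6, 6)))
        m = d.spatial_dopu(s, 1, 1, ALL_VALID(6, 6))
        assert np.allclose(m.values, 1.0, atol=1e-12)

    def test_parallel_states_any_intensity_is_unity(self, rng):
        direction = np.array([0.6, 0.64, 0.48])
        intensities = rng.uniform(0.1, 10.0, 30)
        s = stokes_from_directions(np.tile(direction, (30, 1)), intensities)
        m = d.spatial_dopu(s, 1, 30, ALL_VALID(30, 1))
        assert np.allclose(m.values, 1.0, atol=1e-12)

    def test_orthonormal_triple(self):
        s = stokes_from_directions(np.eye(3))
        m = d.spatial_dopu(s, 1, 3, ALL_VALID(3, 1))
        assert m.values[1, 0] == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_isotropic_ensemble_matches_monte_carlo_null(self, rng):
        n = 1000
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        s = stokes_from_directions(dirs)
        m = d.spatial_dopu(s, 1, n, ALL_VALID(n, 1))
        value = m.values[n // 2, 0]
        null = resultant_length_null(n, 100_000, np.random.default_rng(777))
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= value <= hi

    def test_masked_pixels_excluded_from_average(self):
        # two antiparallel states; masking one leaves the survivor at DOPU 1
        s = stokes_from_directions(np.array([[0, 0, 1.0], [0, 0, -1.0]]))
        mask = d.ValidityMask(mask=np.array([[True], [False]]), threshold_db=0.0)
        m = d.spatial_dopu(s, 1, 2, mask)
        assert m.values[0, 0] == pytest.approx(1.0)
        assert np.isnan(m.values[1, 0])

    def test_kernel_larger_than_image_rejected(self, rng):
        s = d.jones_to_stokes(random_jones_field(rng, (1, 1, 4, 4)))
        with pytest.raises(ValueError, match="kernel"):
            d.spatial_dopu(s, 5, 1, ALL_VALID(4, 4))


class TestRegistration:
    def test_identical_frames_zero_shift(self, rng):
        frame = rng.uniform(0.1, 1.0, (32, 32))
        shifts = d.register_frames(np.stack([frame] * 3))
        assert np.array_equal(shifts.shifts, np.zeros((3, 2), int))

    def test_circular_shift_recovered(self, rng):
        frame = rng.uniform(0.1, 1.0, (40, 48))
        rolled = np.roll(frame, (3, -2), axis=(0, 1))
        shifts = d.register_frames(np.stack([frame, rolled]))
        assert tuple(shifts.shifts[1]) == (3, -2)

    def test_zero_variance_frame_warns(self, rng):
        frame = rng.uniform(0.1, 1.0, (16, 16))
        with pytest.warns(UserWarning, match="variance"):
            shifts = d.register_frames(np.stack([frame, np.ones((16, 16))]))
        assert tuple(shifts.shifts[1]) == (0, 0)


class TestTemporalDopu:
    def _repeat_stokes(self, rng, n_frames):
        jf = random_jones_field(rng, (1, 1, 8, 8))
        s = d.jones_to_stokes(jf)
        rep = lambda a: np.repeat(a, n_frames, axis=1)
        return d.StokesField(i=rep(s.i), q=rep(s.q), u=rep(s.u), v=rep(s.v))

    def test_identical_frames_give_unity(self, rng):
        s = self._repeat_stokes(rng, 30)
        shifts = d.ShiftSeries(shifts=np.zeros((30, 2), int))
        m = d.temporal_dopu(s, shifts, ALL_VALID(8, 8))
        assert np.allclose(m.values[m.valid], 1.0, atol=1e-9)
        assert m.valid.all()

    def test_antiparallel_states_cancel(self):
        shape = (1, 2, 1, 1)
        s = d.StokesField(i=np.ones(shape), q=np.zeros(shape), u=np.zeros(shape),
                          v=np.array([1.0, -1.0]).reshape(shape))
        shifts = d.ShiftSeries(shifts=np.zeros((2, 2), int))
        m = d.temporal_dopu(s, shifts, ALL_VALID(1, 1))
        assert m.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_frame_counts_rejected(self, rng):
        s = self._repeat_stokes(rng, 3)
        shifts = d.ShiftSeries(shifts=np.zeros((4, 2), int))
        with pytest.raises(ValueError, match="frame count"):
            d.temporal_dopu(s, shifts, ALL_VALID(8, 8))

    def test_phantom_layer_contrast(self):
        # static preserving layer vs per-frame-redrawn depolarizing layer
        preserving, depolarizing = [], []
        for seed in range(10):
            spec = d.two_layer(seed=seed, a_lines=48, frames=6, tau=1.0)
            raw, truth = d.synthesize(spec)
            full = d.reconstruct(d.preprocess_spectra(raw))
            inten = full.intensity()[0]
            masks = np.stack([d.build_mask(inten[f]).mask for f in range(6)])
            shifts = d.register_frames(inten)
            m = d.temporal_dopu(d.jones_to_stokes(full), shifts, masks)
            sel0 = (truth.labels == 0) & m.valid
            sel1 = (truth.labels == 1) & m.valid
            preserving.append(np.median(m.values[sel0]))
            depolarizing.append(np.median(m.values[sel1]))
        assert all(p >= 0.95 for p in preserving)
        assert all(q <= 0.6 for q in depolarizing)


class TestSpectralDopu:
    def _band_stokes(self, i, q, u, v):
        shape = (len(i), 1, 1, 1)
        return d.StokesField(i=np.reshape(i, shape), q=np.reshape(q, shape),
                             u=np.reshape(u, shape), v=np.reshape(v, shape))

    def test_single_band_always_unity(self, rng):
        jf = random_jones_field(rng, (1, 1, 8, 8))
        m = d.spectral_dopu(d.jones_to_stokes(jf), ALL_VALID(8, 8))
        assert np.allclose(m.values[m.valid], 1.0, atol=1e-9)

    def test_collinear_bands_unequal_intensity_unity(self):
        inten = np.array([1.0, 2.5, 0.3])
        s = self._band_stokes(inten, 0.6 * inten, 0.8 * inten, 0.0 * inten)
        m = d.spectral_dopu(s, ALL_VALID(1, 1))
        assert m.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_equal_intensity_bands(self):
        s = self._band_stokes(np.ones(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])
        m = d.spectral_dopu(s, ALL_VALID(1, 1))
        assert m.values[0, 0] == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_zero_mean_intensity_invalid(self):
        s = self._band_stokes(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
        m = d.spectral_dopu(s, ALL_VALID(1, 1))
        assert np.isnan(m.values[0, 0])


class TestInvariants:
    def test_range_on_phantom_maps(self, two_layer_products):
        p = two_layer_products
        for m in (p.spatial, p.sdopu):
            vals = m.values[m.valid]
            assert vals.min() >= 0.0
            assert vals.max() <= 1.0 + 1e-9

    def test_global_unitary_rotation_leaves_maps_unchanged(self, rng):
        spec = d.with_snr(PhantomSpec(
            grid=d.KGrid.from_source(samples=256), a_lines=32,
            layers=(LayerSpec(z_range=(40.0, 100.0), scatterer_density=15.0),
                    LayerSpec(z_range=(120.0, 200.0), scatterer_density=15.0,
                              depol_index=0.8, spectral_decorr=6.0)),
            seed=3), 30.0)
        raw, _ = d.synthesize(spec)
        pre = d.preprocess_spectra(raw)
        full = d.reconstruct(pre)
        sub = d.reconstruct_subbands(pre, d.SpectralWindowSpec.default_three_band())
        mask = d.build_mask(full.intensity()[0, 0])

        # Haar-ish random SU(2) rotation applied to every pixel and band
        a = rng.normal() + 1j * rng.normal()
        b = rng.normal() + 1j * rng.normal()
        norm = np.sqrt(abs(a) ** 2 + abs(b) ** 2)
        a, b = a / norm, b / norm

        def rotate(jf):
            return d.JonesField(e1=a * jf.e1 + b * jf.e2,
                                e2=-np.conj(b) * jf.e1 + np.conj(a) * jf.e2,
                                pixel_pitch_z=jf.pixel_pitch_z)

        for jf, maker in [
            (full, lambda s: d.spatial_dopu(s, 8, 5, mask)),
            (sub, lambda s: d.spectral_dopu(s, mask)),
        ]:
            before = maker(d.jones_to_stokes(jf))
            after = maker(d.jones_to_stokes(rotate(jf)))
            assert np.array_equal(before.valid, after.valid)
            assert np.allclose(before.values[before.valid],
                               after.values[after.valid], atol=1e-9)

    def test_kernel_size_monotonicity_on_depolarizing_layer(self):
        hits = 0
        for seed in range(10):
            spec = d.two_layer(seed=seed, a_lines=48)
            raw, truth = d.synthesize(spec)
            s = d.jones_to_stokes(d.reconstruct(d.preprocess_spectra(raw)))
            mask = d.build_mask(s.i[0, 0])
            meds = []
            for kx, kz in [(8, 5), (1, 7), (1, 1)]:
                m = d.spatial_dopu(s, kx, kz, mask)
                sel = (truth.labels == 1) & m.valid
                meds.append(np.median(m.values[sel]))
            hits += meds[0] <= meds[1] <= meds[2]
        assert hits >= 9


class TestKernelEquivalence:
    def test_preserving_phantom_saturates_both_maps(self):
        grid = d.KGrid.from_source()
        spec = PhantomSpec(
            grid=grid, a_lines=48,
            layers=(LayerSpec(z_range=(60.0, 380.0), scatterer_density=15.0),),
            seed=5)
        spec = d.with_snr(spec, 30.0)
        raw, _ = d.synthesize(spec)
        report = kernel_equivalence_check(raw, d.SpectralWindowSpec.tiled(grid, 16))
        assert report["mean_abs_diff"] < 0.02
        med = np.median(report["sdopu"].values[report["sdopu"].valid])
        assert med > 0.95

    def test_single_band_degenerate_limit(self):
        spec = d.two_layer(seed=0, a_lines=32)
        raw, _ = d.synthesize(spec)
        report = kernel_equivalence_check(raw, d.SpectralWindowSpec.tiled(raw.grid, 1))
        both = report["sdopu"].valid & report["axial"].valid
        assert np.allclose(report["sdopu"].values[both], 1.0, atol=1e-9)
        assert np.allclose(report["axial"].values[both], 1.0, atol=1e-9)
        assert report["max_abs_diff"] <= 1e-9
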