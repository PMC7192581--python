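"""PIV pipeline: shifts, drift, accumulation, segmentation, projection."""

import numpy as np
import pytest

import spherotfm as sp
from spherotfm.piv import (
    AccumulatedField,
    IncrementalField,
    accumulate,
    drift_correct,
    piv_pair,
    project_and_filter,
    segment_spheroid,
)


@pytest.fixture(scope="module")
def bead_img():
    """Dense pure-bead frame (no spheroid) at 1 µm/px."""
    scene = sp.generate_scene(density=6e-3, seed=7, shape=(400, 400),
                              pixel_size=1.0, spheroid_radius=1e-3)
    return scene, sp.render_frame(scene)


class TestPivPair:
    def test_identity_zero_offsets(self, bead_img):
        _, img = bead_img
        f = piv_pair(img, img, window=40)
        # ~9% of templates are empty of beads at this density (Poisson)
        assert f.valid.sum() > 0.85 * len(f.valid)
        assert np.abs(f.offsets[f.valid]).max() < 1e-9

    def test_integer_shift_exact(self, bead_img):
        _, img = bead_img
        shifted = np.roll(img, 3, axis=1)
        f = piv_pair(img, shifted, window=40, pixel_size=1.0)
        interior = f.positions[:, 0] > 45  # exclude wrap-around tiles
        sel = f.valid & interior
        assert sel.sum() > 200
        assert np.abs(f.offsets[sel, 0] - 3.0).max() <= 0.05
        assert np.abs(f.offsets[sel, 1]).max() <= 0.05

    def test_half_pixel_shift(self, bead_img):
        scene, img = bead_img
        shifted = sp.render_frame(scene, lambda p: np.tile([0.5, 0.0], (len(p), 1)))
        f = piv_pair(img, shifted, window=40, pixel_size=1.0)
        assert f.valid.sum() > 200
        assert np.abs(f.offsets[f.valid, 0] - 0.5).max() <= 0.2
        assert np.median(f.offsets[f.valid, 0]) == pytest.approx(0.5, abs=0.05)

    def test_offsets_scale_with_pixel_size(self, bead_img):
        _, img = bead_img
        shifted = np.roll(img, 2, axis=0)
        f = piv_pair(img, shifted, window=40, pixel_size=1.29)
        sel = f.valid & (f.positions[:, 1] > 45 * 1.29)
        assert np.median(f.offsets[sel, 1]) == pytest.approx(2 * 1.29, abs=0.01)

    def test_degenerate_tiles_flagged_not_errored(self):
        img = np.full((200, 200), 7.0)
        f = piv_pair(img, img, window=40)
        assert not f.valid.any()

    def test_window_validation(self, bead_img):
        _, img = bead_img
        with pytest.raises(ValueError):
            piv_pair(img, img, window=8)
        with pytest.raises(ValueError):
            piv_pair(img, img, window=500)
        with pytest.raises(ValueError):
            piv_pair(img, img[:100], window=40)


class TestDriftCorrect:
    def _field(self, offsets, valid=None):
        n = len(offsets)
        return IncrementalField(
            positions=np.arange(2 * n, dtype=float).reshape(n, 2),
            offsets=np.asarray(offsets, dtype=float),
            valid=np.ones(n, bool) if valid is None else np.asarray(valid),
            snr=np.full(n, 2.0), window=40, pixel_size=1.0)

    def test_uniform_field_zeroed(self):
        f = drift_correct(self._field([[2.0, -1.0]] * 5))
        assert np.allclose(f.offsets, 0.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 2))
        a = drift_correct(self._field(base))
        b = drift_correct(self._field(base + [3.0, -2.0]))
        assert np.allclose(a.offsets, b.offsets)

    def test_mean_zero_after_correction(self):
        rng = np.random.default_rng(1)
        f = drift_correct(self._field(rng.normal(size=(50, 2))))
        assert np.allclose(f.offsets[f.valid].mean(axis=0), 0.0, atol=1e-14)

    def test_no_valid_tiles_errors(self):
        with pytest.raises(ValueError):
            drift_correct(self._field([[1.0, 1.0]], valid=[False]))


class TestAccumulate:
    def _inc(self, offsets, valid=None):
        n = len(offsets)
        return IncrementalField(
            positions=np.arange(2 * n, dtype=float).reshape(n, 2),
            offsets=np.asarray(offsets, dtype=float),
            valid=np.ones(n, bool) if valid is None else np.asarray(valid),
            snr=np.full(n, 2.0), window=40, pixel_size=1.0)

    def test_single_step_equals_increment(self):
        inc = self._inc([[1.0, 2.0], [0.5, -0.5]])
        acc = accumulate([inc])
        assert np.array_equal(acc.u, inc.offsets)

    def test_opposite_steps_cancel(self):
        v = [[1.0, -2.0], [3.0, 0.5]]
        acc = accumulate([self._inc(v), self._inc([[-a, -b] for a, b in v])])
        assert np.allclose(acc.u, 0.0)

    def test_constant_increment_scales_linearly(self):
        acc = accumulate([self._inc([[0.5, 1.0]])] * 7)
        assert np.allclose(acc.u, [[3.5, 7.0]])

    def test_invalid_increments_counted(self):
        acc = accumulate([self._inc([[1.0, 1.0]], valid=[False]),
                          self._inc([[1.0, 1.0]])])
        assert acc.n_invalid[0] == 1 and not acc.valid[0]
        assert np.allclose(acc.u, [[1.0, 1.0]])

    def test_mismatched_grids_rejected(self):
        a = self._inc([[1.0, 1.0]])
        b = self._inc([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            accumulate([a, b])


class TestSegmentation:
    def test_dark_disc_radius_centroid_area(self):
        scene = sp.generate_scene(seed=5, shape=(300, 300), pixel_size=1.0,
                                  spheroid_radius=50.0)
        img = sp.render_frame(scene)
        geom = segment_spheroid(img, pixel_size=1.0)
        assert geom.r0 == pytest.approx(50.0, abs=1.0)
        assert np.allclose(geom.centroid, [150.0, 150.0], atol=0.5)
        assert geom.area == pytest.approx(np.pi * 50.0**2, rel=0.02)

    def test_no_foreground_errors(self):
        # a blank image with a single gray level has nothing to segment
        img = np.full((100, 100), 5.0)
        with pytest.raises(ValueError):
            segment_spheroid(img, pixel_size=1.0)


class TestProjection:
    def _setup(self, u_vec, pos=(300.0, 200.0)):
        mask = np.zeros((400, 400), bool)
        geom = sp.SpheroidGeometry(mask=mask, centroid=np.array([200.0, 200.0]),
                                   area=np.pi * 50**2, r0=50.0, pixel_size=1.0)
        acc = AccumulatedField(
            positions=np.array([pos]), u=np.array([u_vec], dtype=float),
            n_invalid=np.zeros(1, int), window=40, pixel_size=1.0)
        return project_and_filter(acc, geom)

    def test_vector_toward_center_positive(self):
        # tile right of center; inward means -x direction
        f = self._setup([-3.0, 0.0])
        assert f.passes[0]
        assert f.u_proj[0] == pytest.approx(3.0)

    def test_vector_away_from_center_negative_but_included(self):
        f = self._setup([3.0, 0.0])
        assert f.passes[0]
        assert f.u_proj[0] == pytest.approx(-3.0)

    def test_vector_30_degrees_off_excluded(self):
        ang = np.deg2rad(30.0)
        f = self._setup([-3.0 * np.cos(ang), 3.0 * np.sin(ang)])
        assert not f.passes[0]

    def test_vector_19_degrees_off_included(self):
        ang = np.deg2rad(19.0)
        f = self._setup([-3.0 * np.cos(ang), 3.0 * np.sin(ang)])
        assert f.passes[0]

    def test_tile_at_centroid_excluded(self):
        f = self._setup([-3.0, 0.0], pos=(200.0, 200.0))
        assert not f.passes[0]

    def test_normalization_by_initial_radius(self):
        f = self._setup([-3.0, 0.0])
        assert f.d_norm[0] == pytest.approx(2.0)
        assert f.u_norm[0] == pytest.approx(3.0 / 50.0)


class TestRotationalConsistency:
    def test_rotated_scene_same_distribution(self, table_2k):
        scene = sp.generate_scene(seed=9, shape=(600, 600), pixel_size=1.29,
                                  spheroid_radius=100.0)
        sched = np.concatenate([[0.0], np.linspace(30.0, 300.0, 5)])
        series, _ = sp.make_timelapse(scene, sched, table_2k, seed=1, noise=False)
        cfg = sp.AnalysisConfig(pixel_size=1.29, dt=10.0, window=40)
        res = sp.run_analysis(cfg, series=series, table=table_2k, write=False)
        rot = sp.ImageSeries(frames=np.stack([np.rot90(f) for f in series.frames]),
                             pixel_size=1.29, dt=10.0)
        res_rot = sp.run_analysis(cfg, series=rot, table=table_2k, write=False)
        p0 = res.records[-1].pressure
        p1 = res_rot.records[-1].pressure
        assert p1 == pytest.approx(p0, rel=0.03)
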