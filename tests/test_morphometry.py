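import numpy as np
import pytest

from isletmorph.morphometry import (
    CellMorphometry,
    compare_groups,
    feret_bruteforce,
    measure_cell,
    ols,
    regress,
    ttest,
)
from isletmorph.segmentation import CellMask, hysteresis_segment, purify
from isletmorph.synthetic import CellSpec, SceneSpec, render_scene

SPHERE_VOLUME = 4.0 / 3.0 * np.pi * 125.0  # r = 5 μm
SPHERE_AREA = 4.0 * np.pi * 25.0


def _measure_sphere(sphere_scene):
    img, _ = sphere_scene
    mask = purify(hysteresis_segment(img))
    return measure_cell(mask)


class TestSphereCalibration:
    def test_volume_area_sphericity_feret(self, sphere_scene):
        m = _measure_sphere(sphere_scene)
        assert abs(m.volume - SPHERE_VOLUME) / SPHERE_VOLUME < 0.05
        assert abs(m.surface_area - SPHERE_AREA) / SPHERE_AREA < 0.05
        assert m.sphericity >= 0.97
        assert m.sphericity <= 1.02  # mesh tolerance
        assert abs(m.feret_diameter - 10.0) / 10.0 < 0.05
        assert m.volume_ellipsoid_ratio == pytest.approx(1.0, abs=0.05)

    def test_isotropic_scaling_laws(self, sphere_scene, make_sphere):
        small = _measure_sphere(sphere_scene)
        big_img, _ = make_sphere(radius_um=10.0)
        big = measure_cell(purify(hysteresis_segment(big_img)))
        assert big.volume == pytest.approx(8 * small.volume, rel=0.02)
        assert big.surface_area == pytest.approx(4 * small.surface_area, rel=0.02)
        assert big.sphericity == pytest.approx(small.sphericity, abs=0.015)

    def test_sphericity_invariant_under_translation(self, make_sphere):
        a_img, _ = make_sphere(radius_um=4.0, pad_um=2.0)
        b_img, _ = make_sphere(radius_um=4.0, pad_um=4.0)  # same ball, shifted grid placement
        a = measure_cell(purify(hysteresis_segment(a_img)))
        b = measure_cell(purify(hysteresis_segment(b_img)))
        assert a.sphericity == pytest.approx(b.sphericity, abs=0.01)


class TestEllipsoid:
    def test_ellipsoid_is_its_own_best_fit(self):
        spec = SceneSpec(
            grid_shape=(26, 64, 64),
            cells=[CellSpec(center=(12.0, 9.0, 9.0), semi_axes=(6.0, 3.0, 3.0))],
            psf_sigma=(0.0, 0.0, 0.0),
            seed=1,
        )
        img, _ = render_scene(spec)
        m = measure_cell(purify(hysteresis_segment(img)))
        assert m.volume_ellipsoid_ratio == pytest.approx(1.0, abs=0.05)

    def test_elongated_shape_less_spherical(self, sphere_scene):
        sphere = _measure_sphere(sphere_scene)
        spec = SceneSpec(
            grid_shape=(26, 64, 64),
            cells=[CellSpec(center=(12.0, 9.0, 9.0), semi_axes=(6.0, 3.0, 3.0))],
            psf_sigma=(0.0, 0.0, 0.0),
            seed=1,
        )
        img, _ = render_scene(spec)
        m = measure_cell(purify(hysteresis_segment(img)))
        assert m.sphericity < sphere.sphericity


class TestFeretOracle:
    def test_convex_hull_matches_bruteforce_on_random_masks(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(7)
        for _ in range(5):
            blob = rng.random((8, 18, 18)) > 0.72
            blob = ndi.binary_dilation(blob, np.ones((1, 2, 2)))
            labels, n = ndi.label(blob, np.ones((3, 3, 3)))
            if n == 0:
                continue
            sizes = np.bincount(labels.ravel())[1:]
            mask = CellMask(labels == (1 + sizes.argmax()), (1.0, 0.3, 0.3))
            if mask.n_voxels < 8:
                continue
            coords = np.argwhere(mask.data)
            if (coords.max(0) - coords.min(0) < 1).any():
                continue
            m = measure_cell(mask)
            assert m.feret_diameter == pytest.approx(feret_bruteforce(mask), rel=1e-9)

    def test_thin_mask_rejected(self):
        flat = np.zeros((5, 10, 10), bool)
        flat[2, 2:8, 2:8] = True
        with pytest.raises(ValueError, match="thin"):
            measure_cell(CellMask(flat, (1.0, 0.3, 0.3)))


class TestStats:
    def test_identical_groups_null(self):
        res = ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        res = ttest([1, 2, 3], [4, 5, 6])
        assert res["t"] == pytest.approx(-3.674, abs=1e-3)
        assert res["df"] == 4
        assert res["p"] == pytest.approx(0.0214, abs=2e-3)

    def test_order_invariance_within_groups(self):
        a = ttest([3, 1, 2], [6, 4, 5])
        b = ttest([1, 2, 3], [4, 5, 6])
        assert a["t"] == pytest.approx(b["t"])

    def test_zero_variance_pair_warns_but_reports(self):
        with pytest.warns(UserWarning):
            res = ttest([2.0, 2.0], [3.0, 4.0])
        assert np.isfinite(res["p"])

    def test_compare_groups_field_extraction(self):
        records = [
            CellMorphometry(100 + i, 120, 0.9, 8, 110, 0.9, group_label="isolated")
            for i in range(3)
        ] + [
            CellMorphometry(80 + i, 120, 0.9, 8, 110, 0.9, group_label="clustered")
            for i in range(3)
        ]
        res = compare_groups(records, "volume")
        assert res["mean_a"] == pytest.approx(101.0)
        assert res["mean_b"] == pytest.approx(81.0)
        assert res["p"] < 0.05


class TestRegression:
    def test_collinear_r2_one(self):
        res = ols([1, 2, 3, 4], [2, 4, 6, 8])
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_constant_y_gives_zero(self):
        res = ols([1, 2, 3, 4], [5, 5, 5, 5])
        assert res["slope"] == 0.0 and res["r_squared"] == 0.0

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            ols([2, 2, 2], [1, 2, 3])

    def test_imposed_trend_recovered_per_group(self):
        rng = np.random.default_rng(11)
        records = []
        for g in ("isolated", "clustered"):
            x = rng.uniform(0.5, 1.0, 12)
            y = 0.8 * x + 0.1 + rng.normal(0, 0.01, 12)
            records += [
                CellMorphometry(1, 1, yi, 1, 1, xi, group_label=g) for xi, yi in zip(x, y)
            ]
        res = regress(records, "volume_ellipsoid_ratio", "sphericity")
        for g in ("isolated", "clustered"):
            assert res[g]["slope"] == pytest.approx(0.8, rel=0.1)
            assert res[g]["r_squared"] > 0.9
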