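"""The ten per-cell features: closed-form oracles, brute-force equivalence
and geometric invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snarfpy import morphometry as mm


def _digital_ellipsoid(semi_axes, voxel=0.25, pad=4):
    half = np.ceil(np.asarray(semi_axes) / voxel).astype(int) + pad
    shape = tuple(2 * half + 1)
    z, y, x = np.indices(shape)
    ctr = half
    coords = [(g - c) * voxel for g, c in zip((z, y, x), ctr)]
    inside = sum((c / a) ** 2 for c, a in zip(coords, semi_axes)) <= 1.0
    return inside.astype(np.int32), (voxel,) * 3


def _cylinder_pair(angle_cell_deg=0.0, shape=(40, 40, 40)):
    """Capillary along x plus a cell ellipsoid whose long axis lies in the
    xy-plane at the requested angle from x."""
    cells = np.zeros(shape, np.int32)
    caps = np.zeros(shape, np.int32)
    z, y, x = np.indices(shape)
    caps[((z - 20) ** 2 + (y - 20) ** 2) <= 4] = 1
    t = np.radians(angle_cell_deg)
    d = np.array([0.0, np.sin(t), np.cos(t)])
    rel = np.stack([z - 20, y - 20, x - 20], -1).astype(float)
    along = rel @ d
    perp2 = (rel ** 2).sum(-1) - along ** 2
    cells[(along ** 2 / 36 + perp2 / 2.25) <= 1] = 1
    return cells, caps


class TestClosedForms:
    def test_unit_cube_sphericity(self):
        """pi^(1/3) 6^(2/3) / 6 = 0.806 for the analytic unit cube."""
        assert mm.sphericity_from(1.0, 6.0) == pytest.approx(0.80600, abs=1e-4)

    def test_esd_formula(self):
        assert mm.equivalent_spherical_diameter(np.pi / 6) == pytest.approx(1.0)

    def test_digital_ball_features(self):
        labels, vs = _digital_ellipsoid((5.0, 5.0, 5.0))
        f = mm.morphological_features(labels, 1, vs)
        assert f["esd"] == pytest.approx(10.0, rel=0.02)
        assert 0.9 <= f["sphericity"] <= 1.05  # mesh discretization tolerance
        for key in ("ela", "esla", "esa"):
            assert f[key] == pytest.approx(10.0, rel=0.03)

    def test_ellipsoid_axes_from_covariance(self):
        """Semi-axes (8,4,2) µm -> axis lengths (16,8,4) via 2 sqrt(5 lambda)."""
        labels, vs = _digital_ellipsoid((8.0, 4.0, 2.0))
        f = mm.morphological_features(labels, 1, vs)
        assert f["ela"] == pytest.approx(16.0, rel=0.02)
        assert f["esla"] == pytest.approx(8.0, rel=0.02)
        assert f["esa"] == pytest.approx(4.0, rel=0.02)

    def test_missing_cell_raises(self):
        with pytest.raises(KeyError):
            mm.morphological_features(np.zeros((4, 4, 4), np.int32), 3, (1, 1, 1))


class TestLining:
    def _fixture(self, gap_vox):
        cells = np.zeros((16, 16, 30), np.int32)
        caps = np.zeros_like(cells)
        caps[:, :, :10] = 1
        cells[6:10, 6:10, 10 + gap_vox:14 + gap_vox] = 1
        return cells, caps

    @pytest.mark.parametrize("gap_vox,expected", [(0, True), (2, False)])
    def test_one_micron_rule(self, gap_vox, expected):
        cells, caps = self._fixture(gap_vox)
        out = mm.classify_lining(cells, caps, (1, 1, 1))
        assert bool(out.loc[0, "lining"]) is expected

    def test_sub_micron_gap_with_fine_voxels(self):
        """A cell whose closest voxel is 0.5 µm from a capillary is lining."""
        cells = np.zeros((8, 8, 40), np.int32)
        caps = np.zeros_like(cells)
        caps[:, :, :10] = 1
        cells[2:6, 2:6, 10:18] = 1  # adjacent 0.5-µm voxels: centers 0.5 µm apart
        out = mm.classify_lining(cells, caps, (0.5, 0.5, 0.5))
        assert bool(out.loc[0, "lining"])
        assert out.loc[0, "min_distance_um"] == pytest.approx(0.5)

    def test_agrees_with_brute_force_on_random_volumes(self):
        rng = np.random.default_rng(123)
        for _ in range(3):
            cells = np.zeros((24, 24, 24), np.int32)
            caps = np.zeros_like(cells)
            for cid in (1, 2, 3):
                c = rng.integers(4, 20, 3)
                z, y, x = np.indices(cells.shape)
                cells[((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) <= 4] = cid
            c = rng.integers(4, 20, 2)
            caps[:, c[0], c[1]] = 1
            fast = mm.classify_lining(cells, caps, (1, 1, 1))
            slow = mm.brute_force_lining(cells, caps, (1, 1, 1))
            for rec in fast.itertuples():
                assert bool(rec.lining) == slow[rec.cell_id]

    def test_no_capillaries_warns_all_non_lining(self):
        cells = np.zeros((8, 8, 8), np.int32)
        cells[2:5, 2:5, 2:5] = 1
        with pytest.warns(UserWarning):
            out = mm.classify_lining(cells, np.zeros_like(cells), (1, 1, 1))
        assert not out["lining"].any()


class TestOverlapAndDistance:
    def test_fully_inside(self):
        caps = np.zeros((16, 16, 16), np.int32)
        caps[2:14, 2:14, 2:14] = 1
        cells = np.zeros_like(caps)
        cells[6:10, 6:10, 6:10] = 1
        pct, dist = mm.overlap_and_distance(cells, caps, 1, (1, 1, 1))
        assert pct == pytest.approx(100.0)
        assert dist == 0.0

    def test_disjoint_three_microns(self):
        caps = np.zeros((10, 10, 30), np.int32)
        caps[:, :, :10] = 1
        cells = np.zeros_like(caps)
        cells[4:6, 4:6, 12:14] = 1  # centroid at x=12.5+0.5 -> 3 µm from edge
        pct, dist = mm.overlap_and_distance(cells, caps, 1, (1, 1, 1))
        assert pct == 0.0
        assert dist == pytest.approx(3.0, abs=0.51)

    def test_half_overlap_matches_voxel_count(self):
        caps = np.zeros((10, 10, 20), np.int32)
        caps[:, :, :10] = 1
        cells = np.zeros_like(caps)
        cells[4:6, 4:6, 8:12] = 1  # exactly half the voxels inside
        expected = 100.0 * np.logical_and(cells == 1, caps > 0).sum() / (cells == 1).sum()
        pct, _ = mm.overlap_and_distance(cells, caps, 1, (1, 1, 1))
        assert pct == pytest.approx(expected) == pytest.approx(50.0)


class TestDirection:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0])
    def test_known_angles(self, angle):
        cells, caps = _cylinder_pair(angle)
        got, flagged = mm.direction_angle(cells, caps, 1, (1, 1, 1))
        assert got == pytest.approx(angle, abs=6.0)
        assert not flagged

    def test_spherical_cell_imputes_ninety(self):
        cells = np.zeros((30, 30, 30), np.int32)
        caps = np.zeros_like(cells)
        z, y, x = np.indices(cells.shape)
        caps[((z - 15) ** 2 + (y - 15) ** 2) <= 4] = 1
        cells[((z - 15) ** 2 + (y - 17) ** 2 + (x - 15) ** 2) <= 9] = 1
        got, flagged = mm.direction_angle(cells, caps, 1, (1, 1, 1))
        assert got == 90.0
        assert flagged

    def test_distant_capillary_uses_expanded_window_flagged(self):
        cells, caps = _cylinder_pair(0.0)
        shifted = np.zeros_like(caps)
        shifted[:, 24:28, :] = caps[:, 18:22, :]  # move capillary ~4.5 µm away
        got, flagged = mm.direction_angle(cells, shifted, 1, (1, 1, 1))
        assert flagged
        assert 0.0 <= got <= 90.0


class TestFeatureTable:
    def test_schema_and_invariants_on_scene(self, clean_scene, clean_segmented):
        v1, _, truth = clean_scene
        table = mm.build_feature_table(clean_segmented["cells"],
                                       clean_segmented["capillaries"],
                                       v1.voxel_size,
                                       true_classes=truth.cell_classes)
        assert list(table.columns) == mm.META_COLUMNS + mm.FEATURES + ["true_class"]
        assert (table["esa"] <= table["esla"] + 1e-9).all()
        assert (table["esla"] <= table["ela"] + 1e-9).all()
        assert table["direction"].between(0, 90).all()
        assert table["pct_overlap"].between(0, 100).all()
        assert (table["distance"] >= 0).all()
        assert (table["sphericity"] <= 1.1).all()
        esd_check = (6.0 * table["volume"] / np.pi) ** (1 / 3)
        np.testing.assert_allclose(table["esd"], esd_check, rtol=1e-9)

    def test_translation_invariance(self):
        cells, caps = _cylinder_pair(45.0)
        f0 = mm.morphological_features(cells, 1, (1, 1, 1))
        a0, _ = mm.direction_angle(cells, caps, 1, (1, 1, 1))
        shifted_cells = np.roll(cells, (3, 4, 5), axis=(0, 1, 2))
        shifted_caps = np.roll(caps, (3, 4, 5), axis=(0, 1, 2))
        f1 = mm.morphological_features(shifted_cells, 1, (1, 1, 1))
        a1, _ = mm.direction_angle(shifted_cells, shifted_caps, 1, (1, 1, 1))
        for key in ("sphericity", "esd", "volume", "esa", "ela", "surface_area",
                    "esla"):
            assert f0[key] == pytest.approx(f1[key], rel=1e-6)
        assert a0 == pytest.approx(a1, abs=1e-6)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_ellipsoid_axes_always_sorted(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(50, 3)) * rng.uniform(0.5, 3.0, 3)
    ela, esla, esa = mm.ellipsoid_axes(pts)
    assert ela >= esla >= esa >= 0.0
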