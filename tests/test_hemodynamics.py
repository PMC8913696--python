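"""Stall detection, persistence, vessel widths and luminal-content typing."""

import numpy as np
import pytest

from snarfpy import hemodynamics as hemo
from snarfpy.scene import SceneConfig, generate_scene
from snarfpy.volume import SnarfVolume
from tests.conftest import small_config


def _vol(a, b, vs=(1.0, 1.0, 1.0), tp=1):
    return SnarfVolume({2850: np.asarray(a, float), 2930: np.asarray(b, float)},
                       vs, timepoint=tp)


def _tube_scene(flowing_t1=True, flowing_t2=True, seed=0, shape=(20, 20, 40)):
    """Tissue cube with one axial tube; flowing frames get fresh speckle,
    stalled frames a dim static lumen."""
    rng = np.random.default_rng(seed)
    z, y, x = np.indices(shape)
    lumen = ((z - 10) ** 2 + (y - 10) ** 2) <= 2.5 ** 2
    frames = []
    for flowing in (flowing_t1, flowing_t2):
        a = np.full(shape, 0.7)
        b = np.full(shape, 0.77)
        if flowing:
            spk = 2.5 * np.clip(1 + 0.4 * rng.normal(size=shape), 0.2, None)
            a[lumen] = 0.14 + spk[lumen]
            b[lumen] = 0.15 + spk[lumen]
        else:
            a[lumen] = 0.2
            b[lumen] = 0.22
        frames.append((a, b))
    v1 = _vol(*frames[0], tp=1)
    v2 = _vol(*frames[1], tp=2)
    return lumen, v1, v2


@pytest.mark.parametrize(
    "s1,s2,expected",
    [("stalled", "stalled", "persistent"),
     ("stalled", "flowing", "transient"),
     ("flowing", "stalled", "transient"),
     ("flowing", "flowing", "flowing")],
)
def test_persistence_mapping_exhaustive(s1, s2, expected):
    assert hemo.persistence(s1, s2) == expected


class TestClassifyFlow:
    def test_flowing_segment_detected(self):
        lumen, v1, v2 = _tube_scene(True, True)
        assert hemo.classify_flow(lumen, v1, v2) == "flowing"
        assert hemo.classify_flow(lumen, v2, v1) == "flowing"

    def test_stalled_segment_detected(self):
        lumen, v1, v2 = _tube_scene(False, False)
        assert hemo.classify_flow(lumen, v1, v2) == "stalled"

    def test_transient_stall_assigned_to_correct_frame(self):
        lumen, v1, v2 = _tube_scene(False, True)
        assert hemo.classify_flow(lumen, v1, v2) == "stalled"
        assert hemo.classify_flow(lumen, v2, v1) == "flowing"

    def test_tiny_segment_rejected(self):
        lumen = np.zeros((8, 8, 8), bool)
        lumen[4, 4, 4] = True
        _, v1, v2 = _tube_scene()
        with pytest.raises(ValueError):
            hemo.classify_flow(lumen, _vol(np.ones((8, 8, 8)), np.ones((8, 8, 8))),
                               _vol(np.ones((8, 8, 8)), np.ones((8, 8, 8)), tp=2))

    def test_perfect_recovery_on_noiseless_default_scene(self, default_clean_scene):
        v1, v2, truth = default_clean_scene
        segments = hemo.analyze_segments(truth.vessel_label_volume, v1, v2)
        assert segments
        for s in segments:
            st = truth.vessel_states[s.segment_id]
            assert s.state_t1 == st["state_t1"]
            assert s.state_t2 == st["state_t2"]


class TestVesselWidth:
    @staticmethod
    def _cylinder(radius, voxel=1.0, length=40):
        n = int(round(length / voxel))
        r_vox = int(np.ceil(radius / voxel)) + 4
        side = 2 * r_vox + 1
        z, y, x = np.indices((side, side, n))
        c = r_vox
        return (((z - c) * voxel) ** 2 + ((y - c) * voxel) ** 2) <= radius ** 2, (
            voxel, voxel, voxel)

    def test_cylinder_diameter(self):
        mask, vs = self._cylinder(2.0)
        width, flagged = hemo.vessel_width(mask, vs)
        assert not flagged
        assert width == pytest.approx(4.0, abs=1.0)  # one-voxel tolerance

    def test_converges_with_finer_voxels(self):
        coarse, vs_c = self._cylinder(2.0, voxel=1.0)
        fine, vs_f = self._cylinder(2.0, voxel=0.5)
        w_c, _ = hemo.vessel_width(coarse, vs_c)
        w_f, _ = hemo.vessel_width(fine, vs_f)
        assert abs(w_f - 4.0) <= abs(w_c - 4.0) + 0.05

    def test_tapered_tube_mean_width(self):
        """Radius 2 -> 1 µm linearly: mean diameter 3 µm (analytic mean)."""
        shape = (14, 14, 40)
        z, y, x = np.indices(shape)
        r_of_x = 2.0 - (x / 39.0)
        mask = ((z - 7) ** 2 + (y - 7) ** 2) <= r_of_x ** 2
        width, _ = hemo.vessel_width(mask, (1, 1, 1))
        assert width == pytest.approx(3.0, abs=1.0)

    def test_rotation_invariance(self):
        axial, vs = self._cylinder(2.0)
        rotated = np.transpose(axial, (2, 0, 1))  # tube now along z
        w1, _ = hemo.vessel_width(axial, vs)
        w2, _ = hemo.vessel_width(rotated, vs)
        assert w1 == pytest.approx(w2, abs=0.3)

    def test_degenerate_segment_flagged(self):
        blob = np.zeros((10, 10, 10), bool)
        blob[4:6, 4:6, 4:6] = True
        width, flagged = hemo.vessel_width(blob, (1, 1, 1))
        assert flagged
        assert width > 0


class TestLuminalContents:
    @staticmethod
    def _stalled_with_blobs(blobs):
        """Dim static lumen with typed blobs: ('rbc'|'wbc', x-center)."""
        shape = (20, 20, 60)
        z, y, x = np.indices(shape)
        lumen = ((z - 10) ** 2 + (y - 10) ** 2) <= 3.0 ** 2
        a = np.full(shape, 0.7)
        b = np.full(shape, 0.77)
        a[lumen] = 0.2
        b[lumen] = 0.22
        for kind, cx in blobs:
            blob = lumen & (((z - 10) ** 2 + (y - 10) ** 2 + (x - cx) ** 2) <= 2.5 ** 2)
            if kind == "rbc":  # hemoglobin: flat across channels
                a[blob] += 2.0
                b[blob] += 2.0
            else:  # WBC: protein-dominant
                a[blob] += 0.4
                b[blob] += 2.0
        return lumen, _vol(a, b)

    def test_flat_spectrum_blob_is_rbc_only(self):
        lumen, vol = self._stalled_with_blobs([("rbc", 30)])
        cells, category = hemo.stratify_luminal_cells(lumen, vol)
        assert category == "rbc_only"
        assert all(c.type == "RBC" for c in cells)

    def test_mixed_blobs_are_both(self):
        lumen, vol = self._stalled_with_blobs([("wbc", 12), ("rbc", 30), ("rbc", 48)])
        cells, category = hemo.stratify_luminal_cells(lumen, vol)
        assert category == "both"
        assert sum(c.type == "WBC" for c in cells) == 1
        assert sum(c.type == "RBC" for c in cells) == 2

    def test_empty_lumen_is_none(self):
        lumen, vol = self._stalled_with_blobs([])
        cells, category = hemo.stratify_luminal_cells(lumen, vol)
        assert category == "none"
        assert not cells


class TestCensus:
    def test_all_flowing_zero_stalls(self, default_clean_scene):
        v1, v2, truth = default_clean_scene
        flowing_ids = [sid for sid, st in truth.vessel_states.items()
                       if st["state_t1"] == st["state_t2"] == "flowing"]
        labels = np.where(np.isin(truth.vessel_label_volume, flowing_ids),
                          truth.vessel_label_volume, 0)
        segments = hemo.analyze_segments(labels, v1, v2)
        census = hemo.stall_census(segments)
        assert census["stalled_volume_fraction_t1"] == 0.0
        assert census["stalled_volume_fraction_t2"] == 0.0
        assert census["n_persistent_stalls"] == 0
        assert sum(census["content_counts"].values()) == 0

    def test_stall_recovery_and_wbc_fraction(self):
        """High-stall scene: recovered states and contents match the
        generator truth; the configured content mix puts a WBC in ~45% of
        persistent stalls (8/18-style), within binomial error."""
        cfg = small_config(seed=11, volume_shape_voxels=(128, 128, 128),
                           vessel_density=20, n_cells=40,
                           stall_fraction=0.7, persistent_fraction=0.9,
                           noise_gaussian_sd=0.0, noise_poisson_scale=0.0)
        v1, v2, truth = generate_scene(cfg)
        segments = hemo.analyze_segments(truth.vessel_label_volume, v1, v2)
        for s in segments:
            st = truth.vessel_states[s.segment_id]
            assert (s.state_t1, s.state_t2) == (st["state_t1"], st["state_t2"])
        census = hemo.stall_census(segments)
        n = census["n_persistent_stalls"]
        assert n >= 5
        p = 0.45
        assert abs(census["fraction_with_wbc"] - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_segment_list_raises(self):
        with pytest.raises(ValueError):
            hemo.stall_census([])
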