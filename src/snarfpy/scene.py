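"""Synthetic SNARF scene generator with complete ground truth.

Emulates the statistical structure of label-free two-channel (2850 /
2930 cm^-1) cortical volumes that the downstream analysis assumes:

* a bright lipid/protein tissue background with dark ellipsoidal nuclei,
* tubular capillaries whose lumen carries hemoglobin transient-absorption
  (TAM) signal of near-equal intensity in both channels, with
  frame-to-frame red-blood-cell speckle when flowing and a markedly reduced,
  static SRS signal when stalled,
* lipid-rich myelin tubes bright mainly at 2850 cm^-1,
* class-conditional nucleus morphology for endothelial cells (elongated,
  aligned with the vessel tangent, hugging the wall), pericytes (rounder,
  offset outward, "bump on a log"), unlabeled capillary-lining cells
  (intermediate) and non-lining cells (placed away from vessels),
* a doubling of cell density at the layer-1 to layer-2/3 transition depth,
* depth attenuation exp(-z / attenuation_length) of both channels over a
  constant background offset, Gaussian read noise and Poisson shot noise.

Ground truth (cell labels and classes, vessel labels and per-timepoint flow
states, stall contents, myelin mask) replaces the fluorescent labeling
(Tie2-GFP / NeuroTrace) that provides class identity in vivo.

All randomness flows from a single ``numpy`` Generator seeded by
``SceneConfig.seed``; identical configs produce bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import yaml

from snarfpy.volume import SnarfVolume, write_stack, read_stack, SIDECAR_NAME


class DegenerateConfigurationError(RuntimeError):
    """Object placement failed after bounded retries (scene too crowded)."""


# --------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class ClassMorphology:
    """Nucleus shape/placement model for one cell class.

    semi_axes_um are the mean ellipsoid semi-axes (sorted descending);
    jitter is the relative s.d. applied independently per axis;
    radial_offset_um displaces the centroid outward from the vessel surface
    (lining classes only); orientation is "tangent" (long axis along the
    local vessel tangent), "circumferential" (long axis around the vessel)
    or "random".
    """

    semi_axes_um: tuple[float, float, float]
    jitter: float = 0.12
    radial_offset_um: float = 0.0
    orientation: str = "random"


@dataclasses.dataclass
class OpticalModel:
    """Forward intensity model mapping scene content to the two channels.

    ``mixing`` maps concentrations (lipid, protein) to intensities
    (ch2850, ch2930) row-wise; the default makes 2850 lipid-dominant and
    2930 sensitive to both, as in two-color stimulated Raman histology.
    TAM (hemoglobin) amplitude is added equally to both channels —
    wavenumber-independent by construction.
    """

    mixing: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.2), (0.45, 1.0))
    tissue_lipid: float = 0.6
    tissue_protein: float = 0.5
    nucleus_lipid_factor: float = 0.15   # multiplicative darkening inside nuclei
    nucleus_protein_factor: float = 0.65  # partial darkening of the protein signal
    myelin_lipid_factor: float = 3.0
    lumen_srs_factor: float = 0.2        # residual SRS inside a flowing lumen
    stalled_srs_factor: float = 0.3      # "noticeable decrease" in a stalled lumen
    tam_amplitude: float = 2.5
    speckle_sd: float = 0.35             # relative s.d. of the flowing RBC speckle
    rbc_tam: float = 2.0                 # TAM amplitude of a stuck RBC blob
    wbc_protein: float = 2.0             # protein concentration of a WBC blob
    background_offset: float = 0.05      # depth-independent background floor


DEFAULT_CLASS_MORPHOLOGY = {
    "endothelial": ClassMorphology((5.5, 2.2, 2.0), 0.12, 1.2, "tangent"),
    "pericyte": ClassMorphology((3.2, 2.9, 2.7), 0.10, 2.2, "circumferential"),
    "unlabeled": ClassMorphology((3.4, 2.2, 1.9), 0.12, 1.8, "random"),
    "non_lining": ClassMorphology((4.0, 2.7, 2.3), 0.12, 0.0, "random"),
}

CLASS_ORDER = ("endothelial", "pericyte", "unlabeled", "non_lining")
LINING_CLASSES = ("endothelial", "pericyte", "unlabeled")
CONTENT_CATEGORIES = ("wbc_only", "rbc_only", "both", "none")


@dataclasses.dataclass
class SceneConfig:
    """Full specification of one synthetic scene (see module docstring)."""

    volume_shape_voxels: tuple[int, int, int] = (160, 160, 160)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cells: int = 450
    # (endothelial, pericyte, unlabeled, non_lining); the lining split mirrors
    # the 661:134:120 in vivo class counts at a 70% lining fraction.
    class_proportions: tuple[float, float, float, float] = (0.506, 0.102, 0.092, 0.300)
    class_morphology: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MORPHOLOGY)
    )
    vessel_density: int = 30              # capillary segments per volume
    vessel_radius_um: tuple[float, float] = (1.8, 3.2)
    stall_width_factor: float = 0.92      # slight narrowing of stalled segments
    n_myelin: int = 6
    myelin_radius_um: float = 1.0
    stall_fraction: float = 0.03          # stalled per timepoint
    persistent_fraction: float = 0.5      # of stalls present at both timepoints
    stall_content_probs: tuple[float, float, float, float] = (0.20, 0.35, 0.25, 0.20)
    l23_depth_um: float = 100.0
    l23_density_ratio: float = 2.0        # deep : shallow cell density
    noise_gaussian_sd: float = 0.02
    noise_poisson_scale: float = 200.0    # photons per intensity unit; 0 disables
    attenuation_length_um: float = 70.0
    optics: OpticalModel = dataclasses.field(default_factory=OpticalModel)
    seed: int = 0
    max_placement_retries: int = 500

    def validate(self) -> None:
        for name, probs in (
            ("class_proportions", self.class_proportions),
            ("stall_content_probs", self.stall_content_probs),
        ):
            p = np.asarray(probs, float)
            if np.any(p < 0) or np.any(p > 1) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError(f"{name} must lie in [0,1] and sum to 1, got {probs}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if any(s < 8 for s in self.volume_shape_voxels):
            raise ValueError("volume too small to host any object")
        if not (0.0 <= self.stall_fraction <= 1.0 and 0.0 <= self.persistent_fraction <= 1.0):
            raise ValueError("stall fractions must lie in [0,1]")
        if self.n_cells < 0 or self.vessel_density < 0:
            raise ValueError("counts must be nonnegative")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SceneConfig":
        """Scene sized to yield roughly the reported study population
        (~915 capillary-lining cells at the 661:134:120 class split) in a
        200 µm cube, for full-scale classifier evaluation."""
        return cls(volume_shape_voxels=(200, 200, 200), n_cells=1310,
                   vessel_density=45, seed=seed)

    # ------------------------------------------------------------- YAML I/O

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["class_morphology"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else dict(v)
            for k, v in self.class_morphology.items()
        }
        Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "class_morphology" in d:
            d["class_morphology"] = {
                k: ClassMorphology(
                    semi_axes_um=tuple(v["semi_axes_um"]),
                    jitter=float(v.get("jitter", 0.12)),
                    radial_offset_um=float(v.get("radial_offset_um", 0.0)),
                    orientation=str(v.get("orientation", "random")),
                )
                for k, v in d["class_morphology"].items()
            }
        if "optics" in d and not isinstance(d["optics"], OpticalModel):
            o = dict(d["optics"])
            if "mixing" in o:
                o["mixing"] = tuple(tuple(row) for row in o["mixing"])
            d["optics"] = OpticalModel(**o)
        for key in ("volume_shape_voxels", "voxel_size", "class_proportions",
                    "vessel_radius_um", "stall_content_probs"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SceneConfig fields: {sorted(unknown)}")
        return cls(**d)


def _plain(obj):
    """Recursively convert numpy scalars / tuples for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# ground truth container


@dataclasses.dataclass
class GroundTruth:
    """Complete per-voxel and per-object truth for one synthetic scene."""

    cell_label_volume: np.ndarray        # int, 0 background, k = cell id
    cell_classes: dict[int, str]
    vessel_label_volume: np.ndarray      # int, per-segment ids (full lumen)
    vessel_states: dict[int, dict]       # id -> {state_t1, state_t2, content, fully_contained}
    myelin_mask: np.ndarray              # bool
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        shapes = {
            self.cell_label_volume.shape,
            self.vessel_label_volume.shape,
            self.myelin_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("ground-truth masks disagree in shape")
        cell_ids = set(np.unique(self.cell_label_volume)) - {0}
        if cell_ids != set(self.cell_classes):
            raise ValueError("cell label/class mismatch")
        vessel_ids = set(np.unique(self.vessel_label_volume)) - {0}
        if not vessel_ids <= set(self.vessel_states):
            raise ValueError("vessel segment missing a state entry")

    # --------------------------------------------------------------- disk

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(outdir / "cell_labels.tif", self.cell_label_volume.astype(np.uint16))
        write_stack(outdir / "vessel_labels.tif", self.vessel_label_volume.astype(np.uint16))
        write_stack(outdir / "myelin_mask.tif", self.myelin_mask.astype(np.uint8))
        pd.DataFrame(
            {"cell_id": sorted(self.cell_classes),
             "class": [self.cell_classes[k] for k in sorted(self.cell_classes)]}
        ).to_csv(outdir / "cell_classes.csv", index=False)
        rows = []
        for sid in sorted(self.vessel_states):
            st = self.vessel_states[sid]
            rows.append(
                {
                    "segment_id": sid,
                    "state_t1": st["state_t1"],
                    "state_t2": st["state_t2"],
                    "content": st.get("content", ""),
                    "fully_contained": st["fully_contained"],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "vessel_states.csv", index=False)
        yaml.safe_dump(
            {"voxel_size_um": [float(v) for v in self.voxel_size]},
            (outdir / "truth_meta.yaml").open("w"),
        )

    @classmethod
    def load(cls, indir: str | Path) -> "GroundTruth":
        indir = Path(indir)
        classes = pd.read_csv(indir / "cell_classes.csv")
        states = pd.read_csv(
            indir / "vessel_states.csv", keep_default_na=False
        )
        meta = yaml.safe_load((indir / "truth_meta.yaml").read_text())
        return cls(
            cell_label_volume=read_stack(indir / "cell_labels.tif").astype(np.int32),
            cell_classes=dict(zip(classes["cell_id"], classes["class"])),
            vessel_label_volume=read_stack(indir / "vessel_labels.tif").astype(np.int32),
            vessel_states={
                int(r.segment_id): {
                    "state_t1": r.state_t1,
                    "state_t2": r.state_t2,
                    "content": r.content or None,
                    "fully_contained": bool(r.fully_contained),
                }
                for r in states.itertuples()
            },
            myelin_mask=read_stack(indir / "myelin_mask.tif").astype(bool),
            voxel_size=tuple(meta["voxel_size_um"]),
        )


# --------------------------------------------------------------------------
# geometry helpers


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular_unit(rng: np.random.Generator, axis: np.ndarray) -> np.ndarray:
    v = _random_unit(rng)
    v = v - np.dot(v, axis) * axis
    n = np.linalg.norm(v)
    if n < 1e-8:  # pathological draw parallel to axis
        v = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(v) < 1e-8:
            v = np.cross(axis, [0.0, 1.0, 0.0])
        n = np.linalg.norm(v)
    return v / n


def _orientation_matrix(rng: np.random.Generator, long_axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose first ROW is the long axis (orthonormal basis)."""
    u1 = long_axis / np.linalg.norm(long_axis)
    u2 = _perpendicular_unit(rng, u1)
    u3 = np.cross(u1, u2)
    return np.stack([u1, u2, u3])


def _polyline(rng, shape_um, margin, step=1.0, max_len=260.0, wobble=0.06):
    """Random mildly-curved polyline through the volume, points in µm."""
    lo = np.full(3, margin)
    hi = np.asarray(shape_um) - margin
    p = rng.uniform(lo, hi)
    d = _random_unit(rng)
    pts = [p.copy()]
    for _ in range(int(max_len / step)):
        d = d + wobble * rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = p + step * d
        if np.any(p < lo) or np.any(p > hi):
            break
        pts.append(p.copy())
    return np.asarray(pts)


def _ellipsoid_crop(center_um, semi_axes, rot, voxel_size, shape):
    """Voxel indices of a solid oriented ellipsoid, as (zz, yy, xx) arrays.

    Returns None if the ellipsoid (with a 1-voxel margin) leaves the volume.
    """
    vs = np.asarray(voxel_size, float)
    reach = np.abs(rot.T * np.asarray(semi_axes)).sum(axis=1)  # per-axis extent, µm
    lo_um = np.asarray(center_um) - reach
    hi_um = np.asarray(center_um) + reach
    lo = np.floor(lo_um / vs).astype(int) - 1
    hi = np.ceil(hi_um / vs).astype(int) + 2
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        return None
    grids = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    coords = np.stack([g * vs[a] + vs[a] / 2 for a, g in enumerate(grids)], axis=-1)
    rel = (coords - np.asarray(center_um)) @ rot.T  # into ellipsoid frame
    inside = np.sum((rel / np.asarray(semi_axes)) ** 2, axis=-1) <= 1.0
    if not inside.any():
        return None
    zz, yy, xx = (g[inside] for g in grids)
    return zz, yy, xx


def _smooth_speckle(rng, shape, sd, sigma=1.5):
    """Positive multiplicative speckle field, mean ~1, relative s.d. ~sd."""
    field = ndi.gaussian_filter(rng.normal(size=shape), sigma)
    s = field.std()
    if s > 0:
        field = field / s
    return np.clip(1.0 + sd * field, 0.1, None)


# --------------------------------------------------------------------------
# generation


def generate_scene(config: SceneConfig) -> tuple[SnarfVolume, SnarfVolume, GroundTruth]:
    """Generate two noisy timepoints (nominally 15 min apart) plus ground truth.

    Geometry (vessels, nuclei, myelin, stall states and stuck-cell blobs) is
    shared between timepoints; only the flowing-lumen RBC speckle and the
    measurement noise are redrawn per frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape_voxels)
    vs = np.asarray(config.voxel_size, float)
    shape_um = np.asarray(shape) * vs

    # class tallies are the generator's first draw, so they can be reproduced
    # externally with the same seed policy
    class_counts = rng.multinomial(config.n_cells, np.asarray(config.class_proportions))

    vessel_labels, radii, fully_contained, centerlines = _place_vessels(rng, config, shape, vs, shape_um)
    vessel_states = _draw_vessel_states(rng, config, radii)
    myelin = _place_myelin(rng, config, shape, vs, shape_um, vessel_labels)
    cell_labels, cell_classes = _place_cells(rng, config, shape, vs, shape_um,
                                             vessel_labels, radii, centerlines,
                                             class_counts)

    truth = GroundTruth(
        cell_label_volume=cell_labels,
        cell_classes=cell_classes,
        vessel_label_volume=vessel_labels,
        vessel_states=vessel_states,
        myelin_mask=myelin,
        voxel_size=tuple(vs),
    )
    truth.validate()

    vols = _render(rng, config, truth, centerlines)
    return vols[0], vols[1], truth


def _place_vessels(rng, config, shape, vs, shape_um):
    """Rasterize capillary segments; returns labels, radii, containment, centerlines."""
    centerlines = {}
    radii = {0: 0.0}
    margin = 2.0
    accepted_pts = np.empty((0, 3))
    accepted_r = np.empty((0,))
    for sid in range(1, config.vessel_density + 1):
        r = rng.uniform(*config.vessel_radius_um)
        placed = False
        for _ in range(config.max_placement_retries):
            pts = _polyline(rng, shape_um, margin=max(margin, r + 1.0))
            if len(pts) < 40:
                continue
            if len(accepted_pts):
                # keep tubes separated so segments stay topologically simple
                d = np.sqrt(((pts[::4, None, :] - accepted_pts[None, ::4, :]) ** 2).sum(-1))
                if d.min() < r + accepted_r[::4].max() + 2.0:
                    continue
            centerlines[sid] = pts
            radii[sid] = r
            accepted_pts = np.vstack([accepted_pts, pts])
            accepted_r = np.concatenate([accepted_r, np.full(len(pts), r)])
            placed = True
            break
        if not placed and config.vessel_density > 0:
            raise DegenerateConfigurationError(
                f"could not place vessel segment {sid} after retries"
            )

    labels = np.zeros(shape, np.int32)
    if centerlines:
        cl = np.zeros(shape, np.int32)
        for sid, pts in centerlines.items():
            idx = np.round(pts / vs - 0.5).astype(int)
            idx = np.clip(idx, 0, np.asarray(shape) - 1)
            cl[idx[:, 0], idx[:, 1], idx[:, 2]] = sid
        dist, ind = ndi.distance_transform_edt(cl == 0, sampling=vs, return_indices=True)
        nearest = cl[ind[0], ind[1], ind[2]]
        rad_map = np.asarray([radii.get(i, 0.0) for i in range(max(radii) + 1)])
        labels = np.where(dist <= rad_map[nearest], nearest, 0).astype(np.int32)

    fully = {}
    border = np.zeros(shape, bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    for sid in centerlines:
        fully[sid] = not bool(np.any(border & (labels == sid)))
    return labels, radii, fully, centerlines


def _draw_vessel_states(rng, config, radii):
    """Per-segment flow category: persistent / transient (at t1 or t2) / flowing.

    Per-timepoint stall probability equals ``stall_fraction``; a stall is
    persistent with probability ``persistent_fraction``, else transient and
    assigned to one timepoint uniformly.
    """
    s, pf = config.stall_fraction, config.persistent_fraction
    p_persistent = s * pf
    p_transient = min(1.0 - p_persistent, 2.0 * s * (1.0 - pf))
    states = {}
    content_probs = np.asarray(config.stall_content_probs, float)
    segment_ids = sorted(i for i in radii if i > 0)
    for sid in segment_ids:
        u = rng.random()
        if u < p_persistent:
            st1 = st2 = "stalled"
            content = CONTENT_CATEGORIES[rng.choice(4, p=content_probs)]
        elif u < p_persistent + p_transient:
            if rng.random() < 0.5:
                st1, st2 = "stalled", "flowing"
            else:
                st1, st2 = "flowing", "stalled"
            content = None
        else:
            st1 = st2 = "flowing"
            content = None
        states[sid] = {"state_t1": st1, "state_t2": st2, "content": content,
                       "fully_contained": True}
    return states


def _place_myelin(rng, config, shape, vs, shape_um, vessel_labels):
    mask = np.zeros(shape, bool)
    if config.n_myelin <= 0:
        return mask
    cl = np.zeros(shape, bool)
    for _ in range(config.n_myelin):
        pts = _polyline(rng, shape_um, margin=2.0, wobble=0.04)
        if len(pts) < 20:
            continue
        idx = np.round(pts / vs - 0.5).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        cl[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if cl.any():
        dist = ndi.distance_transform_edt(~cl, sampling=vs)
        mask = dist <= config.myelin_radius_um
    mask &= vessel_labels == 0
    return mask


def _draw_depth(rng, config, depth_um, margin_um=6.0):
    """Target depth from the piecewise density with the L1 -> L2/3 step.

    Sampling the depth *first* (and only then searching for a position near
    it) keeps the realized profile at the configured ratio even when
    placement near vessels is locally crowded; plain accept/reject would let
    overlap retries redistribute cells toward emptier strata. ``margin_um``
    trims bands at the faces where a whole nucleus cannot fit.
    """
    ratio = max(config.l23_density_ratio, 1e-6)
    lo = min(margin_um, depth_um / 4)
    hi = depth_um - lo
    split = float(np.clip(config.l23_depth_um, lo, hi))
    w_shallow = split - lo
    w_deep = ratio * (hi - split)
    if rng.random() < w_deep / max(w_shallow + w_deep, 1e-12):
        return rng.uniform(split, hi)
    return rng.uniform(lo, split)


def _place_cells(rng, config, shape, vs, shape_um, vessel_labels, radii, centerlines,
                 counts):
    labels = np.zeros(shape, np.int32)
    classes: dict[int, str] = {}
    if config.n_cells == 0:
        return labels, classes

    vessel_dist = ndi.distance_transform_edt(vessel_labels == 0, sampling=vs)

    # flattened centerline sample pool (segment id, point index) for lining
    # cells, sorted by depth for stratified draws
    pool = [(sid, k) for sid, pts in centerlines.items() for k in range(1, len(pts) - 1)]
    if not pool and counts[:3].sum() > 0:
        raise DegenerateConfigurationError("lining cells requested but no vessels placed")
    if pool:
        pool_z = np.asarray([centerlines[sid][k][0] for sid, k in pool])
        order = np.argsort(pool_z, kind="stable")
        pool = [pool[i] for i in order]
        pool_z = pool_z[order]
    depth_um = shape_um[0]
    depth_window = 10.0  # µm half-window when matching a drawn depth

    cell_id = 0
    for cls_name, n_cls in zip(CLASS_ORDER, counts):
        morph: ClassMorphology = config.class_morphology[cls_name]
        for _ in range(n_cls):
            cell_id += 1
            ok = False
            # depth is drawn once per cell: overlap retries must not leak
            # probability mass toward less crowded strata. Only when a depth
            # stratum is locally saturated (inner retries exhausted) is the
            # depth redrawn, keeping the distortion rare and bounded.
            inner = max(40, config.max_placement_retries // 10)
            z_target = _draw_depth(rng, config, depth_um)
            for _attempt in range(config.max_placement_retries):
                if _attempt and _attempt % inner == 0:
                    z_target = _draw_depth(rng, config, depth_um)
                if cls_name in LINING_CLASSES:
                    lo = np.searchsorted(pool_z, z_target - depth_window)
                    hi = np.searchsorted(pool_z, z_target + depth_window)
                    if hi <= lo:
                        continue
                    sid, k = pool[int(rng.integers(lo, hi))]
                    pts = centerlines[sid]
                    center_on_line = pts[k]
                    tangent = pts[min(k + 1, len(pts) - 1)] - pts[max(k - 1, 0)]
                    tangent /= np.linalg.norm(tangent)
                    nu = _perpendicular_unit(rng, tangent)
                    center = center_on_line + (radii[sid] + morph.radial_offset_um) * nu
                    if morph.orientation == "tangent":
                        long_axis = tangent
                    elif morph.orientation == "circumferential":
                        long_axis = np.cross(tangent, nu)
                    else:
                        long_axis = _random_unit(rng)
                else:
                    center = np.array([z_target,
                                       rng.uniform(0.0, shape_um[1]),
                                       rng.uniform(0.0, shape_um[2])])
                    long_axis = _random_unit(rng)

                semi = np.asarray(morph.semi_axes_um) * np.clip(
                    1.0 + morph.jitter * rng.normal(size=3), 0.6, 1.6
                )
                semi = np.sort(semi)[::-1]
                rot = _orientation_matrix(rng, long_axis)
                vox = _ellipsoid_crop(center, semi, rot, vs, shape)
                if vox is None:
                    continue
                zz, yy, xx = vox
                if np.any(labels[zz, yy, xx] != 0):
                    continue
                dmin = vessel_dist[zz, yy, xx].min()
                if cls_name == "non_lining":
                    # whole nucleus clearly beyond the 1-µm lining band
                    if dmin < 2.5:
                        continue
                else:
                    # must satisfy the 1-µm lining rule with margin
                    if dmin > 0.5:
                        continue
                if _touches_existing(labels, zz, yy, xx, shape):
                    continue
                labels[zz, yy, xx] = cell_id
                classes[cell_id] = cls_name
                ok = True
                break
            if not ok:
                raise DegenerateConfigurationError(
                    f"could not place cell {cell_id} ({cls_name}) after retries"
                )
    return labels, classes


def _touches_existing(labels, zz, yy, xx, shape) -> bool:
    """True if any candidate voxel is 26-adjacent to an existing nucleus."""
    lo = np.maximum([zz.min() - 1, yy.min() - 1, xx.min() - 1], 0)
    hi = np.minimum([zz.max() + 2, yy.max() + 2, xx.max() + 2], shape)
    crop = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not crop.any():
        return False
    cand = np.zeros(crop.shape, bool)
    cand[zz - lo[0], yy - lo[1], xx - lo[2]] = True
    grown = ndi.binary_dilation(cand, structure=np.ones((3, 3, 3), bool))
    return bool(np.any(grown & (crop > 0)))


def _render(rng, config, truth, centerlines):
    """Render both timepoints from the geometric truth."""
    o = config.optics
    shape = truth.cell_label_volume.shape
    vs = truth.voxel_size
    m = np.asarray(o.mixing, float)

    lipid = np.full(shape, o.tissue_lipid, np.float32)
    protein = np.full(shape, o.tissue_protein, np.float32)
    lipid[truth.myelin_mask] *= o.myelin_lipid_factor
    nuc = truth.cell_label_volume > 0
    lipid[nuc] *= o.nucleus_lipid_factor
    protein[nuc] *= o.nucleus_protein_factor
    base = {
        2850: m[0, 0] * lipid + m[0, 1] * protein,
        2930: m[1, 0] * lipid + m[1, 1] * protein,
    }

    z_um = (np.arange(shape[0]) + 0.5) * vs[0]
    atten = np.exp(-z_um / config.attenuation_length_um).astype(np.float32)[:, None, None]

    # stalled-lumen content blobs are geometry: identical at both timepoints
    blob_tam = np.zeros(shape, np.float32)
    blob_protein = np.zeros(shape, np.float32)
    for sid in sorted(truth.vessel_states):
        st = truth.vessel_states[sid]
        if st.get("content") in (None, "", "none"):
            continue
        _add_content_blobs(rng, truth, centerlines.get(sid), sid, st["content"],
                           blob_tam, blob_protein, o, vs)

    vols = []
    for tp in (1, 2):
        ch = {wn: base[wn].copy() for wn in base}
        for sid in sorted(truth.vessel_states):
            st = truth.vessel_states[sid]
            state = st["state_t1"] if tp == 1 else st["state_t2"]
            lumen = (truth.vessel_label_volume == sid) & ~nuc
            if not lumen.any():
                continue
            if state == "flowing":
                bbox = ndi.find_objects(lumen.astype(np.int8))[0]
                spk = _smooth_speckle(rng, tuple(s.stop - s.start for s in bbox), o.speckle_sd)
                full = np.ones(shape, np.float32)
                full[bbox] = spk
                for wn in ch:
                    ch[wn][lumen] = (o.lumen_srs_factor * ch[wn][lumen]
                                     + o.tam_amplitude * full[lumen])
            else:
                for wn in ch:
                    ch[wn][lumen] = o.stalled_srs_factor * ch[wn][lumen]
        ch[2850] = ch[2850] + blob_tam + m[0, 1] * blob_protein
        ch[2930] = ch[2930] + blob_tam + m[1, 1] * blob_protein

        for wn in ch:
            img = ch[wn] * atten + o.background_offset
            if config.noise_gaussian_sd > 0:
                img = img + rng.normal(0.0, config.noise_gaussian_sd, shape)
            if config.noise_poisson_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) * config.noise_poisson_scale
                                  ).astype(np.float32) / config.noise_poisson_scale
            ch[wn] = np.clip(img, 0.0, None).astype(np.float32)

        vols.append(SnarfVolume(channels=ch, voxel_size=tuple(vs), timepoint=tp))
    return vols


def _add_content_blobs(rng, truth, pts, sid, content, blob_tam, blob_protein, o, vs):
    """Place stuck RBC/WBC blobs along a persistently stalled lumen."""
    if pts is None or len(pts) < 4:
        return
    lumen = (truth.vessel_label_volume == sid) & (truth.cell_label_volume == 0)
    if not lumen.any():
        return
    want_wbc = content in ("wbc_only", "both")
    want_rbc = content in ("rbc_only", "both")
    shape = lumen.shape
    zz = np.indices(shape).reshape(3, -1).T * np.asarray(vs) + np.asarray(vs) / 2

    def _stamp(kind):
        k = rng.integers(2, len(pts) - 2)
        center = pts[k]
        radius = 3.0 if kind == "wbc" else 2.2
        lo = np.maximum(np.floor((center - radius) / vs).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((center + radius) / vs).astype(int) + 2, shape)
        sl = tuple(slice(lo[a], hi[a]) for a in range(3))
        grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        coords = np.stack([g * vs[a] + vs[a] / 2 for a, g in enumerate(grids)], axis=-1)
        inside = np.sum((coords - center) ** 2, axis=-1) <= radius ** 2
        inside &= lumen[sl]
        if kind == "wbc":
            blob_protein[sl][inside] += o.wbc_protein
        else:
            blob_tam[sl][inside] += o.rbc_tam

    if want_rbc:
        for _ in range(int(rng.integers(1, 3))):
            _stamp("rbc")
    if want_wbc:
        _stamp("wbc")


# --------------------------------------------------------------------------
# depth profile


def density_profile(truth: GroundTruth, bin_um: float) -> pd.DataFrame:
    """Cell-centroid counts per depth bin (half-open bins ``[z, z+bin)``).

    Returns a DataFrame with columns ``z_um`` (bin lower edge), ``count`` and
    ``density_per_um`` (count / bin width).
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    vs = truth.voxel_size
    depth_um = truth.cell_label_volume.shape[0] * vs[0]
    edges = np.arange(0.0, depth_um + bin_um, bin_um)
    ids = sorted(set(np.unique(truth.cell_label_volume)) - {0})
    if ids:
        centroids = ndi.center_of_mass(
            truth.cell_label_volume > 0, truth.cell_label_volume, ids
        )
        z = np.asarray([c[0] for c in centroids]) * vs[0] + vs[0] / 2
        counts, _ = np.histogram(z, bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, int)
    return pd.DataFrame(
        {"z_um": edges[:-1], "count": counts, "density_per_um": counts / bin_um}
    )


# --------------------------------------------------------------------------
# on-disk scene layout


def save_scene(outdir: str | Path, vol_t1: SnarfVolume, vol_t2: SnarfVolume,
               truth: GroundTruth, config: SceneConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vol_t1.save(outdir)
    vol_t2.save(outdir)
    truth.save(outdir / "truth")
    if config is not None:
        config.to_yaml(outdir / "scene_config.yaml")


def load_scene(indir: str | Path) -> tuple[SnarfVolume, SnarfVolume, GroundTruth | None]:
    indir = Path(indir)
    v1 = SnarfVolume.load(indir, timepoint=1)
    v2 = SnarfVolume.load(indir, timepoint=2)
    truth = GroundTruth.load(indir / "truth") if (indir / "truth").exists() else None
    return v1, v2, truth
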