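"""Capillary-lining stratification and the ten per-cell features.

A cell is *capillary-lining* when any part of it lies within 1 µm of a
capillary; cells further away are non-lining. For each cell the feature
vector comprises seven morphological quantities — sphericity, equivalent
spherical diameter (ESD), volume, ellipsoid short axis (ESA), ellipsoid
long axis (ELA), surface area (SA) and ellipsoid second-longest axis
(ESLA) — and three relational ones: percent volume overlap with the
capillary, distance from the cell centroid to the capillary surface, and
the angle between the principal axes of cell and capillary within a 5 µm
cube around the cell centroid (direction, folded to [0, 90] degrees).

Formulas: volume = voxel count x voxel volume; SA from a marching-cubes
mesh; sphericity = pi^(1/3) (6V)^(2/3) / SA; ESD = (6V/pi)^(1/3); ellipsoid
axes 2 sqrt(5 lambda_i) from the eigenvalues of the voxel-coordinate
covariance in µm² (exact for a uniform solid ellipsoid).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure

#: Canonical feature column order of the per-cell table (classifier contract).
FEATURES = [
    "sphericity", "esd", "volume", "esa", "ela", "surface_area", "esla",
    "pct_overlap", "distance", "direction",
]

META_COLUMNS = ["cell_id", "lining", "nearest_capillary", "flag_small",
                "flag_direction"]


def sphericity_from(volume: float, surface_area: float) -> float:
    """Sphericity pi^(1/3) (6V)^(2/3) / SA; 1 for a perfect sphere."""
    if surface_area <= 0:
        raise ValueError("surface area must be positive")
    return float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area)


def equivalent_spherical_diameter(volume: float) -> float:
    return float((6.0 * volume / np.pi) ** (1 / 3))


def ellipsoid_axes(coords_um: np.ndarray) -> tuple[float, float, float]:
    """(ela, esla, esa): sorted axis lengths 2 sqrt(5 lambda) of the fitted
    uniform-density ellipsoid, from the covariance of voxel coordinates."""
    cov = np.cov(coords_um.T, bias=True)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    ax = 2.0 * np.sqrt(5.0 * eig)
    return float(ax[0]), float(ax[1]), float(ax[2])


def _coords_um(mask_idx: tuple[np.ndarray, ...], voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, float)
    return np.stack([(mask_idx[a] + 0.5) * vs[a] for a in range(3)], axis=1)


# --------------------------------------------------------------------------
# lining


def _object_slices(labels: np.ndarray) -> dict[int, tuple[slice, ...]]:
    """Bounding-box slice per label id (one pass over the volume)."""
    out = {}
    for i, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is not None:
            out[i] = sl
    return out


def classify_lining(
    cell_labels: np.ndarray,
    capillary_labels: np.ndarray,
    voxel_size,
    threshold_um: float = 1.0,
) -> pd.DataFrame:
    """Per-cell lining flag and nearest capillary id.

    A cell is lining iff the minimum Euclidean distance (µm) from any of its
    voxels to a capillary voxel is <= ``threshold_um``. The nearest capillary
    id is read at the closest capillary voxel; when several capillaries tie,
    the distance-transform assignment is deterministic for a fixed input.
    """
    vs = np.asarray(voxel_size, float)
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    if not capillary_labels.any():
        warnings.warn("no capillaries present; all cells classified non-lining")
        return pd.DataFrame(
            {"cell_id": ids, "lining": False, "nearest_capillary": 0,
             "min_distance_um": np.inf}
        )
    dist, idx = ndi.distance_transform_edt(
        capillary_labels == 0, sampling=vs, return_indices=True
    )
    nearest = capillary_labels[idx[0], idx[1], idx[2]]
    slices = _object_slices(cell_labels)
    rows = []
    for cid in ids:
        sl = slices.get(int(cid))
        sel = (cell_labels[sl] == cid) if sl else (cell_labels == cid)
        d = dist[sl][sel] if sl else dist[sel]
        k = int(np.argmin(d))
        near = nearest[sl][sel][k] if sl else nearest[sel][k]
        rows.append({
            "cell_id": int(cid),
            "lining": bool(d[k] <= threshold_um),
            "nearest_capillary": int(near),
            "min_distance_um": float(d[k]),
        })
    return pd.DataFrame(rows)


def brute_force_lining(cell_labels, capillary_labels, voxel_size,
                       threshold_um: float = 1.0) -> dict[int, bool]:
    """All-pairs voxel-distance lining oracle (small volumes only)."""
    vs = np.asarray(voxel_size, float)
    cap = np.argwhere(capillary_labels > 0) * vs
    out = {}
    ids = np.unique(cell_labels)
    for cid in ids[ids > 0]:
        cell = np.argwhere(cell_labels == cid) * vs
        if cap.size == 0:
            out[int(cid)] = False
            continue
        d2 = ((cell[:, None, :] - cap[None, :, :]) ** 2).sum(-1)
        out[int(cid)] = bool(np.sqrt(d2.min()) <= threshold_um)
    return out


# --------------------------------------------------------------------------
# per-cell morphology


def morphological_features(
    cell_labels: np.ndarray,
    cell_id: int,
    voxel_size,
    min_voxels: int = 27,
    _slice: tuple[slice, ...] | None = None,
) -> dict:
    """Seven morphological features for one cell (see module docstring).

    Objects below ``min_voxels`` get ``flag_small=True``; their numbers are
    still reported but should be treated as unreliable. ``_slice`` is an
    optional precomputed bounding box to avoid a full-volume scan.
    """
    vs = np.asarray(voxel_size, float)
    region = cell_labels[_slice] if _slice is not None else cell_labels
    sel = region == cell_id
    if not sel.any():
        if _slice is not None:
            raise KeyError(f"cell id {cell_id} not in provided bounding box")
        raise KeyError(f"cell id {cell_id} not present")
    n_vox = int(sel.sum())
    volume = n_vox * float(np.prod(vs))

    sl = ndi.find_objects(sel.astype(np.int8))[0]
    crop = np.pad(sel[sl], 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(crop, level=0.5, spacing=tuple(vs))
    sa = float(measure.mesh_surface_area(verts, faces))

    idx = np.nonzero(sel)
    coords = _coords_um(idx, vs)  # features are translation-invariant
    ela, esla, esa = ellipsoid_axes(coords)

    return {
        "sphericity": sphericity_from(volume, sa),
        "esd": equivalent_spherical_diameter(volume),
        "volume": volume,
        "esa": esa,
        "ela": ela,
        "surface_area": sa,
        "esla": esla,
        "flag_small": n_vox < min_voxels,
    }


def overlap_and_distance(
    cell_labels: np.ndarray,
    capillary_labels: np.ndarray,
    cell_id: int,
    voxel_size,
    capillary_id: int | None = None,
    distance_map: np.ndarray | None = None,
    _slice: tuple[slice, ...] | None = None,
) -> tuple[float, float]:
    """(% volume overlap with the capillary mask, centroid-to-surface distance µm).

    Overlap uses the raw capillary mask (literal voxel intersection) of the
    nearest capillary when ``capillary_id`` is given, else of all
    capillaries. Distance is from the cell's center of mass to the closest
    capillary edge: the Euclidean distance transform of the capillary
    background sampled at the center-of-mass voxel — 0 when the centroid
    lies inside a capillary. Sub-voxel precision is not attempted. A
    precomputed ``distance_map`` (EDT to any capillary, µm) avoids repeating
    the transform across cells.
    """
    cells = cell_labels[_slice] if _slice is not None else cell_labels
    caps = capillary_labels[_slice] if _slice is not None else capillary_labels
    sel = cells == cell_id
    if not sel.any():
        raise KeyError(f"cell id {cell_id} not present")
    cap = caps > 0 if capillary_id is None else caps == capillary_id
    pct = 100.0 * float(np.logical_and(sel, cap).sum()) / float(sel.sum())
    if not capillary_labels.any():
        return pct, float("inf")
    vs = np.asarray(voxel_size, float)
    if distance_map is None:
        distance_map = ndi.distance_transform_edt(capillary_labels == 0, sampling=vs)
    com = np.asarray(ndi.center_of_mass(sel))
    if _slice is not None:
        com += np.asarray([s.start for s in _slice])
    voxel = tuple(int(round(c)) for c in com)
    voxel = tuple(np.clip(voxel, 0, np.asarray(cell_labels.shape) - 1))
    return pct, float(distance_map[voxel])


def direction_angle(
    cell_labels: np.ndarray,
    capillary_labels: np.ndarray,
    cell_id: int,
    voxel_size,
    cube_um: float = 5.0,
    capillary_id: int | None = None,
    min_voxels: int = 4,
    isotropy_tolerance: float = 1.05,
    _slice: tuple[slice, ...] | None = None,
) -> tuple[float, bool]:
    """Angle (degrees, <= 90) between cell and capillary principal axes.

    Both objects are restricted to a cube of side ``cube_um`` centered on the
    cell's center of mass and modeled as ellipsoids via their voxel
    covariance; the angle between top eigenvectors is folded to [0, 90] by
    taking |cos|. If no capillary voxel falls inside the cube the window is
    expanded to twice the side (flagged); if either object is still absent or
    its in-cube covariance is isotropic (no defined long axis), 90 degrees is
    imputed — absence of alignment evidence must not mimic the aligned
    (endothelial-like) signature — and the flag is set.

    Returns (angle_degrees, flagged).
    """
    vs = np.asarray(voxel_size, float)
    region = cell_labels[_slice] if _slice is not None else cell_labels
    sel_crop = region == cell_id
    if not sel_crop.any():
        raise KeyError(f"cell id {cell_id} not present")
    com = np.asarray(ndi.center_of_mass(sel_crop))
    if _slice is not None:
        com += np.asarray([s.start for s in _slice])

    def _window(half_um):
        half = np.maximum(1, np.round(half_um / vs).astype(int))
        lo = np.maximum(np.round(com).astype(int) - half, 0)
        hi = np.minimum(np.round(com).astype(int) + half + 1,
                        np.asarray(cell_labels.shape))
        return tuple(slice(lo[a], hi[a]) for a in range(3))

    win = _window(np.full(3, cube_um / 2.0))
    flagged = False
    cap_win = capillary_labels[win]
    cap = (cap_win > 0) if capillary_id is None else (cap_win == capillary_id)
    if not cap.any():
        win = _window(np.full(3, cube_um))  # expanded 2x window
        cap_win = capillary_labels[win]
        cap = (cap_win > 0) if capillary_id is None else (cap_win == capillary_id)
        flagged = True

    def _axis(mask_crop):
        idx = np.nonzero(mask_crop)
        if idx[0].size < min_voxels:
            return None
        coords = _coords_um(idx, vs)
        cov = np.cov(coords.T, bias=True)
        w, v = np.linalg.eigh(cov)
        if w[-1] <= 0 or (w[-2] > 0 and w[-1] / max(w[-2], 1e-12) < isotropy_tolerance):
            return None  # isotropic: no meaningful long axis
        return v[:, -1]

    u = _axis(cell_labels[win] == cell_id)
    v = _axis(cap)
    if u is None or v is None:
        return 90.0, True
    cosang = abs(float(np.dot(u, v)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return angle, flagged


# --------------------------------------------------------------------------
# feature table


def build_feature_table(
    cell_labels: np.ndarray,
    capillary_labels: np.ndarray,
    voxel_size,
    lining_threshold_um: float = 1.0,
    true_classes: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-cell table: ids/flags, the ten features in canonical
    order, and (optionally) ground-truth classes. This CSV layout is the
    classifier's input contract."""
    lining = classify_lining(cell_labels, capillary_labels, voxel_size,
                             lining_threshold_um)
    if capillary_labels.any():
        dist_map = ndi.distance_transform_edt(
            capillary_labels == 0, sampling=np.asarray(voxel_size, float))
    else:
        dist_map = None
    slices = _object_slices(cell_labels)
    rows = []
    for rec in lining.itertuples():
        cid = int(rec.cell_id)
        sl = slices.get(cid)
        feats = morphological_features(cell_labels, cid, voxel_size, _slice=sl)
        cap_id = int(rec.nearest_capillary) or None
        pct, dist = overlap_and_distance(cell_labels, capillary_labels, cid,
                                         voxel_size, capillary_id=cap_id,
                                         distance_map=dist_map, _slice=sl)
        if rec.lining:
            ang, ang_flag = direction_angle(cell_labels, capillary_labels, cid,
                                            voxel_size, capillary_id=cap_id,
                                            _slice=sl)
        else:
            ang, ang_flag = 90.0, True
        row = {
            "cell_id": cid,
            "lining": bool(rec.lining),
            "nearest_capillary": int(rec.nearest_capillary),
            "flag_small": bool(feats.pop("flag_small")),
            "flag_direction": bool(ang_flag),
        }
        row.update(feats)
        row["pct_overlap"] = pct
        row["distance"] = dist if np.isfinite(dist) else -1.0
        row["direction"] = ang
        if true_classes is not None:
            row["true_class"] = true_classes.get(cid, "")
        rows.append(row)
    cols = META_COLUMNS + FEATURES + (["true_class"] if true_classes is not None else [])
    return pd.DataFrame(rows, columns=cols)
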