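"""3D segmentation of cell nuclei and capillary segments.

Nuclei are dark, roughly convex holes in the (lipid-dominant) SRS tissue
signal; they are detected by local-contrast thresholding of the smoothed
lipid map, split with a marker-based watershed on the Euclidean distance
transform (markers from its h-maxima, so elongated nuclei keep a single
marker), and gated by equivalent spherical diameter. Capillaries are
obtained by skeletonizing the vessel mask, cutting the skeleton at branch
points and labeling each branch-wise segment; segments wider than the
capillary cutoff (default 10 µm diameter, the standard capillary
definition) are discarded. All geometric gates operate in µm.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import morphology
from skimage.morphology import extrema
from skimage.segmentation import watershed

from snarfpy.volume import write_stack

CONN26 = np.ones((3, 3, 3), bool)


@dataclasses.dataclass
class SegmentationResult:
    cell_labels: np.ndarray
    capillary_labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_stack(outdir / "cell_labels.tif", self.cell_labels.astype(np.uint16))
        write_stack(outdir / "capillary_labels.tif",
                    self.capillary_labels.astype(np.uint16))
        object_table(self.cell_labels, self.voxel_size).to_csv(
            outdir / "cells.csv", index=False)
        object_table(self.capillary_labels, self.voxel_size).to_csv(
            outdir / "capillaries.csv", index=False)


def object_table(labels: np.ndarray, voxel_size) -> pd.DataFrame:
    """Per-object id, centroid (µm) and volume (µm³)."""
    vs = np.asarray(voxel_size, float)
    ids = sorted(set(np.unique(labels)) - {0})
    rows = []
    if ids:
        centroids = ndi.center_of_mass(labels > 0, labels, ids)
        counts = ndi.sum_labels(np.ones_like(labels), labels, ids)
        for oid, c, n in zip(ids, centroids, counts):
            rows.append({
                "id": int(oid),
                "centroid_z_um": (c[0] + 0.5) * vs[0],
                "centroid_y_um": (c[1] + 0.5) * vs[1],
                "centroid_x_um": (c[2] + 0.5) * vs[2],
                "volume_um3": float(n) * float(np.prod(vs)),
            })
    return pd.DataFrame(rows, columns=["id", "centroid_z_um", "centroid_y_um",
                                       "centroid_x_um", "volume_um3"])


# --------------------------------------------------------------------------
# nuclei


def segment_cells(
    lipid_map: np.ndarray,
    protein_map: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_diameter_um: float = 4.0,
    max_diameter_um: float = 16.0,
    darkness_threshold: float = 0.25,
    smooth_sigma_um: float = 0.6,
    background_sigma_um: float = 12.0,
    marker_h_um: float | None = None,
) -> np.ndarray:
    """Label dark 3D nuclei in the tissue maps.

    Darkness is measured relative to a large-scale Gaussian estimate of the
    local background, which cancels depth attenuation and global intensity
    rescaling: a voxel is nucleus candidate where
    ``(background - intensity) / background > darkness_threshold``.
    Touching nuclei are split by watershed on the distance transform with
    h-maxima markers; objects outside the [min, max] equivalent-diameter
    gate are removed. Labels are relabeled contiguously, ordered by raster
    position of the object's first voxel (deterministic).
    """
    vs = np.asarray(voxel_size, float)
    intensity = np.asarray(lipid_map, float) + 0.5 * np.asarray(protein_map, float)
    smoothed = ndi.gaussian_filter(intensity, smooth_sigma_um / vs)
    background = ndi.gaussian_filter(intensity, background_sigma_um / vs)
    darkness = (background - smoothed) / np.maximum(background, 1e-9)
    mask = darkness > darkness_threshold
    if not mask.any():
        return np.zeros(intensity.shape, np.int32)

    min_r = min_diameter_um / 2.0
    min_vox = max(8, int(round((4.0 / 3.0) * np.pi * min_r ** 3 / np.prod(vs) * 0.3)))
    lab, n = ndi.label(mask, structure=CONN26)
    if n:
        sizes = np.bincount(lab.ravel())
        mask = sizes[lab] >= min_vox
        mask[lab == 0] = False
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(intensity.shape, np.int32)

    edt = ndi.distance_transform_edt(mask, sampling=vs)
    # marker depth: deep enough that one elongated nucleus keeps one marker,
    # shallow enough that touching round nuclei still separate
    h = marker_h_um if marker_h_um is not None else max(0.5, 0.75 * min_r)
    peaks = extrema.h_maxima(edt, h)
    # discretized EDT ties can mark several voxels of one peak; one dilation
    # step merges tie clusters without bridging distinct nuclei
    peaks = ndi.binary_dilation(peaks, structure=CONN26)
    # thin objects whose EDT never rises h above its surroundings produce no
    # h-maximum; seed every markerless component at its deepest voxel
    comp, n_comp = ndi.label(mask, structure=CONN26)
    if n_comp:
        has_marker = np.zeros(n_comp + 1, bool)
        has_marker[np.unique(comp[peaks])] = True
        for ci in range(1, n_comp + 1):
            if not has_marker[ci]:
                sel = comp == ci
                flat = np.argmax(np.where(sel, edt, -1.0))
                peaks[np.unravel_index(flat, mask.shape)] = True
    markers, n_markers = ndi.label(peaks, structure=CONN26)
    if n_markers == 0:
        markers = comp
    labels = watershed(-edt, markers=markers, mask=mask)

    # diameter gate in physical units
    voxel_vol = float(np.prod(vs))
    ids = np.unique(labels)
    ids = ids[ids > 0]
    counts = ndi.sum_labels(np.ones_like(labels), labels, ids)
    esd = (6.0 * counts * voxel_vol / np.pi) ** (1.0 / 3.0)
    bad = ids[(esd < min_diameter_um) | (esd > max_diameter_um)]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    return relabel_sequential(labels)


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels to 1..n in order of first raster occurrence."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    order = [i for _, i in sorted((f, i) for i, f in zip(ids, first) if i != 0)]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels]


# --------------------------------------------------------------------------
# capillaries


def segment_capillaries(
    vessel_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    max_capillary_width_um: float = 10.0,
    min_skeleton_voxels: int = 4,
) -> np.ndarray:
    """Branch-wise capillary segment labels from a binary vessel mask.

    The mask is skeletonized; skeleton voxels with more than two 26-connected
    skeleton neighbours are branch points and are removed, splitting the
    skeleton into branch segments. Every vessel voxel is then assigned to its
    nearest branch. Segments whose mean width (2x the distance-transform
    value along the branch) exceeds ``max_capillary_width_um`` are discarded
    — they are not capillaries.
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any():
        return np.zeros(vessel_mask.shape, np.int32)
    vs = np.asarray(voxel_size, float)

    skel = morphology.skeletonize(vessel_mask)
    if not skel.any():
        # degenerate blob: single segment
        lab, _ = ndi.label(vessel_mask, structure=CONN26)
        return relabel_sequential(lab)

    neighbours = ndi.convolve(skel.astype(np.int8), CONN26.astype(np.int8),
                              mode="constant") - 1
    branch_points = skel & (neighbours > 2)
    branches = skel & ~branch_points
    seg, n = ndi.label(branches, structure=CONN26)
    # drop tiny spur branches, then relabel
    if n:
        sizes = np.bincount(seg.ravel())
        small = np.nonzero(sizes < min_skeleton_voxels)[0]
        small = small[small > 0]
        if small.size:
            seg[np.isin(seg, small)] = 0
    if not (seg > 0).any():
        lab, _ = ndi.label(vessel_mask, structure=CONN26)
        return relabel_sequential(lab)

    # assign every vessel voxel to the nearest branch skeleton voxel
    _, idx = ndi.distance_transform_edt(seg == 0, sampling=vs, return_indices=True)
    labels = np.where(vessel_mask, seg[idx[0], idx[1], idx[2]], 0).astype(np.int32)

    # width gate
    edt = ndi.distance_transform_edt(vessel_mask, sampling=vs)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for oid in ids:
        on_skel = (seg == oid)
        width = 2.0 * float(edt[on_skel].mean()) if on_skel.any() else 0.0
        if width > max_capillary_width_um:
            labels[labels == oid] = 0
    return relabel_sequential(labels)


# --------------------------------------------------------------------------
# label matching (oracle support / end-to-end evaluation)


def match_labels(pred: np.ndarray, truth: np.ndarray, min_overlap: float = 0.5
                 ) -> dict[int, int]:
    """Map each predicted object id to the truth id covering the majority of
    its voxels (>= ``min_overlap`` of the predicted object), else to 0."""
    out: dict[int, int] = {}
    for pid, sl in enumerate(ndi.find_objects(pred), start=1):
        if sl is None:
            continue
        sel = pred[sl] == pid
        vals, counts = np.unique(truth[sl][sel], return_counts=True)
        best = int(vals[np.argmax(counts)])
        frac = counts.max() / sel.sum()
        out[int(pid)] = best if (best != 0 and frac >= min_overlap) else 0
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
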