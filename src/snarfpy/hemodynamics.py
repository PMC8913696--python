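"""Stalled-capillary detection, persistence, widths and luminal contents.

Flowing capillaries carry strong, frame-to-frame-varying red-blood-cell
contrast; stalled capillaries show a marked decrease of the luminal
protein/lipid SRS signal and are static between the two acquisitions
(nominally 15 min apart). A stall present at both timepoints is
*persistent*, at exactly one *transient*. For persistent stalls that are
fully contained in the imaging volume, luminal blobs are stratified as WBC
(protein-SRS-dominant, high 2930/2850 ratio) or RBC (hemoglobin absorption,
near-equal in both channels) and the lumen is categorized as WBC-only,
RBC-only, both, or none.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import morphology

from snarfpy.volume import SnarfVolume

EPS = 1e-9
CONTENT_CATEGORIES = ("wbc_only", "rbc_only", "both", "none")


@dataclasses.dataclass
class LuminalCell:
    position_um: tuple[float, float, float]
    spectral_ratio: float   # ch2930 / ch2850 within the blob
    type: str               # "RBC" | "WBC"


@dataclasses.dataclass
class VesselSegment:
    segment_id: int
    mean_width_um: float
    state_t1: str
    state_t2: str
    persistence: str
    fully_contained: bool
    content: str | None = None
    n_voxels: int = 0
    width_flagged: bool = False


def persistence(state_t1: str, state_t2: str) -> str:
    """flowing / transient / persistent from the two per-timepoint states."""
    stalled = (state_t1 == "stalled", state_t2 == "stalled")
    if all(stalled):
        return "persistent"
    if any(stalled):
        return "transient"
    return "flowing"


# --------------------------------------------------------------------------
# flow state


def _lumen_and_shell(segment_mask, all_vessels, voxel_size, shell_um=3.0):
    vs = np.asarray(voxel_size, float)
    r = max(1, int(round(shell_um / vs.min())))
    shell = ndi.binary_dilation(segment_mask, structure=morphology.ball(r))
    shell &= ~all_vessels
    return shell


def slice_background(mean_channel: np.ndarray, quantile: float = 0.01) -> np.ndarray:
    """Per-slice dark-floor estimate (depth-dependent background level)."""
    flat = mean_channel.reshape(mean_channel.shape[0], -1)
    return np.quantile(flat, quantile, axis=1)


def classify_flow(
    segment_mask: np.ndarray,
    vol_t: SnarfVolume,
    vol_other: SnarfVolume,
    all_vessels: np.ndarray | None = None,
    srs_drop_fraction: float = 0.7,
    variance_threshold: float = 0.3,
    min_voxels: int = 10,
    background_t: np.ndarray | None = None,
) -> str:
    """Flow state of one segment at the timepoint of ``vol_t``.

    Stalled iff the luminal temporal variance attributable to this frame is
    below ``variance_threshold`` and the background-corrected mean luminal
    intensity is below ``srs_drop_fraction`` times the background-corrected
    perivascular tissue mean. The per-slice dark floor is subtracted from
    both so that depth attenuation over a constant detection background
    does not wash out the luminal SRS decrease. With only two frames,
    inter-frame variation is attributed to the *brighter* frame (that is
    where flowing-RBC texture lives); the dimmer frame of a transient stall
    therefore keeps zero flow evidence and is correctly called stalled,
    while the flowing frame is not.
    """
    segment_mask = np.asarray(segment_mask, bool)
    if segment_mask.sum() < min_voxels:
        raise ValueError(f"segment below {min_voxels} voxels")
    if all_vessels is None:
        all_vessels = segment_mask
    shell = _lumen_and_shell(segment_mask, all_vessels, vol_t.voxel_size)

    m_t = vol_t.mean_channel()
    m_o = vol_other.mean_channel()
    if background_t is None:
        background_t = slice_background(m_t)
    zz = np.nonzero(segment_mask)[0]
    b = float(background_t[zz].mean())
    lumen_t = float(m_t[segment_mask].mean())
    lumen_o = float(m_o[segment_mask].mean())
    shell_t = float(m_t[shell].mean()) if shell.any() else lumen_t
    b = min(b, 0.95 * shell_t)  # keep the corrected tissue level positive

    diff = m_t[segment_mask] - m_o[segment_mask]
    nmsd = float(np.mean(diff**2)) / max(0.5 * (lumen_t + lumen_o), EPS) ** 2
    variance_t = nmsd if lumen_t > lumen_o else 0.0

    # dimness is judged on the luminal median: static stuck cells (bright
    # blobs) or nucleus bulges (dark) must not mask the state of the lumen
    lumen_med = float(np.median(m_t[segment_mask]))
    dim = (lumen_med - b) < srs_drop_fraction * max(shell_t - b, EPS)
    return "stalled" if (variance_t < variance_threshold and dim) else "flowing"


# --------------------------------------------------------------------------
# width


def vessel_width(
    segment_mask: np.ndarray,
    voxel_size,
    min_centerline_voxels: int = 3,
) -> tuple[float, bool]:
    """Mean width (µm) = mean over centerline voxels of 2x the distance-
    transform value. Degenerate segments (too short to skeletonize) fall
    back to the equivalent diameter, flagged. Returns (width, flagged)."""
    segment_mask = np.asarray(segment_mask, bool)
    vs = np.asarray(voxel_size, float)
    if not segment_mask.any():
        raise ValueError("empty segment")
    edt = ndi.distance_transform_edt(segment_mask, sampling=vs)
    skel = morphology.skeletonize(segment_mask)
    if skel.sum() >= min_centerline_voxels:
        return 2.0 * float(edt[skel].mean()), False
    vol = segment_mask.sum() * float(np.prod(vs))
    return float((6.0 * vol / np.pi) ** (1 / 3)), True


# --------------------------------------------------------------------------
# luminal contents


def stratify_luminal_cells(
    segment_mask: np.ndarray,
    vol: SnarfVolume,
    ratio_threshold: float = 2.0,
    blob_threshold: float = 1.5,
    min_blob_um3: float = 8.0,
) -> tuple[list[LuminalCell], str]:
    """Detect luminal blobs in a (persistently stalled, fully contained)
    segment and type each as WBC or RBC by its 2930/2850 spectral ratio.

    Blobs are connected regions whose mean-channel intensity exceeds
    ``blob_threshold`` times the luminal background (median of the lumen).
    A blob with ratio > ``ratio_threshold`` is protein-dominant (WBC), else
    hemoglobin-flat (RBC). The default threshold is the midpoint between
    the two spectral signatures of the synthetic optical model; on real
    data it must be calibrated. Returns (cells, category)."""
    segment_mask = np.asarray(segment_mask, bool)
    vs = np.asarray(vol.voxel_size, float)
    mean = vol.mean_channel()
    lumen_bg = float(np.median(mean[segment_mask]))
    blobs = segment_mask & (mean > blob_threshold * max(lumen_bg, EPS))
    lab, n = ndi.label(blobs, structure=np.ones((3, 3, 3), bool))
    min_vox = max(1, int(round(min_blob_um3 / np.prod(vs))))
    cells: list[LuminalCell] = []
    a = vol.channel(2850)
    b = vol.channel(2930)
    for i in range(1, n + 1):
        sel = lab == i
        if sel.sum() < min_vox:
            continue
        ratio = float(b[sel].mean()) / max(float(a[sel].mean()), EPS)
        com = ndi.center_of_mass(sel)
        cells.append(
            LuminalCell(
                position_um=tuple((np.asarray(com) + 0.5) * vs),
                spectral_ratio=ratio,
                type="WBC" if ratio > ratio_threshold else "RBC",
            )
        )
    has_wbc = any(c.type == "WBC" for c in cells)
    has_rbc = any(c.type == "RBC" for c in cells)
    if has_wbc and has_rbc:
        category = "both"
    elif has_wbc:
        category = "wbc_only"
    elif has_rbc:
        category = "rbc_only"
    else:
        category = "none"
    return cells, category


# --------------------------------------------------------------------------
# per-volume segment analysis and census


def analyze_segments(
    capillary_labels: np.ndarray,
    vol_t1: SnarfVolume,
    vol_t2: SnarfVolume,
    srs_drop_fraction: float = 0.7,
    variance_threshold: float = 0.3,
    ratio_threshold: float = 2.0,
    min_voxels: int = 10,
) -> list[VesselSegment]:
    """Classify every capillary segment at both timepoints, measure widths,
    and stratify the contents of persistent, fully contained stalls."""
    vol_t1.check_registered(vol_t2)
    all_vessels = capillary_labels > 0
    bg1 = slice_background(vol_t1.mean_channel())
    bg2 = slice_background(vol_t2.mean_channel())
    border = np.zeros(capillary_labels.shape, bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    segments: list[VesselSegment] = []
    ids = np.unique(capillary_labels)
    for sid in ids[ids > 0]:
        sel = capillary_labels == sid
        if sel.sum() < min_voxels:
            continue
        contained = not bool(np.any(sel & border))
        st1 = classify_flow(sel, vol_t1, vol_t2, all_vessels,
                            srs_drop_fraction, variance_threshold, min_voxels,
                            background_t=bg1)
        st2 = classify_flow(sel, vol_t2, vol_t1, all_vessels,
                            srs_drop_fraction, variance_threshold, min_voxels,
                            background_t=bg2)
        pers = persistence(st1, st2)
        width, wflag = vessel_width(sel, vol_t1.voxel_size)
        content = None
        if pers == "persistent" and contained:
            _, content = stratify_luminal_cells(sel, vol_t1, ratio_threshold)
        segments.append(
            VesselSegment(
                segment_id=int(sid), mean_width_um=width, state_t1=st1,
                state_t2=st2, persistence=pers, fully_contained=contained,
                content=content, n_voxels=int(sel.sum()), width_flagged=wflag,
            )
        )
    return segments


def segments_table(segments: list[VesselSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "mean_width_um": s.mean_width_um,
                "state_t1": s.state_t1,
                "state_t2": s.state_t2,
                "persistence": s.persistence,
                "content": s.content or "",
                "fully_contained": s.fully_contained,
                "n_voxels": s.n_voxels,
            }
            for s in segments
        ],
        columns=["segment_id", "mean_width_um", "state_t1", "state_t2",
                 "persistence", "content", "fully_contained", "n_voxels"],
    )


def stall_census(segments: list[VesselSegment], animal: str = "animal-1") -> dict:
    """Stalled fractions (volume- and count-based, per timepoint), width
    arrays for the flowing-vs-stalled comparison, content frequencies and
    the fraction of persistent stalls containing at least one WBC."""
    if not segments:
        raise ValueError("no segments to census")
    vox = np.asarray([s.n_voxels for s in segments], float)
    out: dict = {"animal": animal, "n_segments": len(segments)}
    widths_flowing, widths_stalled = [], []
    for tp in ("state_t1", "state_t2"):
        stalled = np.asarray([getattr(s, tp) == "stalled" for s in segments])
        out[f"stalled_volume_fraction_{tp[-2:]}"] = (
            float(vox[stalled].sum() / vox.sum()) if vox.sum() else 0.0)
        out[f"stalled_count_fraction_{tp[-2:]}"] = float(stalled.mean())
    for s in segments:
        if s.persistence == "flowing":
            widths_flowing.append(s.mean_width_um)
        else:
            widths_stalled.append(s.mean_width_um)
    out["widths_flowing_um"] = widths_flowing
    out["widths_stalled_um"] = widths_stalled
    persistent = [s for s in segments if s.persistence == "persistent"
                  and s.fully_contained and s.content is not None]
    counts = {c: 0 for c in CONTENT_CATEGORIES}
    for s in persistent:
        counts[s.content] += 1
    out["content_counts"] = counts
    n_pers = len(persistent)
    n_wbc = counts["wbc_only"] + counts["both"]
    out["n_persistent_stalls"] = n_pers
    out["fraction_with_wbc"] = (n_wbc / n_pers) if n_pers else float("nan")
    return out
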