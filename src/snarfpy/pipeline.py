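"""End-to-end orchestration: simulate -> separate -> segment -> features ->
classify -> hemodynamics -> report.

Each stage reads the previous stage's files and writes its own under one run
directory, so every stage is independently re-runnable on prior outputs.
A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` (documented, deterministic), and a
run manifest records the config snapshot, seeds, thresholds actually used,
file hashes and timings. With a fixed seed all data outputs (TIFF/CSV/JSON
report) are byte-reproducible; only the manifest's timing block varies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from snarfpy import classifier as clf
from snarfpy import hemodynamics as hemo
from snarfpy import morphometry, scene, segmentation, separation
from snarfpy.volume import SnarfVolume, read_stack, write_stack

log = logging.getLogger("snarfpy")

STAGES = ("scene", "separation", "segmentation", "features", "classifier",
          "hemodynamics")


def default_pipeline_config() -> dict:
    """Full default config; every threshold a stage uses appears here."""
    return {
        "scene": dataclasses.asdict(scene.SceneConfig()),
        "separation": {
            "intensity_quantile": 0.90,
            "flatness_tolerance": 0.25,
            "variance_threshold": 0.3,
            "min_component_um3": 150.0,
            "closing_radius_um": 2.0,
            "mixing": [[1.0, 0.2], [0.45, 1.0]],
            "denoise": "none",
            "myelin_tubularity_threshold": 0.2,
            "myelin_min_length_um": 10.0,
            "myelin_radius_um": 1.0,
        },
        "segmentation": {
            "min_diameter_um": 4.0,
            "max_diameter_um": 16.0,
            "darkness_threshold": 0.25,
            "max_capillary_width_um": 10.0,
        },
        "morphometry": {"lining_threshold_um": 1.0, "cube_um": 5.0},
        "classifier": {"n_trees": 20, "split": 0.7, "n_repeats": 20,
                       "importance": "impurity"},
        "hemodynamics": {"srs_drop_fraction": 0.7, "variance_threshold": 0.3,
                         "ratio_threshold": 2.0},
    }


def load_pipeline_config(path: str | Path | None) -> dict:
    cfg = default_pipeline_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, values in user.items():
            if not isinstance(values, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            cfg[section].update(values)
    return cfg


def fan_out_seeds(seed: int, n: int = len(STAGES)) -> dict[str, int]:
    """Derive one deterministic 31-bit seed per stage from the global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return {name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> None:
    sc = scene.SceneConfig.from_dict({**cfg["scene"], "seed": seed})
    v1, v2, truth = scene.generate_scene(sc)
    scene.save_scene(outdir / "scene", v1, v2, truth, config=sc)
    prof = scene.density_profile(truth, bin_um=10.0)
    prof.to_csv(outdir / "scene" / "density_profile.csv", index=False)
    log.info("simulate: %d cells, %d vessel segments",
             len(truth.cell_classes), len(truth.vessel_states))


def stage_separate(cfg: dict, outdir: Path) -> None:
    sep = cfg["separation"]
    v1, v2, _ = scene.load_scene(outdir / "scene")
    if sep["denoise"] != "none":
        v1 = separation.denoise(v1, sep["denoise"])
        v2 = separation.denoise(v2, sep["denoise"])
    vessels = separation.extract_vessels(
        v1, v2,
        intensity_quantile=sep["intensity_quantile"],
        flatness_tolerance=sep["flatness_tolerance"],
        variance_threshold=sep["variance_threshold"],
        min_component_um3=sep["min_component_um3"],
        closing_radius_um=sep["closing_radius_um"],
    )
    model = separation.UnmixingModel(np.asarray(sep["mixing"], float))
    lipid, protein, residual = separation.unmix(v1, model, vessels)
    myelin = separation.extract_myelin(
        lipid, v1.voxel_size,
        tubularity_threshold=sep["myelin_tubularity_threshold"],
        min_length_um=sep["myelin_min_length_um"],
        radius_um=sep["myelin_radius_um"],
        vessel_mask=vessels,
    )
    d = outdir / "separation"
    d.mkdir(parents=True, exist_ok=True)
    write_stack(d / "vessel_mask.tif", vessels.astype(np.uint8))
    write_stack(d / "lipid.tif", lipid.astype(np.float32))
    write_stack(d / "protein.tif", protein.astype(np.float32))
    write_stack(d / "myelin_mask.tif", myelin.astype(np.uint8))
    write_stack(d / "residual.tif", residual.astype(np.float32))
    profile, limits = separation.sbr_depth_profile(v1)
    profile.to_csv(d / "sbr_profile.csv", index=False)
    (d / "depth_limits.json").write_text(json.dumps(
        {str(k): v for k, v in limits.items()}, indent=2, sort_keys=True))
    log.info("separate: vessel voxels=%d, depth limits=%s", int(vessels.sum()), limits)


def stage_segment(cfg: dict, outdir: Path) -> None:
    seg = cfg["segmentation"]
    v1 = SnarfVolume.load(outdir / "scene", timepoint=1)
    lipid = read_stack(outdir / "separation" / "lipid.tif")
    protein = read_stack(outdir / "separation" / "protein.tif")
    vessels = read_stack(outdir / "separation" / "vessel_mask.tif").astype(bool)
    cells = segmentation.segment_cells(
        lipid, protein, v1.voxel_size,
        min_diameter_um=seg["min_diameter_um"],
        max_diameter_um=seg["max_diameter_um"],
        darkness_threshold=seg["darkness_threshold"],
    )
    caps = segmentation.segment_capillaries(
        vessels, v1.voxel_size,
        max_capillary_width_um=seg["max_capillary_width_um"],
    )
    segmentation.SegmentationResult(cells, caps, v1.voxel_size).save(
        outdir / "segmentation")
    log.info("segment: %d cells, %d capillary segments",
             int(cells.max()), int(caps.max()))


def stage_features(cfg: dict, outdir: Path) -> None:
    v1 = SnarfVolume.load(outdir / "scene", timepoint=1)
    cells = read_stack(outdir / "segmentation" / "cell_labels.tif").astype(np.int32)
    caps = read_stack(outdir / "segmentation" / "capillary_labels.tif").astype(np.int32)
    truth_dir = outdir / "scene" / "truth"
    true_classes = None
    if truth_dir.exists():
        truth = scene.GroundTruth.load(truth_dir)
        matches = segmentation.match_labels(cells, truth.cell_label_volume)
        true_classes = {cid: truth.cell_classes.get(tid, "")
                        for cid, tid in matches.items() if tid}
    table = morphometry.build_feature_table(
        cells, caps, v1.voxel_size,
        lining_threshold_um=cfg["morphometry"]["lining_threshold_um"],
        true_classes=true_classes,
    )
    d = outdir / "features"
    d.mkdir(parents=True, exist_ok=True)
    table.to_csv(d / "features.csv", index=False)
    log.info("features: %d cells, %d lining", len(table), int(table["lining"].sum()))


def stage_classifier(cfg: dict, outdir: Path, seed: int) -> None:
    cc = cfg["classifier"]
    table = pd.read_csv(outdir / "features" / "features.csv")
    if "true_class" not in table.columns:
        raise ValueError("features.csv has no true_class column; cannot train")
    rows = table[table["lining"] & table["true_class"].isin(clf.CLASSES)]
    d = outdir / "classifier"
    d.mkdir(parents=True, exist_ok=True)
    model = clf.train(rows, rows["true_class"], n_trees=cc["n_trees"],
                      split=cc["split"], seed=seed)
    model.save(d / "model.joblib")
    report = clf.evaluate(rows, rows["true_class"], n_trees=cc["n_trees"],
                          split=cc["split"], seed=seed,
                          n_repeats=cc["n_repeats"], importance=cc["importance"])
    report.to_json(d / "evaluation.json")
    pd.DataFrame(
        [{"class": c, "fpr": f, "tpr": t}
         for c, (fpr, tpr) in report.roc_curves.items()
         for f, t in zip(fpr, tpr)]
    ).to_csv(d / "roc_curves.csv", index=False)
    pd.DataFrame(
        {"feature": list(report.importances),
         "importance": list(report.importances.values())}
    ).to_csv(d / "importances.csv", index=False)
    report.oob_curve.to_csv(d / "oob_curve.csv", index=False)
    preds = clf.predict(model, rows)
    preds.to_csv(d / "predictions.csv", index=False)
    log.info("classifier: accuracy %.1f ± %.1f%%", report.accuracy_mean,
             report.accuracy_sd)


def stage_hemodynamics(cfg: dict, outdir: Path) -> None:
    hc = cfg["hemodynamics"]
    v1, v2, _ = scene.load_scene(outdir / "scene")
    caps = read_stack(outdir / "segmentation" / "capillary_labels.tif").astype(np.int32)
    segments = hemo.analyze_segments(
        caps, v1, v2,
        srs_drop_fraction=hc["srs_drop_fraction"],
        variance_threshold=hc["variance_threshold"],
        ratio_threshold=hc["ratio_threshold"],
    )
    d = outdir / "hemodynamics"
    d.mkdir(parents=True, exist_ok=True)
    hemo.segments_table(segments).to_csv(d / "segments.csv", index=False)
    census = hemo.stall_census(segments) if segments else {}
    (d / "census.json").write_text(json.dumps(census, indent=2, sort_keys=True))
    n_stall = sum(s.persistence != "flowing" for s in segments)
    log.info("hemodynamics: %d segments, %d with a stall", len(segments), n_stall)


# --------------------------------------------------------------------------
# driver


def run_pipeline(config_path: str | Path | None, outdir: str | Path,
                 seed: int = 0) -> dict:
    """Run every stage and write the manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_pipeline_config(config_path)
    seeds = fan_out_seeds(seed)
    timings = {}
    steps = [
        ("scene", lambda: stage_simulate(cfg, outdir, seeds["scene"])),
        ("separation", lambda: stage_separate(cfg, outdir)),
        ("segmentation", lambda: stage_segment(cfg, outdir)),
        ("features", lambda: stage_features(cfg, outdir)),
        ("classifier", lambda: stage_classifier(cfg, outdir, seeds["classifier"])),
        ("hemodynamics", lambda: stage_hemodynamics(cfg, outdir)),
    ]
    for name, fn in steps:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    make_report(outdir)

    from snarfpy import __version__
    hashes = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.suffix in {".csv", ".tif", ".json", ".yaml", ".md"}
    }
    manifest = {
        "config": cfg, "seed": seed, "stage_seeds": seeds,
        "version": __version__, "timings_s": timings, "file_sha256": hashes,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# report


def make_report(run_dir: str | Path) -> Path:
    """Human-readable summary (seven sections) of a run directory.

    Regeneration is idempotent: the report depends only on stage files.
    """
    run_dir = Path(run_dir)
    lines = ["# SNARF analysis report", ""]

    def missing(name):
        lines.extend([f"## {name}", "", "stage missing", ""])

    # 1. SBR / depth
    sbr = run_dir / "separation" / "sbr_profile.csv"
    if sbr.exists():
        prof = pd.read_csv(sbr)
        limits = json.loads((run_dir / "separation" / "depth_limits.json").read_text())
        lines += ["## Signal-to-background vs depth", ""]
        lines += [f"- depth limit (SBR > 2), {wn} cm-1: {v:.1f} um"
                  for wn, v in sorted(limits.items())]
        head = prof.iloc[:: max(1, len(prof) // 10)]
        lines += ["", head.to_string(index=False, float_format=lambda v: f"{v:.2f}"), ""]
    else:
        missing("Signal-to-background vs depth")

    # 2. stall census  3. width comparison
    census_path = run_dir / "hemodynamics" / "census.json"
    if census_path.exists():
        census = json.loads(census_path.read_text())
        lines += ["## Stall census", ""]
        lines += [f"- segments: {census.get('n_segments', 0)}"]
        for tp in ("t1", "t2"):
            lines += [f"- stalled volume fraction {tp}: "
                      f"{100 * census.get(f'stalled_volume_fraction_{tp}', 0):.2f}%"]
        lines += [f"- persistent stalls (fully contained): "
                  f"{census.get('n_persistent_stalls', 0)}"]
        lines += [f"- content counts: {census.get('content_counts', {})}"]
        fw = census.get("fraction_with_wbc")
        if fw is not None and not (isinstance(fw, float) and np.isnan(fw)):
            lines += [f"- fraction of persistent stalls with >= 1 WBC: {100 * fw:.0f}%"]
        lines += [""]
        lines += ["## Vessel width: flowing vs stalled", ""]
        wf = census.get("widths_flowing_um", [])
        ws = census.get("widths_stalled_um", [])
        lines += [f"- flowing: n={len(wf)}, mean={np.mean(wf):.2f} um" if wf
                  else "- flowing: none"]
        lines += [f"- stalled: n={len(ws)}, mean={np.mean(ws):.2f} um" if ws
                  else "- stalled: none"]
        if len(wf) >= 2 and len(ws) >= 2:
            from scipy import stats
            t, p = stats.ttest_ind(wf, ws)
            lines += [f"- two-tailed unpaired t-test: t={t:.3f}, p={p:.4f}"]
        else:
            lines += ["- t-test: insufficient replication"]
        lines += [""]
    else:
        missing("Stall census")
        missing("Vessel width: flowing vs stalled")

    # 4. cell populations
    feat = run_dir / "features" / "features.csv"
    if feat.exists():
        table = pd.read_csv(feat)
        lines += ["## Cell populations", ""]
        n = len(table)
        n_lin = int(table["lining"].sum())
        pct = 100.0 * n_lin / n if n else 0.0
        lines += [f"- cells: {n}; capillary-lining: {n_lin} ({pct:.1f}%)"]
        if "true_class" in table.columns:
            vc = table.loc[table["lining"], "true_class"].value_counts()
            lines += [f"- lining class counts (ground truth): {vc.to_dict()}"]
        lines += [""]
    else:
        missing("Cell populations")

    # 5. accuracy  6. ROC  7. importances
    evaluation = run_dir / "classifier" / "evaluation.json"
    if evaluation.exists():
        ev = json.loads(evaluation.read_text())
        lines += ["## Prediction accuracy", ""]
        lines += [f"- overall: {ev['accuracy_mean_pct']:.1f} ± "
                  f"{ev['accuracy_sd_pct']:.1f}% over {ev['n_repeats']} splits"]
        lines += [f"- macro (mean per-class recall): "
                  f"{ev['macro_accuracy_mean_pct']:.1f} ± "
                  f"{ev['macro_accuracy_sd_pct']:.1f}%"]
        oob = ev["oob_curve"]
        lines += [f"- out-of-bag error at trees {oob['n_trees']}: "
                  + ", ".join(f"{100 * e:.1f}%" for e in oob["oob_error"]), ""]
        lines += ["## ROC / AUC (one-vs-rest)", ""]
        lines += [f"- {c}: AUC = {a:.3f}" for c, a in sorted(ev["per_class_auc"].items())]
        lines += ["", "## Feature importances", ""]
        imp = sorted(ev["importances"].items(), key=lambda kv: -kv[1])
        lines += [f"- {name}: {val:.3f}" for name, val in imp]
        lines += [""]
    else:
        missing("Prediction accuracy")
        missing("ROC / AUC (one-vs-rest)")
        missing("Feature importances")

    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
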