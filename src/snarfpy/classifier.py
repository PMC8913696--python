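"""Random-forest identity prediction for capillary-lining cells.

A 20-tree classification forest with stratified 70/30 train/test splits
predicts endothelial / pericyte / unlabeled identity from the ten-feature
table. Evaluation reports accuracy (overall and macro) as mean ± s.d. over
repeated random splits, one-vs-rest ROC/AUC per class from the forest's
vote fractions, normalized feature importances (impurity by default,
permutation by config), the out-of-bag error as a function of tree count,
and the confusion matrix. A classic pooled-variance two-tailed unpaired
t-test (Welch optional) serves the per-animal group comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import train_test_split

from snarfpy.morphometry import FEATURES

CLASSES = ("endothelial", "pericyte", "unlabeled")


class ContractError(ValueError):
    """Feature table does not match the ten-feature training contract."""


class DegenerateTrainingError(ValueError):
    """Fewer than two classes present in the training labels."""


class InsufficientReplicationError(ValueError):
    """A group has fewer than two animals; no variance estimate possible."""


@dataclasses.dataclass
class ClassifierModel:
    """Trained forest plus its split protocol (for reproducibility)."""

    forest: RandomForestClassifier
    n_trees: int = 20
    split: float = 0.7
    seed: int = 0
    classes: tuple[str, ...] = CLASSES
    feature_names: tuple[str, ...] = tuple(FEATURES)
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return joblib.load(Path(path))


def _check_table(feature_table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURES if c not in feature_table.columns]
    if missing:
        raise ContractError(f"missing feature columns: {missing}")
    x = feature_table[list(FEATURES)].to_numpy(float)
    if np.any(~np.isfinite(x)):
        raise ContractError("feature table contains non-finite values")
    return x


def train(
    feature_table: pd.DataFrame,
    labels,
    n_trees: int = 20,
    split: float = 0.7,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the forest on a stratified ``split`` fraction of the rows.

    Split indices are recorded on the returned model so the exact train/test
    partition can be reproduced.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    x = _check_table(feature_table)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("need at least two classes to train")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, train_size=split, stratify=y, random_state=seed)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x[tr], y[tr])
    return ClassifierModel(forest=forest, n_trees=n_trees, split=split, seed=seed,
                           classes=tuple(forest.classes_), train_index=tr, test_index=te)


def predict(model: ClassifierModel, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Per-row predicted class and vote fractions (one column per class)."""
    x = _check_table(feature_table)
    proba = model.forest.predict_proba(x)
    pred = model.forest.classes_[np.argmax(proba, axis=1)]
    out = pd.DataFrame({"predicted_class": pred})
    for j, cls in enumerate(model.forest.classes_):
        out[f"vote_{cls}"] = proba[:, j]
    if "cell_id" in feature_table.columns:
        out.insert(0, "cell_id", feature_table["cell_id"].to_numpy())
    return out


@dataclasses.dataclass
class EvaluationReport:
    accuracy_mean: float            # percent, overall
    accuracy_sd: float
    macro_accuracy_mean: float      # percent, mean of per-class recalls
    macro_accuracy_sd: float
    per_class_auc: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    importances: dict[str, float]
    oob_curve: pd.DataFrame         # columns: n_trees, oob_error
    confusion: pd.DataFrame
    n_repeats: int = 20

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "macro_accuracy_mean_pct": self.macro_accuracy_mean,
            "macro_accuracy_sd_pct": self.macro_accuracy_sd,
            "per_class_auc": self.per_class_auc,
            "importances": self.importances,
            "n_repeats": self.n_repeats,
            "confusion": {
                "classes": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "oob_curve": {
                "n_trees": self.oob_curve["n_trees"].tolist(),
                "oob_error": self.oob_curve["oob_error"].tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def evaluate(
    feature_table: pd.DataFrame,
    labels,
    n_trees: int = 20,
    split: float = 0.7,
    seed: int = 0,
    n_repeats: int = 20,
    importance: str = "impurity",
    oob_tree_grid: tuple[int, ...] = (5, 10, 15, 20, 30, 50, 75, 100),
    max_split_retries: int = 20,
) -> EvaluationReport:
    """Repeated-split evaluation of the forest (see module docstring).

    Accuracy mean ± s.d. is computed over ``n_repeats`` independent
    stratified splits; if a split drops a class from the test set it is
    redrawn (bounded retries). ROC curves come from the first repeat's
    one-vs-rest vote fractions; AUCs are averaged over repeats.
    """
    x = _check_table(feature_table)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("need at least two classes to evaluate")
    rng = np.random.default_rng(seed)
    classes = sorted(np.unique(y))

    accs, maccs = [], []
    aucs = {c: [] for c in classes}
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    confusion_total = np.zeros((len(classes), len(classes)), int)

    for rep in range(n_repeats):
        for _ in range(max_split_retries):
            rs = int(rng.integers(0, 2**31 - 1))
            tr, te = train_test_split(np.arange(len(y)), train_size=split,
                                      stratify=y, random_state=rs)
            if set(np.unique(y[te])) == set(classes):
                break
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=rs, n_jobs=1)
        forest.fit(x[tr], y[tr])
        proba = forest.predict_proba(x[te])
        pred = forest.classes_[np.argmax(proba, axis=1)]
        accs.append(float(np.mean(pred == y[te])))
        cm = confusion_matrix(y[te], pred, labels=classes)
        recalls = np.diag(cm) / np.maximum(cm.sum(axis=1), 1)
        maccs.append(float(recalls.mean()))
        confusion_total += cm
        for j, c in enumerate(forest.classes_):
            fpr, tpr, _ = roc_curve((y[te] == c).astype(int), proba[:, j])
            aucs[c].append(float(auc(fpr, tpr)))
            if rep == 0:
                roc_curves[c] = (fpr, tpr)

    # importances from a forest fit on the full table; rows are sorted into a
    # canonical order first so the importance vector does not depend on the
    # incidental row order of the input table
    order = np.lexsort(tuple(x.T) + (np.asarray(y, str),))
    ref = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    ref.fit(x[order], y[order])
    if importance == "impurity":
        imp = ref.feature_importances_
    elif importance == "permutation":
        res = permutation_importance(ref, x[order], y[order], n_repeats=10,
                                     random_state=seed, n_jobs=1)
        imp = np.clip(res.importances_mean, 0, None)
    else:
        raise ValueError(f"unknown importance kind {importance!r}")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    feature_names = list(feature_table[list(FEATURES)].columns)

    oob = oob_error_curve(x, y, oob_tree_grid, seed=seed)

    return EvaluationReport(
        accuracy_mean=100.0 * float(np.mean(accs)),
        accuracy_sd=100.0 * float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        macro_accuracy_mean=100.0 * float(np.mean(maccs)),
        macro_accuracy_sd=100.0 * float(np.std(maccs, ddof=1)) if len(maccs) > 1 else 0.0,
        per_class_auc={c: float(np.mean(v)) for c, v in aucs.items()},
        roc_curves=roc_curves,
        importances=dict(zip(feature_names, imp.tolist())),
        oob_curve=oob,
        confusion=pd.DataFrame(confusion_total, index=classes, columns=classes),
        n_repeats=n_repeats,
    )


def oob_error_curve(x, y, tree_grid=(5, 10, 15, 20, 30, 50, 75, 100), seed: int = 0,
                    n_replicates: int = 1) -> pd.DataFrame:
    """Out-of-bag error at each tree count.

    With ``n_replicates`` > 1 the error at each tree count is averaged over
    independently seeded forests, separating the genuine convergence of the
    ensemble from single-forest bootstrap noise (~sqrt(err/n) per fit).
    """
    rows = []
    for t in tree_grid:
        errs = []
        for r in range(n_replicates):
            forest = RandomForestClassifier(n_estimators=int(t), oob_score=True,
                                            bootstrap=True, random_state=seed + r,
                                            n_jobs=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # few-tree fits may lack OOB rows
                forest.fit(x, y)
            errs.append(1.0 - float(forest.oob_score_))
        rows.append({"n_trees": int(t), "oob_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# group statistics


def age_group_comparison(summaries: pd.DataFrame, value: str = "value",
                         group: str = "group", welch: bool = False) -> pd.DataFrame:
    """Two-tailed unpaired t-test for every pair of groups.

    ``summaries`` holds one row per animal with a group column and a value
    column. Returns per-pair t, p, and per-group mean/s.d./n. No
    multiple-testing correction is applied (single pairwise tests).
    """
    groups = {g: df[value].to_numpy(float) for g, df in summaries.groupby(group)}
    for g, v in groups.items():
        if len(v) < 2:
            raise InsufficientReplicationError(
                f"group {g!r} has {len(v)} animal(s); need >= 2")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
            rows.append({
                "group_a": a, "group_b": b,
                "t": float(t), "p": float(p),
                "mean_a": float(groups[a].mean()), "sd_a": float(groups[a].std(ddof=1)),
                "n_a": len(groups[a]),
                "mean_b": float(groups[b].mean()), "sd_b": float(groups[b].std(ddof=1)),
                "n_b": len(groups[b]),
            })
    return pd.DataFrame(rows)
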