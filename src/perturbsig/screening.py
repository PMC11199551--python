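"""Downstream task harness: ligand-based virtual screening and drug
response prediction on model-derived compound representations.

Activity labelling follows the bioactivity convention of calling a compound
active when its potency (IC50/Ki/Kd) is strictly below 10 uM, with inactives
subsampled at five per active.  Response labelling calls a compound
sensitive when its dose-response AUC is below 5.5 and resistant otherwise.
Representations are either a single cell line's predicted signature, an
early fusion (concatenation over cell lines), or structure-based baselines
(fingerprint, optionally concatenated with the basal profile); late fusion
averages per-cell classifier probabilities instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (average_precision_score, balanced_accuracy_score,
                             f1_score, log_loss, matthews_corrcoef,
                             roc_auc_score)
from sklearn.model_selection import GridSearchCV

from .metrics import pearson

ACTIVITY_THRESHOLD_UM = 10.0
RESPONSE_AUC_THRESHOLD = 5.5
NEGATIVE_RATIO = 5

#: the four searched random-forest hyperparameters
RF_SEARCH_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 10],
    "criterion": ["gini", "entropy"],
    "oob_score": [False, True],
}


@dataclass
class LabeledSet:
    """Feature matrix + labels for a compound list; task-aware."""

    compound_ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    task: str = "classification"

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels)
        if len(self.compound_ids) != self.features.shape[0] \
                or len(self.compound_ids) != self.labels.shape[0]:
            raise ValueError("ids, features and labels must align")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------

def label_activity(potencies_um: dict[str, float],
                   threshold_um: float = ACTIVITY_THRESHOLD_UM,
                   negative_ratio: int = NEGATIVE_RATIO,
                   seed: int = 0) -> dict[str, int]:
    """Binary activity labels with 1:``negative_ratio`` negative sampling.

    Active (1) iff potency < ``threshold_um`` (strict).  Inactives are drawn
    without replacement from the remaining pool, ``negative_ratio`` per
    active (the whole pool if smaller), deterministically under ``seed``.
    """
    if any(v <= 0 for v in potencies_um.values()):
        raise ValueError("potencies must be positive concentrations")
    actives = sorted(c for c, v in potencies_um.items() if v < threshold_um)
    if not actives:
        raise ValueError("no active compounds below threshold")
    pool = sorted(c for c, v in potencies_um.items() if v >= threshold_um)
    rng = np.random.default_rng(seed)
    n_neg = min(len(pool), negative_ratio * len(actives))
    negatives = list(rng.choice(pool, size=n_neg, replace=False)) if n_neg \
        else []
    labels = {c: 1 for c in actives}
    labels.update({c: 0 for c in negatives})
    return labels


def label_response(aucs: dict[str, float],
                   threshold: float = RESPONSE_AUC_THRESHOLD) -> dict[str, int]:
    """Sensitive (1) iff AUC < threshold, resistant (0) iff AUC >= threshold."""
    return {c: int(a < threshold) for c, a in aucs.items()}


# ---------------------------------------------------------------------------
# Representation assembly
# ---------------------------------------------------------------------------

def assemble_features(compound_ids: list[str], cells: list[str],
                      predictions: dict[tuple[str, str], np.ndarray],
                      mode: str = "single",
                      structure: dict[str, np.ndarray] | None = None,
                      basal: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Build the per-compound feature matrix for a downstream learner.

    ``predictions`` maps (compound_id, cell) to the predicted signature dX'.
    Modes: ``single`` (first cell's signature), ``early_fusion``
    (concatenation over ``cells`` in the given order), ``structure``
    (fingerprint only) and ``structure_basal`` (fingerprint (+) basal
    profile of the first cell).
    """
    rows = []
    for c in compound_ids:
        if mode in ("single", "early_fusion"):
            use = cells[:1] if mode == "single" else cells
            parts = []
            for cell in use:
                if (c, cell) not in predictions:
                    raise KeyError(f"no prediction for compound {c!r} "
                                   f"on cell {cell!r}")
                parts.append(np.asarray(predictions[(c, cell)], dtype=float))
            rows.append(np.concatenate(parts))
        elif mode == "structure":
            rows.append(np.asarray(structure[c], dtype=float))
        elif mode == "structure_basal":
            rows.append(np.concatenate([
                np.asarray(structure[c], dtype=float),
                np.asarray(basal[cells[0]], dtype=float)]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Learners and evaluation
# ---------------------------------------------------------------------------

def default_learner(task: str, seed: int = 0, search: bool = False):
    """Random-forest default with the four-way hyperparameter grid.

    ``search=True`` wraps the forest in a cross-validated grid search over
    n_estimators, max_depth, criterion and oob_score.
    """
    cls = RandomForestClassifier if task == "classification" \
        else RandomForestRegressor
    est = cls(n_estimators=300, random_state=seed)
    if search:
        scoring = "average_precision" if task == "classification" else "r2"
        return GridSearchCV(est, RF_SEARCH_GRID, cv=3, scoring=scoring)
    return est


def _classification_metrics(y_true, proba) -> dict[str, float]:
    pred = (proba >= 0.5).astype(int)
    return {
        "aupr": float(average_precision_score(y_true, proba)),
        "auroc": float(roc_auc_score(y_true, proba)),
        "bacc": float(balanced_accuracy_score(y_true, pred)),
        "f1": float(f1_score(y_true, pred)),
        "log_loss": float(log_loss(y_true, proba, labels=[0, 1])),
        "mcc": float(matthews_corrcoef(y_true, pred)),
    }


def fit_and_evaluate(train: LabeledSet, test: LabeledSet,
                     learner_factory=None, repeats: int = 5,
                     seed: int = 0) -> dict:
    """Train/evaluate a learner over repeated seeds; mean +/- sd metrics.

    Classification reports AUPR, AUROC, BACC, F1, log-loss and MCC from
    predicted probabilities; regression reports the Pearson correlation of
    predicted vs true response AUCs and exports the ranking by predicted
    AUC (most sensitive first) for enrichment analysis.  Train and test must
    be compound-disjoint.
    """
    leak = set(train.compound_ids) & set(test.compound_ids)
    if leak:
        raise ValueError(f"compounds shared between train and test: "
                         f"{sorted(leak)[:10]}")
    if train.task != test.task:
        raise ValueError("train/test task mismatch")
    task = train.task
    per_repeat: list[dict[str, float]] = []
    rankings = []
    for r in range(repeats):
        rep_seed = seed + r
        learner = (learner_factory(task, rep_seed) if learner_factory
                   else default_learner(task, rep_seed))
        learner.fit(train.features, train.labels)
        if task == "classification":
            proba = learner.predict_proba(test.features)[:, 1]
            per_repeat.append(_classification_metrics(
                test.labels.astype(int), proba))
        else:
            pred = learner.predict(test.features)
            per_repeat.append({"pearson": pearson(
                test.labels.astype(float), pred)})
            order = np.argsort(pred, kind="stable")
            rankings.append([test.compound_ids[i] for i in order])
    keys = per_repeat[0].keys()
    summary = {k: (float(np.mean([m[k] for m in per_repeat])),
                   float(np.std([m[k] for m in per_repeat])))
               for k in keys}
    out = {"per_repeat": per_repeat, "summary": summary}
    if rankings:
        out["rankings_by_predicted_auc"] = rankings
    return out


def late_fusion(per_cell_probabilities: dict[str, list[float]]) -> dict[str, float]:
    """Fuse per-cell classifier probabilities by their arithmetic mean."""
    out = {}
    for cid, probs in per_cell_probabilities.items():
        if len(probs) == 0:
            raise ValueError(f"empty probability list for compound {cid!r}")
        p = np.asarray(probs, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        out[cid] = float(p.mean())
    return out


def similarity_binned_evaluation(y_true: dict[str, int],
                                 proba: dict[str, float],
                                 max_sims: dict[str, float],
                                 bins=((0.0, 0.3), (0.3, 0.5), (0.5, 0.7),
                                       (0.7, 1.0))) -> dict[tuple, dict]:
    """Recompute classification metrics within max-train-similarity bins.

    Bins are half-open intervals (lo, hi]; a compound with similarity 0.3
    falls in (0.0, 0.3].  Bins containing no test compound, or only one
    class, are omitted from the result.
    """
    out = {}
    for lo, hi in bins:
        ids = [c for c in y_true if lo < max_sims[c] <= hi]
        if not ids:
            continue
        yt = np.array([y_true[c] for c in ids])
        if len(np.unique(yt)) < 2:
            continue
        pp = np.array([proba[c] for c in ids])
        out[(lo, hi)] = _classification_metrics(yt, pp)
    return out
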