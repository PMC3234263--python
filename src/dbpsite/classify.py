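"""Class-imbalanced SVM training and chain-level cross-validation.

DNA-binding residues are heavily outnumbered on protein surfaces
(roughly 15% of surface residues in typical training sets), so models
are trained on all binding residues plus an equal number of nonbinding
residues sampled at random from the training chains, while test folds
keep their natural imbalance.  Cross-validation splits at the chain
level: all residues of a chain fall in the same fold, the interface
propensity table is rebuilt from the four training folds of each round,
and feature columns are z-scored with training-fold statistics before
fitting an RBF-kernel SVM.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    FEATURE_SETS,
    PropensityTable,
    feature_names,
    interface_propensity_table,
)
from .metrics import confusion_counts, pr_curve_auc, recall_precision_f1
from .structure import THREE_TO_ONE

__all__ = [
    "ResidueRecord",
    "records_to_matrix",
    "balanced_sample",
    "train_svm",
    "predict_scores",
    "split_chains",
    "cross_validate",
    "CvResult",
    "FoldResult",
    "save_model",
    "load_model",
]

DEFAULT_C = 1.0
DEFAULT_GAMMA = 1.0 / 43.0  # kernel width matched to the 43-dim input


@dataclass
class ResidueRecord:
    """One surface residue with everything needed to featurize it.

    The propensity-independent features (RW-PSSM block, WBC, central
    ScASA) are precomputed; WIP is recomputed per cross-validation fold
    from the fold's own propensity table using the stored patch
    composition.
    """

    chain_id: str
    key: tuple[str, int, str]
    name: str                      # 3-letter parent type
    label: bool                    # True = binding
    rw_pssm: np.ndarray            # 40 values
    wbc: float
    sc_asa: float
    patch_member_names: list[str]  # parent types, central first
    patch_weights: np.ndarray


def _wip(record: ResidueRecord, table: PropensityTable) -> float:
    ip = np.array(
        [table.values[THREE_TO_ONE.get(nm, "X")] for nm in record.patch_member_names]
    )
    w = record.patch_weights
    return float((w * ip).sum() / w.sum())


def records_to_matrix(
    records: Sequence[ResidueRecord],
    ip_table: PropensityTable,
    feature_set: str = "full",
) -> np.ndarray:
    """Feature matrix in the canonical column order of ``feature_names``."""
    if feature_set not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set!r}")
    rows = []
    for rec in records:
        blocks = {
            "rw_pssm": rec.rw_pssm,
            "wip": [_wip(rec, ip_table)],
            "wbc": [rec.wbc],
            "sc_asa": [rec.sc_asa],
        }
        rows.append(np.concatenate([np.atleast_1d(blocks[b]) for b in FEATURE_SETS[feature_set]]))
    return np.asarray(rows, dtype=float)


def balanced_sample(labels: Sequence[bool], rng: np.random.Generator) -> np.ndarray:
    """Indices of all positives plus an equal number of random negatives.

    Negatives are drawn without replacement; when fewer negatives than
    positives exist, all of both are kept with a warning.  Deterministic
    for a fixed generator state.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("balanced sampling needs both classes")
    if len(neg) < len(pos):
        warnings.warn(
            f"only {len(neg)} negatives for {len(pos)} positives; keeping all"
        )
        chosen_neg = neg
    else:
        chosen_neg = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, chosen_neg]))


def train_svm(
    X: np.ndarray,
    y: Sequence[bool],
    C: float = DEFAULT_C,
    gamma=DEFAULT_GAMMA,
) -> Pipeline:
    """Fit a z-scoring + RBF-kernel SVM pipeline producing decision scores."""
    y = np.asarray(y, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=C, gamma=gamma)),
        ]
    )
    model.fit(X, y)
    return model


def predict_scores(
    model: Pipeline, X: np.ndarray, threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous decision scores and thresholded labels for all residues.

    Nonbinding residues are never removed from a test set; every surface
    residue receives a score, and the label is score >= threshold.
    """
    n_expected = model.named_steps["scale"].n_features_in_
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature schema mismatch: model expects {n_expected} columns, "
            f"got {X.shape[1]}"
        )
    scores = model.decision_function(X)
    return scores, scores >= threshold


def split_chains(
    chain_ids: Sequence[str], n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Random chain-level fold assignment with sizes differing by <= 1."""
    unique = sorted(set(chain_ids))
    if len(unique) < n_folds:
        raise ValueError(f"need at least {n_folds} chains for {n_folds}-fold CV")
    perm = list(rng.permutation(unique))
    return [list(part) for part in np.array_split(perm, n_folds)]


@dataclass
class FoldResult:
    fold: int
    train_chains: list[str]
    test_chains: list[str]
    ip_table: PropensityTable
    sampled_train_keys: list
    scores: np.ndarray
    truth: np.ndarray
    metrics: dict


@dataclass
class CvResult:
    folds: list[FoldResult] = field(default_factory=list)
    excluded_folds: list[int] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [
            {"fold": f.fold, **f.metrics} for f in self.folds
        ]
        frame = pd.DataFrame(rows)
        mean = frame.drop(columns="fold").mean().to_dict()
        frame = pd.concat(
            [frame, pd.DataFrame([{"fold": "mean", **mean}])], ignore_index=True
        )
        return frame

    def mean_metric(self, name: str) -> float:
        return float(np.mean([f.metrics[name] for f in self.folds]))


def cross_validate(
    records: Sequence[ResidueRecord],
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
    C: float = DEFAULT_C,
    gamma=DEFAULT_GAMMA,
    feature_set: str = "full",
    threshold: float = 0.0,
    pseudocount: float = 1.0,
    folds: list[list[str]] | None = None,
) -> CvResult:
    """Chain-level k-fold cross-validation with per-fold propensities.

    Per fold: the interface propensity table and the balanced training
    sample are derived only from training-fold chains; the untouched,
    imbalanced test fold is scored in full.  Metrics are reported per
    fold and averaged unweighted over folds.  Folds without positives
    are excluded with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = list(records)
    if folds is None:
        folds = split_chains([r.chain_id for r in records], n_folds, rng)
    result = CvResult()
    for fold_idx, test_chains in enumerate(folds):
        test_set = set(test_chains)
        train = [r for r in records if r.chain_id not in test_set]
        test = [r for r in records if r.chain_id in test_set]
        if not any(r.label for r in test):
            warnings.warn(f"fold {fold_idx} has no binding residues; excluded")
            result.excluded_folds.append(fold_idx)
            continue
        ip_table = interface_propensity_table(
            [(r.name, "binding" if r.label else "nonbinding") for r in train],
            pseudocount=pseudocount,
        )
        X_train = records_to_matrix(train, ip_table, feature_set)
        y_train = np.array([r.label for r in train])
        sample = balanced_sample(y_train, rng)
        model = train_svm(X_train[sample], y_train[sample], C=C, gamma=gamma)
        X_test = records_to_matrix(test, ip_table, feature_set)
        y_test = np.array([r.label for r in test])
        scores, predicted = predict_scores(model, X_test, threshold)
        recall, precision, f1 = recall_precision_f1(
            confusion_counts(predicted, y_test)
        )
        auc = pr_curve_auc(scores, y_test).area
        result.folds.append(
            FoldResult(
                fold=fold_idx,
                train_chains=sorted({r.chain_id for r in train}),
                test_chains=sorted(test_set),
                ip_table=ip_table,
                sampled_train_keys=[train[i].key for i in sample],
                scores=scores,
                truth=y_test,
                metrics={
                    "recall": recall,
                    "precision": precision,
                    "f1": f1,
                    "pr_auc": auc,
                    "prevalence": float(y_test.mean()),
                },
            )
        )
    return result


def save_model(model: Pipeline, path, feature_set: str, config: dict | None = None):
    """Persist a fitted pipeline with its feature schema and config."""
    payload = {
        "model": model,
        "feature_names": feature_names(feature_set),
        "feature_set": feature_set,
        "config": config or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)
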