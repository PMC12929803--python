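"""Balanced dataset assembly, group-wise splitting, XGBoost training and
evaluation with strict and weighted precision.

The assembled dataset balances positives (original + augmented variants)
against negatives 1:1.  Splitting uses GroupShuffleSplit with the group key
of a row defined as the lexicographically smaller accession of its pair, so
augmented variants always land in their parent pair's partition and no
anchor protein straddles partitions.  Hyperparameters are tuned by 3-fold
stratified grid search maximizing AUPRC, and the winner is retrained with
early stopping (patience 20 rounds) monitored on the validation partition,
with ``scale_pos_weight`` set to the training negative-to-positive ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold
from xgboost import XGBClassifier

from .exceptions import ConfigurationError, InsufficientDataError
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

DEFAULT_GRID = {
    "max_depth": [4, 6, 8],
    "learning_rate": [0.01, 0.05, 0.1],
    "subsample": [0.6, 0.8, 1.0],
}

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)
HIGH_CONFIDENCE_THRESHOLD = 0.95


def assemble_dataset(
    originals: pd.DataFrame,
    augmented: pd.DataFrame,
    negatives: pd.DataFrame,
    seed: int = 0,
    extra_negatives: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the 1:1 balanced modeling table.

    ``originals`` and ``negatives`` are pair feature tables indexed by
    (protein_a, protein_b); ``augmented`` is the long variant table from
    :func:`coelunet.augment.augment_dataset`.  Negatives are sampled without
    replacement to match the positive row count exactly, topping up from
    ``extra_negatives`` if the staged pool is exhausted.

    Returns a DataFrame with one row per instance: ``row_id``, pair columns,
    the five features, ``label`` (1/0), ``group`` (smaller accession) and
    ``origin`` in {original, augmented, negative}.
    """
    if originals.empty:
        raise InsufficientDataError("no original positives to assemble")
    rows = []
    for (a, b), feat in originals[FEATURE_NAMES].iterrows():
        rows.append((f"{a}|{b}", a, b, *feat, 1, min(a, b), "original"))
    for _, r in augmented.iterrows():
        a, b = r["protein_a"], r["protein_b"]
        rows.append(
            (f"{a}|{b}|aug{int(r['variant'])}", a, b,
             *[r[f] for f in FEATURE_NAMES], 1, min(a, b), "augmented")
        )
    n_pos = len(rows)

    neg_pool = negatives
    if len(neg_pool) < n_pos and extra_negatives is not None:
        top_up = extra_negatives.loc[~extra_negatives.index.isin(neg_pool.index)]
        log.info("topping up negatives: %d staged + %d extra", len(neg_pool), len(top_up))
        neg_pool = pd.concat([neg_pool, top_up])
    if len(neg_pool) < n_pos:
        raise InsufficientDataError(
            f"need {n_pos} negatives but only {len(neg_pool)} are available"
        )
    rng = np.random.default_rng(seed)
    take = np.sort(rng.choice(len(neg_pool), size=n_pos, replace=False))
    for a, b in neg_pool.index[take]:
        feat = neg_pool.loc[(a, b), FEATURE_NAMES]
        rows.append((f"{a}|{b}", a, b, *feat, 0, min(a, b), "negative"))

    table = pd.DataFrame(
        rows,
        columns=["row_id", "protein_a", "protein_b", *FEATURE_NAMES, "label", "group", "origin"],
    )
    if table["row_id"].duplicated().any():
        raise ConfigurationError("duplicate row ids in assembled dataset")
    return table


def group_split(
    dataset: pd.DataFrame,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> pd.Series:
    """Assign every row to train/validation/test, keeping groups intact.

    Group allocation is random (GroupShuffleSplit) with row-count fractions
    approximating ``fractions``; every row of a group - including all
    augmented variants of a pair - lands in exactly one partition.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ConfigurationError("fractions must sum to 1")
    groups = dataset["group"].to_numpy()
    if len(np.unique(groups)) < 3:
        raise InsufficientDataError("need at least 3 groups to split three ways")
    f_train, f_val, f_test = fractions
    gss1 = GroupShuffleSplit(n_splits=1, train_size=f_train, random_state=seed)
    train_idx, rest_idx = next(gss1.split(dataset, groups=groups))
    rest = dataset.iloc[rest_idx]
    gss2 = GroupShuffleSplit(
        n_splits=1, train_size=f_val / (f_val + f_test), random_state=seed + 1
    )
    val_rel, test_rel = next(gss2.split(rest, groups=rest["group"].to_numpy()))
    assign = pd.Series(index=dataset["row_id"], dtype=object, name="partition")
    assign.iloc[train_idx] = "train"
    assign.iloc[rest_idx[val_rel]] = "validation"
    assign.iloc[rest_idx[test_rel]] = "test"
    return assign


@dataclass
class ModelBundle:
    """A trained boosted-tree classifier plus everything needed to reuse it."""

    model: XGBClassifier
    params: dict
    scale_pos_weight: float
    feature_names: list[str]
    seed: int
    tuning_history: pd.DataFrame  # one row per grid point with cv_auprc

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return self.model.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        """Persist the native booster plus a JSON sidecar of the metadata."""
        path = Path(path)
        self.model.get_booster().save_model(str(path))
        sidecar = {
            "params": self.params,
            "scale_pos_weight": self.scale_pos_weight,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "best_iteration": int(getattr(self.model, "best_iteration", -1)),
            "tuning_history": self.tuning_history.to_dict(orient="records"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _xy(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return rows[FEATURE_NAMES].to_numpy(dtype=float), rows["label"].to_numpy(dtype=int)


def train_and_tune(
    train_rows: pd.DataFrame,
    val_rows: pd.DataFrame,
    grid: dict | None = None,
    seed: int = 0,
    cv_estimators: int = 100,
    max_estimators: int = 500,
) -> ModelBundle:
    """Grid search (3-fold stratified CV AUPRC) then early-stopped retrain."""
    grid = grid or DEFAULT_GRID
    X_train, y_train = _xy(train_rows)
    X_val, y_val = _xy(val_rows)
    for name, y in (("training", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise InsufficientDataError(f"{name} partition contains a single class")
    n_neg, n_pos = int((y_train == 0).sum()), int((y_train == 1).sum())
    spw = n_neg / n_pos

    history = []
    best: tuple[float, dict] | None = None
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for depth in grid["max_depth"]:
        for lr in grid["learning_rate"]:
            for sub in grid["subsample"]:
                point = {"max_depth": depth, "learning_rate": lr, "subsample": sub}
                auprcs = []
                for tr, te in skf.split(X_train, y_train):
                    clf = XGBClassifier(
                        n_estimators=cv_estimators,
                        scale_pos_weight=spw,
                        random_state=seed,
                        tree_method="hist",
                        n_jobs=1,
                        eval_metric="aucpr",
                        **point,
                    )
                    clf.fit(X_train[tr], y_train[tr])
                    auprcs.append(
                        average_precision_score(y_train[te], clf.predict_proba(X_train[te])[:, 1])
                    )
                cv_auprc = float(np.mean(auprcs))
                history.append({**point, "cv_auprc": cv_auprc})
                if best is None or cv_auprc > best[0]:
                    best = (cv_auprc, point)
    assert best is not None
    _, best_point = best

    final = XGBClassifier(
        n_estimators=max_estimators,
        scale_pos_weight=spw,
        random_state=seed,
        tree_method="hist",
        n_jobs=1,
        eval_metric="aucpr",
        early_stopping_rounds=20,
        **best_point,
    )
    final.fit(X_train, y_train, eval_set=[(X_val, y_val)], verbose=False)
    return ModelBundle(
        model=final,
        params=best_point,
        scale_pos_weight=spw,
        feature_names=list(FEATURE_NAMES),
        seed=seed,
        tuning_history=pd.DataFrame(history),
    )


@dataclass
class CurveSet:
    auroc: float
    auprc: float
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]  # fpr, tpr, thresholds
    pr: tuple[np.ndarray, np.ndarray, np.ndarray]   # precision, recall, thresholds


def evaluate_curves(bundle: ModelBundle, rows: pd.DataFrame) -> CurveSet:
    """ROC/AUROC (trapezoidal) and PR/AUPRC (step) on labeled rows."""
    X, y = _xy(rows)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("evaluation rows contain a single class")
    prob = bundle.model.predict_proba(X)[:, 1]
    fpr, tpr, roc_thr = roc_curve(y, prob)
    prec, rec, pr_thr = precision_recall_curve(y, prob)
    return CurveSet(
        auroc=float(roc_auc_score(y, prob)),
        auprc=float(average_precision_score(y, prob)),
        roc=(fpr, tpr, roc_thr),
        pr=(prec, rec, pr_thr),
    )


def strict_precision(
    predictions: pd.DataFrame, threshold: float = HIGH_CONFIDENCE_THRESHOLD
) -> float:
    """Precision over predictions >= threshold, unknowns counted as negatives.

    ``predictions`` needs columns ``prob`` and ``label`` (positive / negative
    / unknown).  TP = selected labeled positives; FP = everything else
    selected, including unknowns.  NaN when nothing is selected.
    """
    sel = predictions[predictions["prob"] >= threshold]
    if sel.empty:
        log.warning("no prediction reaches threshold %.3f; precision undefined", threshold)
        return float("nan")
    tp = int((sel["label"] == "positive").sum())
    return tp / len(sel)


def weighted_precision_curve(predictions: pd.DataFrame) -> pd.DataFrame:
    """Cumulative weighted precision over confidence-ranked predictions.

    Rows are sorted by probability descending (ties broken by ``id``).  The
    weight of a labeled positive is 1, of a labeled negative 0, and of an
    unknown its predicted probability; the curve value at rank k is the mean
    weight of the top k.
    """
    if predictions.empty:
        raise InsufficientDataError("no predictions")
    df = predictions.copy()
    if "id" not in df.columns:
        df["id"] = np.arange(len(df)).astype(str)
    df = df.sort_values(["prob", "id"], ascending=[False, True], kind="mergesort")
    weight = np.where(
        df["label"] == "positive", 1.0,
        np.where(df["label"] == "negative", 0.0, df["prob"]),
    )
    ranks = np.arange(1, len(df) + 1)
    curve = np.cumsum(weight) / ranks
    return pd.DataFrame(
        {"rank": ranks, "id": df["id"].to_numpy(), "prob": df["prob"].to_numpy(),
         "label": df["label"].to_numpy(), "weighted_precision": curve}
    )
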