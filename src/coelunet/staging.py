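"""Phase-one training-set construction.

Negatives are downsampled to a 5:1 negative-to-positive ratio, all staged
pairs are scored with an out-of-fold random forest on the five co-elution
features, and positives scoring strictly above the confidence threshold are
selected for phase-two augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, InsufficientDataError
from .features import FEATURE_NAMES
from .goldstd import LabelTable, Pair

log = logging.getLogger(__name__)


@dataclass
class StagedSet:
    """Pairs retained after negative downsampling, with first-stage scores."""

    positives: list[Pair]
    negatives: list[Pair]
    ratio: int
    seed: int
    scores: pd.Series | None = None  # index (protein_a, protein_b) -> score

    def all_pairs(self) -> list[Pair]:
        return self.positives + self.negatives


def downsample_negatives(labels: LabelTable, ratio: int = 5, seed: int = 0) -> StagedSet:
    """Keep all positives and a seeded uniform sample of ratio x negatives.

    When fewer negatives exist than the target, all are kept with a warning.
    """
    if ratio < 1:
        raise ConfigurationError("ratio must be >= 1")
    positives = sorted(labels.pairs_with_label("positive"))
    if not positives:
        raise InsufficientDataError("label table contains no positive pairs")
    negatives = sorted(labels.pairs_with_label("negative"))
    target = ratio * len(positives)
    if len(negatives) <= target:
        if len(negatives) < target:
            log.warning(
                "only %d negatives available for target %d; keeping all",
                len(negatives), target,
            )
        kept = negatives
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(negatives), size=target, replace=False)
        kept = [negatives[i] for i in sorted(idx)]
    return StagedSet(positives=positives, negatives=kept, ratio=ratio, seed=seed)


def first_stage_scores(
    features: pd.DataFrame,
    staged: StagedSet,
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
) -> pd.Series:
    """Out-of-fold random-forest positive-class probability per staged pair.

    ``features`` is a pair feature table indexed by (protein_a, protein_b).
    Fold assignment is stratified and seeded; a fold degenerating to one
    class triggers a reshuffle (new derived seed), at most 5 attempts.
    """
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    pairs = staged.all_pairs()
    missing = [p for p in pairs if p not in features.index]
    if missing:
        raise InsufficientDataError(f"{len(missing)} staged pairs lack features, e.g. {missing[:3]}")
    X = features.loc[pairs, FEATURE_NAMES].to_numpy(dtype=float)
    y = np.array([1] * len(staged.positives) + [0] * len(staged.negatives))

    last_error: Exception | None = None
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        oof = np.full(len(y), np.nan)
        try:
            for train_idx, test_idx in skf.split(X, y):
                if len(np.unique(y[train_idx])) < 2:
                    raise InsufficientDataError("single-class training fold")
                clf = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=seed, n_jobs=1
                )
                clf.fit(X[train_idx], y[train_idx])
                oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
            index = pd.MultiIndex.from_tuples(pairs, names=["protein_a", "protein_b"])
            scores = pd.Series(oof, index=index, name="first_stage_score")
            staged.scores = scores
            return scores
        except InsufficientDataError as err:  # refold with a new seed
            last_error = err
            log.warning("fold attempt %d degenerate, reshuffling", attempt + 1)
    raise InsufficientDataError(f"could not build {n_folds} two-class folds: {last_error}")


def select_high_confidence(
    scores: pd.Series, positives: list[Pair], threshold: float = 0.5
) -> set[Pair]:
    """Labeled positives whose first-stage score is strictly > threshold."""
    selected = {p for p in positives if float(scores.loc[p]) > threshold}
    if not selected:
        raise InsufficientDataError(
            f"no positive scored above {threshold}; inspect features or lower the threshold"
        )
    return selected
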