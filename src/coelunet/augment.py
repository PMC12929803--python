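"""Phase-two positive augmentation.

Each high-confidence positive pair spawns perturbed profile variants via
(1) per-value random scaling on [0.9, 1.1] and (2) missing-value processing,
where each NA position is either retained or swapped with an adjacent
fraction.  Variants are ranked by the composite score

    composite = n_valid * 0.5 + |pearson_raw| * 30 - euclidean * 0.01

and the top ``n_head`` (default 40) plus bottom ``n_tail`` (default 10) of
``n_candidates`` (default 200) are retained, all carrying the parent's
positive label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import FEATURE_NAMES, FeatureParams, FeatureVector, compute_pair_features
from .goldstd import Pair
from .profiles import ProfileMatrix
from .scheme import FractionScheme

log = logging.getLogger(__name__)

SCALE_LO = 0.9
SCALE_HI = 1.1


def perturb_trace(x: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Apply both perturbation tiers to one trace.

    Tier 1 multiplies every observed value by an independent uniform draw on
    [0.9, 1.1]; tier 2 visits every originally missing position and either
    keeps it in place or swaps it with an adjacent fraction (direction
    uniform; at the edges the only valid direction).  Swapping conserves the
    observed values (contents move, nothing is overwritten).
    """
    out = np.asarray(x, dtype=float).copy()
    observed = ~np.isnan(out)
    out[observed] *= rng.uniform(SCALE_LO, SCALE_HI, size=int(observed.sum()))
    for i in np.flatnonzero(~observed):
        if rng.random() < 0.5:
            continue  # NA retained in place
        if i == 0:
            j = 1
        elif i == len(out) - 1:
            j = len(out) - 2
        else:
            j = i + (1 if rng.random() < 0.5 else -1)
        out[i], out[j] = out[j], out[i]
    return out


def perturb_pair(
    x: Sequence[float], y: Sequence[float], seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Perturb both traces of a pair; deterministic given the seed."""
    if len(x) != len(y):
        raise ConfigurationError("traces must have equal length")
    rng = np.random.default_rng(seed)
    return perturb_trace(x, rng), perturb_trace(y, rng)


def composite_score(fv: FeatureVector) -> float:
    """n_valid * 0.5 + |pearson_raw| * 30 - euclidean * 0.01"""
    return fv.n_valid * 0.5 + abs(fv.pearson_raw) * 30.0 - fv.euclidean * 0.01


@dataclass
class AugmentedVariant:
    parent: Pair
    index: int                 # candidate index within the pool
    x: np.ndarray
    y: np.ndarray
    features: FeatureVector
    composite_score: float
    side: str                  # "head" or "tail"
    seed: int


def augment_pair(
    x: Sequence[float],
    y: Sequence[float],
    scheme: FractionScheme,
    n_candidates: int = 200,
    n_head: int = 40,
    n_tail: int = 10,
    seed: int = 0,
    parent: Pair = ("", ""),
    params: FeatureParams = FeatureParams(),
) -> list[AugmentedVariant]:
    """Generate, score and select perturbed variants of one positive pair.

    ``n_candidates`` variants are drawn, sorted by composite score descending
    (ties broken by candidate index), and the first ``n_head`` plus last
    ``n_tail`` are returned - 50 variants at the defaults.
    """
    if n_head + n_tail > n_candidates:
        raise ConfigurationError("n_head + n_tail must not exceed n_candidates")
    rng = np.random.default_rng(seed)
    candidates: list[AugmentedVariant] = []
    for idx in range(n_candidates):
        xv, yv = perturb_trace(x, rng), perturb_trace(y, rng)
        fv = compute_pair_features(xv, yv, scheme, params)
        candidates.append(
            AugmentedVariant(
                parent=parent, index=idx, x=xv, y=yv,
                features=fv, composite_score=composite_score(fv),
                side="", seed=seed,
            )
        )
    ranked = sorted(candidates, key=lambda v: (-v.composite_score, v.index))
    head = ranked[:n_head]
    tail = ranked[len(ranked) - n_tail :] if n_tail else []
    for v in head:
        v.side = "head"
    for v in tail:
        v.side = "tail"
    return head + tail


def augment_dataset(
    matrix: ProfileMatrix,
    pairs: Iterable[Pair],
    condition: str | None = None,
    n_candidates: int = 200,
    n_head: int = 40,
    n_tail: int = 10,
    seed: int = 0,
    params: FeatureParams = FeatureParams(),
) -> pd.DataFrame:
    """Augment every selected positive pair on its across-replicate mean traces.

    Returns a long DataFrame with parent pair, variant index, selection side,
    composite score and the recomputed feature vector of every retained
    variant.  Reproducible from (matrix, pairs, seed): each pair gets a
    child seed spawned deterministically from ``seed``.
    """
    cond = condition if condition is not None else matrix.conditions()[0]
    pair_list = sorted(tuple(sorted(p)) for p in set(map(tuple, pairs)))
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(pair_list))
    rows = []
    for (a, b), child in zip(pair_list, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        variants = augment_pair(
            matrix.mean_trace(a, cond),
            matrix.mean_trace(b, cond),
            matrix.scheme,
            n_candidates=n_candidates,
            n_head=n_head,
            n_tail=n_tail,
            seed=child_seed,
            parent=(a, b),
            params=params,
        )
        for v in variants:
            rows.append(
                {
                    "protein_a": a,
                    "protein_b": b,
                    "variant": v.index,
                    "side": v.side,
                    "composite_score": v.composite_score,
                    **{name: getattr(v.features, name) for name in FEATURE_NAMES},
                    "n_valid": v.features.n_valid,
                }
            )
    cols = ["protein_a", "protein_b", "variant", "side", "composite_score",
            *FEATURE_NAMES, "n_valid"]
    return pd.DataFrame(rows, columns=cols)
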