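"""Dataset assembly, group splitting, training, curves, precision variants."""

import numpy as np
import pandas as pd
import pytest

from coelunet import (
    assemble_dataset,
    evaluate_curves,
    group_split,
    strict_precision,
    train_and_tune,
    weighted_precision_curve,
)
from coelunet.classify import DEFAULT_GRID
from coelunet.exceptions import InsufficientDataError
from coelunet.features import FEATURE_NAMES


def _feature_frame(pairs, good=True, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        base = 0.9 if good else 0.1
        rows.append(
            {
                "protein_a": a, "protein_b": b,
                "pearson_raw": base + rng.normal(0, 0.03),
                "pearson_smoothed": base + rng.normal(0, 0.03),
                "euclidean": (0.2 if good else 1.4) + rng.normal(0, 0.03),
                "co_peak": 1.0 if good else 0.0,
                "wcc": base + rng.normal(0, 0.03),
                "n_valid": 60,
            }
        )
    return pd.DataFrame(rows).set_index(["protein_a", "protein_b"])


def _aug_frame(pairs, n_variants, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        for v in range(n_variants):
            rows.append(
                {
                    "protein_a": a, "protein_b": b, "variant": v,
                    "side": "head" if v < 0.8 * n_variants else "tail",
                    "composite_score": float(rng.random()),
                    "pearson_raw": 0.9 + rng.normal(0, 0.03),
                    "pearson_smoothed": 0.9 + rng.normal(0, 0.03),
                    "euclidean": 0.2 + rng.normal(0, 0.03),
                    "co_peak": 1.0,
                    "wcc": 0.9 + rng.normal(0, 0.03),
                    "n_valid": 60,
                }
            )
    return pd.DataFrame(rows)


def _pairs(prefix, n, start=0):
    return [(f"{prefix}{i:03d}a", f"{prefix}{i:03d}b") for i in range(start, start + n)]


@pytest.fixture()
def assembled():
    pos = _pairs("P", 30)
    neg = _pairs("N", 700)
    dataset = assemble_dataset(
        _feature_frame(pos, good=True),
        _aug_frame(pos, 20),
        _feature_frame(neg, good=False),
        seed=5,
    )
    return dataset


def test_assembly_balances_one_to_one():
    # 10 originals x 50 variants + 10 originals = 510 positives
    pos = _pairs("P", 10)
    neg = _pairs("N", 600)
    dataset = assemble_dataset(
        _feature_frame(pos, good=True),
        _aug_frame(pos, 50),
        _feature_frame(neg, good=False),
        seed=5,
    )
    labels = dataset["label"].value_counts()
    assert labels[1] == 510
    assert labels[0] == 510
    assert not dataset["row_id"].duplicated().any()


def test_assembly_without_augmentation():
    pos = _pairs("P", 5)
    neg = _pairs("N", 20)
    empty_aug = _aug_frame([], 0)
    dataset = assemble_dataset(
        _feature_frame(pos), empty_aug, _feature_frame(neg, good=False), seed=1
    )
    assert (dataset["label"] == 1).sum() == 5
    assert (dataset["label"] == 0).sum() == 5


def test_assembly_deterministic():
    pos, neg = _pairs("P", 5), _pairs("N", 80)
    args = (_feature_frame(pos), _aug_frame(pos, 10), _feature_frame(neg, good=False))
    assert assemble_dataset(*args, seed=2).equals(assemble_dataset(*args, seed=2))


def test_assembly_top_up_and_exhaustion():
    pos = _pairs("P", 10)
    staged_neg = _feature_frame(_pairs("N", 100), good=False)
    extra_neg = _feature_frame(_pairs("X", 500), good=False, seed=1)
    dataset = assemble_dataset(_feature_frame(pos), _aug_frame(pos, 50), staged_neg,
                               seed=3, extra_negatives=extra_neg)
    assert (dataset["label"] == 0).sum() == 510
    with pytest.raises(InsufficientDataError):
        assemble_dataset(_feature_frame(pos), _aug_frame(pos, 50), staged_neg, seed=3)


def test_group_split_keeps_groups_and_variants_together(assembled):
    parts = group_split(assembled, seed=4)
    joined = assembled.assign(partition=parts.to_numpy())
    spread = joined.groupby("group")["partition"].nunique()
    assert (spread == 1).all()
    # variants co-located with their parent pair
    parent = joined[joined["origin"] == "original"].set_index(["protein_a", "protein_b"])
    for (a, b), sub in joined[joined["origin"] == "augmented"].groupby(
        ["protein_a", "protein_b"]
    ):
        assert set(sub["partition"]) == {parent.loc[(a, b), "partition"]}
    sizes = joined["partition"].value_counts(normalize=True)
    assert sizes["train"] > sizes["validation"]
    assert sizes["train"] > sizes["test"]


def test_group_split_fraction_of_equal_groups():
    rows = []
    for g in range(10):
        for r in range(4):
            rows.append({"row_id": f"g{g}r{r}", "protein_a": f"A{g}", "protein_b": f"B{g}",
                         **{f: 0.5 for f in FEATURE_NAMES}, "label": g % 2,
                         "group": f"A{g}", "origin": "original"})
    dataset = pd.DataFrame(rows)
    parts = group_split(dataset, seed=0)
    counts = pd.Series(parts.to_numpy()).value_counts()
    assert counts["train"] == 32 and counts["validation"] == 4 and counts["test"] == 4


def _fit(assembled, seed=6, grid=None):
    parts = group_split(assembled, seed=seed)
    arr = parts.to_numpy()
    grid = grid or {"max_depth": [4], "learning_rate": [0.1], "subsample": [1.0]}
    bundle = train_and_tune(
        assembled[arr == "train"], assembled[arr == "validation"],
        grid=grid, seed=seed,
    )
    return bundle, assembled[arr == "test"]


def test_training_on_separable_features(assembled):
    bundle, test_rows = _fit(assembled)
    assert bundle.params["max_depth"] in DEFAULT_GRID["max_depth"]
    curves = evaluate_curves(bundle, test_rows)
    assert curves.auroc > 0.95
    assert curves.auprc > 0.95
    train_neg = bundle.scale_pos_weight
    assert train_neg > 0


def test_tuned_hyperparameters_stay_in_grid(assembled):
    grid = {"max_depth": [4, 6], "learning_rate": [0.05, 0.1], "subsample": [0.8]}
    bundle, _ = _fit(assembled, grid=grid)
    assert bundle.params["max_depth"] in grid["max_depth"]
    assert bundle.params["learning_rate"] in grid["learning_rate"]
    assert bundle.params["subsample"] in grid["subsample"]
    assert len(bundle.tuning_history) == 4


def test_model_bundle_persists_booster_and_sidecar(assembled, tmp_path):
    import json

    import xgboost as xgb

    bundle, test_rows = _fit(assembled)
    out = tmp_path / "model.ubj"
    bundle.save(out)
    sidecar = json.loads(out.with_suffix(".json").read_text())
    assert sidecar["feature_names"] == list(FEATURE_NAMES)
    assert sidecar["params"] == bundle.params
    booster = xgb.Booster()
    booster.load_model(str(out))
    dm = xgb.DMatrix(test_rows[FEATURE_NAMES].to_numpy(dtype=float))
    # the wrapper predicts at the early-stopped best iteration
    rounds = (0, bundle.model.best_iteration + 1)
    np.testing.assert_allclose(
        booster.predict(dm, iteration_range=rounds),
        bundle.predict_proba(test_rows),
        atol=1e-6,
    )


def test_label_permutation_gives_chance_auroc(assembled):
    rng = np.random.default_rng(11)
    shuffled = assembled.copy()
    shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
    bundle, test_rows = _fit(shuffled, seed=11)
    curves = evaluate_curves(bundle, test_rows)
    assert 0.4 < curves.auroc < 0.6


def brute_force_auroc(y, score):
    """P(score_pos > score_neg) + 0.5 P(tie), by exhaustive comparison."""
    pos = score[y == 1]
    neg = score[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auroc_matches_pairwise_comparison_oracle(assembled):
    bundle, test_rows = _fit(assembled)
    curves = evaluate_curves(bundle, test_rows)
    prob = bundle.predict_proba(test_rows)
    oracle = brute_force_auroc(test_rows["label"].to_numpy(), prob)
    assert curves.auroc == pytest.approx(oracle, abs=1e-10)


def test_perfect_and_inverted_rankings():
    rows = pd.DataFrame(
        {
            **{f: np.linspace(0, 1, 10) for f in FEATURE_NAMES},
            "label": [0] * 5 + [1] * 5,
        }
    )
    # synthetic "model": use a passthrough by scoring with one feature
    y = rows["label"].to_numpy()
    perfect = rows["pearson_raw"].to_numpy()
    assert brute_force_auroc(y, perfect) == 1.0
    assert brute_force_auroc(y, -perfect) == 0.0


class TestPrecision:
    def test_strict_precision_counts_unknowns_as_false(self):
        preds = pd.DataFrame(
            {
                "prob": [0.99, 0.98, 0.97, 0.96, 0.5],
                "label": ["positive", "positive", "unknown", "negative", "positive"],
            }
        )
        assert strict_precision(preds, threshold=0.95) == pytest.approx(0.5)

    def test_strict_precision_all_positive(self):
        preds = pd.DataFrame({"prob": [0.99, 0.98], "label": ["positive", "positive"]})
        assert strict_precision(preds, threshold=0.95) == 1.0

    def test_strict_precision_empty_selection_is_nan(self):
        preds = pd.DataFrame({"prob": [0.1], "label": ["positive"]})
        assert np.isnan(strict_precision(preds, threshold=0.95))

    def test_weighted_curve_hand_example(self):
        preds = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "prob": [0.99, 0.8, 0.6],
                "label": ["positive", "unknown", "negative"],
            }
        )
        curve = weighted_precision_curve(preds)["weighted_precision"]
        np.testing.assert_allclose(curve, [1.0, 0.9, 0.6])

    def test_all_positive_curve_is_constant_one(self):
        preds = pd.DataFrame(
            {"prob": [0.9, 0.7, 0.3], "label": ["positive"] * 3}
        )
        np.testing.assert_allclose(
            weighted_precision_curve(preds)["weighted_precision"], 1.0
        )

    def test_weighted_dominates_strict_at_every_rank(self):
        rng = np.random.default_rng(2)
        n = 300
        preds = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n)],
                "prob": rng.random(n),
                "label": rng.choice(["positive", "negative", "unknown"], size=n),
            }
        )
        curve = weighted_precision_curve(preds)
        strict_cum = np.cumsum(curve["label"] == "positive") / np.arange(1, n + 1)
        assert (curve["weighted_precision"].to_numpy() >= strict_cum - 1e-12).all()
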