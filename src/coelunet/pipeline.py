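"""End-to-end demonstration pipeline on the synthetic complexome.

Chains every stage - simulation, gold-standard curation, feature
computation, two-phase training-set construction, XGBoost training and the
differential analysis - and reports held-out classifier performance plus
recovery of the planted fold-change complexes.  Used by the worked example
and by the recovery checks; all randomness derives from one seed.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import augment as _augment
from . import classify as _classify
from . import differential as _diff
from . import goldstd as _gold
from . import staging as _staging
from .features import pair_feature_table
from .scheme import FractionScheme
from .simulate import SimConfig, SimTruth, simulate_complexome, simulate_databases

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    truth: SimTruth
    labels: _gold.LabelTable
    staged: _staging.StagedSet
    selected: set[tuple[str, str]]
    dataset: pd.DataFrame
    partitions: pd.Series
    bundle: _classify.ModelBundle
    test_curves: _classify.CurveSet
    differential_table: pd.DataFrame
    differential_sensitivity: float
    differential_fdr: float


def run_pipeline(
    seed: int = 7,
    config: SimConfig | None = None,
    scheme: FractionScheme | None = None,
    decoy_fraction: float = 0.1,
) -> PipelineResult:
    """Run the whole workflow on one simulated case/control complexome."""
    scheme = scheme or FractionScheme()
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)

    log.info("simulating complexome (seed %d)", config.seed)
    matrix, truth = simulate_complexome(config, scheme)
    dbs = simulate_databases(truth, decoy_fraction=decoy_fraction, seed=seed + 1)

    with tempfile.TemporaryDirectory() as tmp:
        paths = dbs.write(tmp)
        records = []
        for dialect in ("corum-like", "humap-like", "portal-like"):
            records.append(_gold.parse_complex_table(paths[dialect], dialect))
        refined = [
            _gold.refine_against_proteome(recs, paths["fasta"]) for recs in records
        ]
    pairset = _gold.expand_to_pairs(*refined)
    gold_proteins = {p for recs in refined for r in recs for p in r.members}
    labels = _gold.label_pairs(matrix.proteins, pairset.pairs, gold_proteins)

    control = config.conditions[0]
    case = config.conditions[1] if len(config.conditions) > 1 else None

    staged = _staging.downsample_negatives(labels, ratio=5, seed=seed + 2)
    log.info("computing features for %d staged pairs", len(staged.all_pairs()))
    staged_features = pair_feature_table(matrix, staged.all_pairs(), condition=control)
    scores = _staging.first_stage_scores(staged_features, staged, n_folds=5, seed=seed + 3)
    selected = _staging.select_high_confidence(scores, staged.positives)

    log.info("augmenting %d high-confidence positives", len(selected))
    augmented = _augment.augment_dataset(matrix, selected, condition=control, seed=seed + 4)

    originals = staged_features.loc[sorted(selected)]
    staged_neg_features = staged_features.loc[staged.negatives]
    n_pos_rows = len(originals) + len(augmented)
    all_negatives = labels.pairs_with_label("negative")
    extra = sorted(set(all_negatives) - set(staged.negatives))
    n_extra = max(0, n_pos_rows - len(staged_neg_features))
    extra_features = None
    if n_extra > 0 and extra:
        take = rng.choice(len(extra), size=min(len(extra), n_extra + 50), replace=False)
        log.info("computing features for %d top-up negatives", len(take))
        extra_features = pair_feature_table(
            matrix, [extra[i] for i in sorted(take)], condition=control
        )
    dataset = _classify.assemble_dataset(
        originals, augmented, staged_neg_features, seed=seed + 5,
        extra_negatives=extra_features,
    )
    partitions = _classify.group_split(dataset, seed=seed + 6)
    train = dataset[partitions.to_numpy() == "train"]
    val = dataset[partitions.to_numpy() == "validation"]
    test = dataset[partitions.to_numpy() == "test"]
    log.info("training on %d rows (val %d, test %d)", len(train), len(val), len(test))
    bundle = _classify.train_and_tune(train, val, seed=seed + 7)
    curves = _classify.evaluate_curves(bundle, test)
    log.info("held-out AUROC %.3f / AUPRC %.3f", curves.auroc, curves.auprc)

    diff_table = pd.DataFrame()
    sensitivity, fdr = float("nan"), float("nan")
    if case is not None:
        calibration = _diff.MWCalibration.fit(dbs.calibration_standards)
        annotated = dbs.annotated_mw.set_index("accession")["mw_kda"]
        diff_table = _diff.differential_analysis(
            matrix, sorted(pairset.pairs), case=case, control=control,
            calibration=calibration, annotated_mw=annotated,
        )
        planted = truth.differential_pairs()
        if not diff_table.empty:
            called = {
                (r.protein_a, r.protein_b)
                for r in diff_table.itertuples() if r.called
            }
            evaluable = {
                (r.protein_a, r.protein_b) for r in diff_table.itertuples()
            }
            planted_eval = planted & evaluable
            if planted_eval:
                sensitivity = len(called & planted_eval) / len(planted_eval)
            fdr = (len(called - planted) / len(called)) if called else 0.0
            log.info("differential sensitivity %.2f, empirical FDR %.3f", sensitivity, fdr)

    return PipelineResult(
        truth=truth,
        labels=labels,
        staged=staged,
        selected=selected,
        dataset=dataset,
        partitions=partitions,
        bundle=bundle,
        test_curves=curves,
        differential_table=diff_table,
        differential_sensitivity=sensitivity,
        differential_fdr=fdr,
    )
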