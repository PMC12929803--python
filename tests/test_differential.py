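"""Differential co-elution: intensities, RT/MW filters, LRT, BH, modules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coelunet import (
    FractionScheme,
    MWCalibration,
    bh_adjust,
    call_differential,
    cluster_modules,
    lrt_test,
    mw_filter,
    pair_intensity,
    rt_reproducibility_filter,
)
from coelunet.exceptions import ConfigurationError, InsufficientDataError
from conftest import build_matrix, gaussian_trace


@pytest.fixture()
def sch():
    return FractionScheme(n_fractions=40, start_s=0.0, width_s=19.0)


def _shifted_pair_matrix(sch, shifts):
    """One pair per shift d: protein B's apex moves by d fractions in rep 3."""
    traces = {}
    for d in shifts:
        a, b = f"A{d}", f"B{d}"
        traces[a] = {("c", r): list(gaussian_trace(sch, 15.0)) for r in "123"}
        traces[b] = {
            ("c", "1"): list(gaussian_trace(sch, 20.0)),
            ("c", "2"): list(gaussian_trace(sch, 20.0)),
            ("c", "3"): list(gaussian_trace(sch, 20.0 + d)),
        }
    return build_matrix(traces, sch)


class TestPairIntensity:
    def test_sum_of_dominant_peak_areas(self, sch):
        m = build_matrix(
            {
                "A": {("c", "1"): list(gaussian_trace(sch, 15.0, height=3.0))},
                "B": {("c", "1"): list(gaussian_trace(sch, 15.0, height=2.0))},
            },
            sch,
        )
        only_a = pair_intensity(("A", "A"), m, ("c", "1")) / 2
        only_b = pair_intensity(("B", "B"), m, ("c", "1")) / 2
        both = pair_intensity(("A", "B"), m, ("c", "1"))
        assert both == pytest.approx(only_a + only_b)

    def test_all_missing_trace_skips_pair(self, sch):
        m = build_matrix(
            {
                "A": {("c", "1"): list(gaussian_trace(sch, 15.0))},
                "B": {("c", "1"): [np.nan] * sch.n_fractions},
            },
            sch,
        )
        assert pair_intensity(("A", "B"), m, ("c", "1")) is None

    def test_matches_analytic_gaussian_trapezoid(self, sch):
        # the declared peak region: walk from the apex of the 3-point-smoothed
        # trace down to the first fraction below 10% of the apex (inclusive);
        # for a noise-free Gaussian that region is derived here from scratch
        apex, sigma, h = 20.0, 2.0, 1e6
        f = np.arange(1, sch.n_fractions + 1, dtype=float)
        y = h * np.exp(-0.5 * ((f - apex) / sigma) ** 2)
        s = np.convolve(np.pad(y, 1, mode="edge"), np.ones(3) / 3, mode="valid")
        a = int(np.argmax(s))
        inside = np.flatnonzero(s >= 0.1 * s[a])
        lo, hi = max(inside[0] - 1, 0), min(inside[-1] + 1, len(y) - 1)
        analytic = float(np.trapezoid(y[lo : hi + 1], dx=sch.width_s))
        m = build_matrix({"A": {("c", "1"): list(y)}, "B": {("c", "1"): list(y)}}, sch)
        got = pair_intensity(("A", "B"), m, ("c", "1"))
        assert got == pytest.approx(2 * analytic, rel=1e-9)


class TestRTFilter:
    def test_one_fraction_shift_passes(self, sch):
        m = _shifted_pair_matrix(sch, [1])
        ok, shift, _ = rt_reproducibility_filter(
            ("A1", "B1"), m, [("c", r) for r in "123"]
        )
        assert ok and shift == pytest.approx(19.0)

    def test_three_fraction_shift_fails(self, sch):
        m = _shifted_pair_matrix(sch, [3])
        ok, shift, reason = rt_reproducibility_filter(
            ("A3", "B3"), m, [("c", r) for r in "123"]
        )
        assert not ok and "B3" in reason

    def test_identical_replicates_pass_with_zero_shift(self, sch):
        m = _shifted_pair_matrix(sch, [0])
        ok, shift, _ = rt_reproducibility_filter(
            ("A0", "B0"), m, [("c", r) for r in "123"]
        )
        assert ok and shift == 0.0

    def test_single_replicate_fails_with_reason(self, sch):
        m = _shifted_pair_matrix(sch, [0])
        ok, _, reason = rt_reproducibility_filter(("A0", "B0"), m, [("c", "1")])
        assert not ok and "replicates" in reason

    def test_boundary_is_inclusive_at_two_fractions(self, sch):
        m = _shifted_pair_matrix(sch, [2])
        ok, shift, _ = rt_reproducibility_filter(
            ("A2", "B2"), m, [("c", r) for r in "123"]
        )
        assert ok and shift == pytest.approx(38.0)


class TestMWFilter:
    @pytest.fixture()
    def cal(self):
        standards = pd.DataFrame(
            {"fraction": [5, 15, 25, 35, 45], "mw_kda": [2000, 700, 250, 90, 30]}
        )
        return MWCalibration.fit(standards)

    def test_complexed_elution_passes(self, cal):
        apex = 10.0  # apparent ~ 1200 kDa
        assert mw_filter(apex, cal, 50.0)

    def test_late_elution_of_large_protein_fails(self, cal):
        apex = 45.0  # apparent ~ 30 kDa
        assert not mw_filter(apex, cal, 50.0)

    def test_boundary_inclusive(self, cal):
        apex = 20.0
        apparent = cal.apparent_mw_kda(apex)
        assert mw_filter(apex, cal, apparent)

    def test_increasing_calibration_rejected(self):
        bad = pd.DataFrame({"fraction": [5, 15], "mw_kda": [30, 700]})
        with pytest.raises(ConfigurationError):
            MWCalibration.fit(bad)


class TestLRT:
    def test_identical_groups_give_p_one(self):
        stat, p = lrt_test([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert stat == pytest.approx(0.0)
        assert p == 1.0

    def test_eightfold_change_with_variance_floor(self):
        stat, p = lrt_test([800.0, 800.0, 800.0], [100.0, 100.0, 100.0])
        assert p < 0.01

    def test_positive_intensities_required(self):
        with pytest.raises(ConfigurationError):
            lrt_test([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])
        with pytest.raises(InsufficientDataError):
            lrt_test([1.0], [1.0, 1.0])

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(0)
        n_reps = 10_000
        rejections = 0
        ps = np.empty(n_reps)
        for i in range(n_reps):
            case = np.exp(rng.normal(0, 0.3, size=3))
            ctrl = np.exp(rng.normal(0, 0.3, size=3))
            _, p = lrt_test(case, ctrl)
            ps[i] = p
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.08
        # null p-values approximately uniform
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05


class TestBH:
    def test_hand_computed_adjustment(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(4)
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_step_up_oracle_on_random_inputs(self):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.2])


class TestCallRule:
    def _row(self, q, fc, rt=True, mw=True):
        return {
            "protein_a": "A", "protein_b": "B", "mean_case": 2.0, "mean_control": 1.0,
            "fold_change": fc, "median_fold_change": fc, "max_delta_rt_s": 0.0,
            "rt_ok": rt, "mw_ok": mw, "lrt_stat": 1.0, "p_value": q, "q_value": q,
        }

    @pytest.mark.parametrize(
        "q,fc,rt,mw,called",
        [
            (0.01, 2.0, True, True, True),
            (0.01, 1.2, True, True, False),
            (0.2, 3.0, True, True, False),
            (0.01, 0.4, True, True, True),   # down-regulation passes two-sided rule
            (0.01, 2.0, False, True, False),
            (0.01, 2.0, True, False, False),
        ],
    )
    def test_gating(self, q, fc, rt, mw, called):
        table = pd.DataFrame([self._row(q, fc, rt, mw)])
        out = call_differential(table)
        assert bool(out["called"].iloc[0]) == called
        if called:
            assert out["direction"].iloc[0] == ("up" if fc > 1 else "down")

    def test_filter_order_independent(self):
        rng = np.random.default_rng(5)
        rows = [
            self._row(float(rng.random()), float(rng.uniform(0.2, 4.0)),
                      bool(rng.random() < 0.8), bool(rng.random() < 0.8))
            for _ in range(50)
        ]
        table = pd.DataFrame(rows)
        a = call_differential(table)["called"]
        shuffled = table.sample(frac=1.0, random_state=1)
        b = call_differential(shuffled)["called"].sort_index()
        assert a.tolist() == b.tolist()


class TestModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        block1 = np.tile([1.0, 5.0, 1.0, 5.0], (10, 3)) + rng.normal(0, 0.05, (10, 12))
        block2 = np.tile([5.0, 1.0, 5.0, 1.0], (10, 3)) + rng.normal(0, 0.05, (10, 12))
        table = pd.DataFrame(np.vstack([block1, block2]))
        modules = cluster_modules(table, cut_height=4.0)
        assert modules.nunique() == 2
        assert modules.iloc[:10].nunique() == 1
        assert modules.iloc[10:].nunique() == 1

    def test_extreme_cuts(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.random((8, 6)))
        assert cluster_modules(table, cut_height=1e9).nunique() == 1
        assert cluster_modules(table, cut_height=1e-9).nunique() == 8

    def test_single_row_single_module(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0]])
        assert cluster_modules(table).tolist() == [1]

    def test_singleton_pooling_option(self):
        rng = np.random.default_rng(8)
        block = np.tile([1.0, 5.0, 1.0], (6, 2)) + rng.normal(0, 0.02, (6, 6))
        outliers = rng.normal(0, 5.0, (2, 6))
        table = pd.DataFrame(np.vstack([block, outliers]))
        modules = cluster_modules(table, cut_height=2.0, pool_singletons=True)
        assert modules.iloc[:6].nunique() == 1
        assert set(modules.iloc[6:]) == {modules.max()}


def test_planted_fold_changes_recovered(scheme, small_sim):
    from coelunet import differential_analysis, simulate_databases

    matrix, truth = small_sim
    dbs = simulate_databases(truth, decoy_fraction=0.0, seed=12)
    cal = MWCalibration.fit(dbs.calibration_standards)
    annotated = dbs.annotated_mw.set_index("accession")["mw_kda"]
    table = differential_analysis(
        matrix, sorted(truth.truth_pairs()), case="case", control="control",
        calibration=cal, annotated_mw=annotated,
    )
    planted = truth.differential_pairs()
    called = {(r.protein_a, r.protein_b) for r in table.itertuples() if r.called}
    evaluable = {(r.protein_a, r.protein_b) for r in table.itertuples()}
    sens = len(called & planted) / len(planted & evaluable)
    fdr = len(called - planted) / max(len(called), 1)
    assert sens >= 0.8
    assert fdr <= 0.1
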