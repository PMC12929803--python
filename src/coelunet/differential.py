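"""Differential co-elution analysis between a case and a control condition.

The intensity of a protein pair in one replicate is the sum of the two
proteins' dominant chromatographic peak areas.  Pairs are tested for a
condition effect with a nested Gaussian likelihood-ratio test on log2 pair
intensities, corrected with Benjamini-Hochberg, and called differential
only when they additionally pass

* the retention-time reproducibility filter (apex shift across replicates
  at most two fraction widths, 38 s at 19 s/fraction, for both proteins in
  both conditions),
* the molecular-weight filter (apparent SEC mass at the apex at least the
  annotated monomer mass, for both proteins), and
* a two-sided fold-change rule (ratio > 1.5 or < 1/1.5 by default).

Called pairs are grouped into modules by average-linkage hierarchical
clustering of their z-scored intensity profiles, cut at a fixed height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier
from scipy.spatial import distance as _dist
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, InsufficientDataError
from .goldstd import Pair, pair_key
from .profiles import PeakCall, ProfileMatrix, dominant_peak, interpolate_missing

log = logging.getLogger(__name__)

DEFAULT_MAX_SHIFT_S = 38.0       # two fractions at 19 s
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05
DEFAULT_CUT_HEIGHT = 50.0
VARIANCE_FLOOR_REL = 1e-6        # floor = 1e-6 * mean(log2 intensity)^2


# ---------------------------------------------------------------------------
# molecular-weight calibration
# ---------------------------------------------------------------------------

@dataclass
class MWCalibration:
    """Log-linear SEC calibration fitted to standards: log10(kDa) ~ fraction."""

    intercept: float
    slope: float

    @classmethod
    def fit(cls, standards: pd.DataFrame) -> "MWCalibration":
        """Fit from a table with columns ``fraction`` and ``mw_kda``."""
        if len(standards) < 2:
            raise InsufficientDataError("need at least 2 calibration standards")
        res = _stats.linregress(standards["fraction"], np.log10(standards["mw_kda"]))
        if res.slope >= 0:
            raise ConfigurationError(
                "SEC calibration must have MW decreasing with fraction"
            )
        return cls(intercept=float(res.intercept), slope=float(res.slope))

    def apparent_mw_kda(self, apex_fraction: float) -> float:
        return 10.0 ** (self.intercept + self.slope * apex_fraction)


def mw_filter(
    apex_fraction: float, calibration: MWCalibration, annotated_mw_kda: float
) -> bool:
    """Pass iff the apparent mass at the apex >= the annotated monomer mass.

    A protein eluting at a mass larger than its monomer is compatible with
    complexed elution; the boundary (apparent == annotated) passes.
    """
    if annotated_mw_kda is None or np.isnan(annotated_mw_kda):
        raise ConfigurationError("annotated molecular weight is missing")
    return calibration.apparent_mw_kda(apex_fraction) >= annotated_mw_kda


# ---------------------------------------------------------------------------
# pair intensity and reproducibility
# ---------------------------------------------------------------------------

def _dominant(
    matrix: ProfileMatrix,
    prot: str,
    sample: tuple[str, str],
    cache: dict | None = None,
) -> PeakCall | None:
    """Dominant peak of a reconstructed chromatogram (interior missing
    fractions linearly interpolated before peak calling)."""
    if cache is not None and (prot, sample) in cache:
        return cache[(prot, sample)]
    trace = interpolate_missing(matrix.trace(prot, sample))
    pk = dominant_peak(trace, matrix.scheme)
    if cache is not None:
        cache[(prot, sample)] = pk
    return pk


def pair_intensity(
    pair: Pair,
    matrix: ProfileMatrix,
    sample: tuple[str, str],
    _cache: dict | None = None,
) -> float | None:
    """Sum of the two proteins' dominant-peak areas in one sample.

    Returns None (pair skipped) when either trace yields no peak.
    """
    a, b = pair
    peaks = []
    for prot in (a, b):
        pk = _dominant(matrix, prot, sample, _cache)
        if pk is None:
            log.debug("pair %s skipped in %s: %s has no peak", pair, sample, prot)
            return None
        peaks.append(pk)
    return float(sum(p.area for p in peaks))


def rt_reproducibility_filter(
    pair: Pair,
    matrix: ProfileMatrix,
    samples: list[tuple[str, str]],
    max_shift_s: float = DEFAULT_MAX_SHIFT_S,
    _cache: dict | None = None,
) -> tuple[bool, float, str]:
    """Across-replicate apex retention-time reproducibility of a pair.

    For each protein the maximum pairwise apex-RT difference across the
    given samples is taken; the pair passes iff both maxima are at most
    ``max_shift_s``.  Returns (pass, max shift observed, reason).
    """
    if len(samples) < 2:
        return False, float("nan"), "fewer than 2 replicates"
    worst = 0.0
    for prot in pair:
        rts = []
        for sample in samples:
            pk = _dominant(matrix, prot, sample, _cache)
            if pk is not None:
                rts.append(pk.apex_rt_s)
        if len(rts) < 2:
            return False, float("nan"), f"{prot}: peaks in fewer than 2 replicates"
        shift = max(rts) - min(rts)
        worst = max(worst, shift)
        if shift > max_shift_s:
            return False, worst, f"{prot}: apex shift {shift:.1f}s > {max_shift_s:.1f}s"
    return True, worst, ""


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def lrt_test(
    case: np.ndarray | list[float], control: np.ndarray | list[float]
) -> tuple[float, float]:
    """Likelihood-ratio test of a condition effect on log2 pair intensity.

    Nested Gaussian means model: null = one common mean, alternative =
    separate group means with shared variance.  Returns (statistic, p).
    The statistic is Lambda = n * ln(RSS0/RSS1) with a relative variance
    floor (1e-6 x mean^2) guarding degenerate zero-variance replicates;
    the p-value is taken from the exact finite-sample reference of the
    equivalent F statistic, F(1, n-2), which keeps the null distribution
    uniform even at 3+3 replicates where the chi-square(1) asymptote is
    anticonservative.
    """
    y1 = np.asarray(case, dtype=float)
    y0 = np.asarray(control, dtype=float)
    if len(y1) < 2 or len(y0) < 2:
        raise InsufficientDataError("need >= 2 replicates per group")
    if np.any(y1 <= 0) or np.any(y0 <= 0):
        raise ConfigurationError("intensities must be positive for the log model")
    l1, l0 = np.log2(y1), np.log2(y0)
    y = np.concatenate([l1, l0])
    n = len(y)
    floor = VARIANCE_FLOOR_REL * float(np.mean(y)) ** 2
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = float(np.sum((l1 - l1.mean()) ** 2) + np.sum((l0 - l0.mean()) ** 2))
    rss0 = max(rss0, n * floor)
    rss1 = max(rss1, n * floor)
    stat = n * np.log(rss0 / rss1)
    f_stat = (rss0 - rss1) / (rss1 / (n - 2))
    p = float(_stats.f.sf(max(f_stat, 0.0), 1, n - 2))
    return float(stat), min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the differential table
# ---------------------------------------------------------------------------

def differential_analysis(
    matrix: ProfileMatrix,
    pairs,
    case: str,
    control: str,
    calibration: MWCalibration,
    annotated_mw: dict[str, float] | pd.Series,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    max_shift_s: float = DEFAULT_MAX_SHIFT_S,
) -> pd.DataFrame:
    """Score every candidate pair and apply all differential filters.

    Returns one row per evaluable pair with per-condition mean intensities,
    mean-based and median-of-ratios fold changes, the maximum apex RT shift,
    filter flags, LRT p, BH q and the final ``called`` flag with direction.
    """
    if isinstance(annotated_mw, pd.Series):
        annotated_mw = annotated_mw.to_dict()
    case_samples = [(case, r) for r in matrix.replicates(case)]
    ctrl_samples = [(control, r) for r in matrix.replicates(control)]
    cache: dict = {}
    rows = []
    for pair in sorted({pair_key(*p) for p in pairs}):
        a, b = pair
        case_int = [pair_intensity(pair, matrix, s, _cache=cache) for s in case_samples]
        ctrl_int = [pair_intensity(pair, matrix, s, _cache=cache) for s in ctrl_samples]
        if any(v is None for v in case_int + ctrl_int):
            log.debug("pair %s skipped: missing intensity in a replicate", pair)
            continue
        case_int = np.array(case_int, dtype=float)
        ctrl_int = np.array(ctrl_int, dtype=float)
        mean_case, mean_ctrl = float(case_int.mean()), float(ctrl_int.mean())
        fc = mean_case / mean_ctrl if mean_ctrl > 0 else np.nan
        k = min(len(case_int), len(ctrl_int))
        median_fc = float(np.median(case_int[:k] / ctrl_int[:k]))

        rt_ok = True
        max_shift = 0.0
        for samples in (case_samples, ctrl_samples):
            ok, shift, _ = rt_reproducibility_filter(
                pair, matrix, samples, max_shift_s, _cache=cache
            )
            rt_ok = rt_ok and ok
            if np.isfinite(shift):
                max_shift = max(max_shift, shift)

        mw_ok = True
        for prot in pair:
            if prot not in annotated_mw or pd.isna(annotated_mw[prot]):
                mw_ok = False
                log.debug("pair %s: no annotated MW for %s", pair, prot)
                break
            shifts = []
            for s in case_samples + ctrl_samples:
                pk = _dominant(matrix, prot, s, cache)
                if pk is not None:
                    shifts.append(pk.apex_fraction)
            apex = float(np.median(shifts))
            if not mw_filter(apex, calibration, annotated_mw[prot]):
                mw_ok = False
                break

        stat, p = lrt_test(case_int, ctrl_int)
        rows.append(
            {
                "protein_a": a, "protein_b": b,
                "mean_case": mean_case, "mean_control": mean_ctrl,
                "fold_change": fc, "median_fold_change": median_fc,
                "max_delta_rt_s": max_shift, "rt_ok": rt_ok, "mw_ok": mw_ok,
                "lrt_stat": stat, "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    return call_differential(table, alpha=alpha, fc_threshold=fc_threshold)


def call_differential(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Apply the call rule: RT pass AND MW pass AND q <= alpha AND two-sided
    fold change (> fc_threshold or < 1/fc_threshold).  Order-independent."""
    out = table.copy()
    fc = out["fold_change"]
    fc_pass = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
    out["called"] = out["rt_ok"] & out["mw_ok"] & (out["q_value"] <= alpha) & fc_pass
    out["direction"] = np.where(
        ~out["called"], "", np.where(fc > 1.0, "up", "down")
    )
    return out


# ---------------------------------------------------------------------------
# module extraction
# ---------------------------------------------------------------------------

def cluster_modules(
    intensity: pd.DataFrame,
    linkage: str = "average",
    cut_height: float = DEFAULT_CUT_HEIGHT,
    pool_singletons: bool = False,
) -> pd.Series:
    """Cut a dendrogram of z-scored pair-intensity profiles into modules.

    ``intensity`` has one row per called pair and one column per sample or
    fraction.  Rows are z-scored, clustered on Euclidean distance with the
    given linkage, and branches merging below ``cut_height`` become modules
    1..X.  With ``pool_singletons``, rows that never merge below the cut are
    pooled into one extra module X + 1 (assemblies only stable above the
    threshold); by default they stay as their own modules.
    """
    if linkage not in ("average", "ward"):
        raise ConfigurationError("linkage must be 'average' or 'ward'")
    if len(intensity) < 2:
        return pd.Series(np.ones(len(intensity), dtype=int), index=intensity.index, name="module_id")
    values = intensity.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    method = "ward" if linkage == "ward" else "average"
    tree = _hier.linkage(_dist.pdist(z, metric="euclidean"), method=method)
    labels = _hier.fcluster(tree, t=cut_height, criterion="distance")
    if pool_singletons:
        counts = pd.Series(labels).value_counts()
        singletons = set(counts[counts == 1].index)
        multi = sorted(set(labels) - singletons)
        remap = {old: new for new, old in enumerate(multi, start=1)}
        overflow = len(multi) + 1
        labels = np.array([remap.get(l, overflow) for l in labels], dtype=int)
    return pd.Series(labels, index=intensity.index, name="module_id")
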