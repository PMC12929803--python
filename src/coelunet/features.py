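"""The five co-elution features of a protein pair, plus n_valid.

For two elution traces x and y over the same fraction scheme:

* ``pearson_raw``      - Pearson r over the jointly observed fractions;
* ``pearson_smoothed`` - Pearson r of the 3-point smoothed traces over the
  same joint support;
* ``euclidean``        - L2 distance of the max-normalized traces
  (missing treated as 0);
* ``co_peak``          - fraction of matched peak apexes within a tolerance,
  |matches| / max(#peaks_x, #peaks_y);
* ``wcc``              - lag-windowed, triangularly weighted normalized
  cross-correlation;

and ``n_valid``, the number of fractions where both traces are observed.
Degenerate inputs (fewer than 3 joint fractions, zero variance, all-zero
signals) map to 0 and are flagged rather than propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError
from .profiles import PeakCall, ProfileMatrix, detect_peaks
from .scheme import FractionScheme

FEATURE_NAMES = ["pearson_raw", "pearson_smoothed", "euclidean", "co_peak", "wcc"]

FLAG_LOW_SUPPORT = "low_support"
FLAG_DEGENERATE = "degenerate"


@dataclass
class FeatureVector:
    pearson_raw: float
    pearson_smoothed: float
    euclidean: float
    co_peak: float
    wcc: float
    n_valid: int
    flags: frozenset[str] = frozenset()

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pearson_raw, self.pearson_smoothed, self.euclidean, self.co_peak, self.wcc]
        )


def smooth_profile(trace: Sequence[float], window: int = 3) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    Missing values are treated as 0 inside the window; ``window=1`` is the
    identity (apart from missing -> 0).
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 1")
    x = np.nan_to_num(np.asarray(trace, dtype=float))
    if window == 1:
        return x
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r from the definition; (0, True) when variance degenerates."""
    if len(x) < 2:
        return 0.0, True
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0, True
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0)), False


def wcc(x: Sequence[float], y: Sequence[float], w: int = 1) -> float:
    """Weighted cross-correlation over lags |l| <= w.

    Triangular weights omega_l = 1 - |l|/(w+1) on the raw cross/auto
    covariance sums c_xy(l) = sum_t x_t * y_{t+l}; missing is treated as 0.
    Returns 0 when either signal is all-zero.
    """
    xv = np.nan_to_num(np.asarray(x, dtype=float))
    yv = np.nan_to_num(np.asarray(y, dtype=float))
    if len(xv) != len(yv):
        raise FormatError("wcc requires equal-length traces")

    def weighted(u: np.ndarray, v: np.ndarray) -> float:
        total = 0.0
        for lag in range(-w, w + 1):
            omega = 1.0 - abs(lag) / (w + 1.0)
            if lag >= 0:
                c = float(u[: len(u) - lag] @ v[lag:]) if lag < len(u) else 0.0
            else:
                c = float(u[-lag:] @ v[: len(v) + lag]) if -lag < len(u) else 0.0
            total += omega * c
        return total

    denom = weighted(xv, xv) * weighted(yv, yv)
    if denom <= 0.0:
        return 0.0
    return float(np.clip(weighted(xv, yv) / np.sqrt(denom), -1.0, 1.0))


def _match_apexes(ax: Sequence[int], ay: Sequence[int], tol: float) -> int:
    """Greedy one-to-one apex matching by increasing apex distance."""
    candidates = sorted(
        ((abs(a - b), i, j) for i, a in enumerate(ax) for j, b in enumerate(ay)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_x: set[int] = set()
    used_y: set[int] = set()
    matches = 0
    for d, i, j in candidates:
        if d > tol:
            break
        if i in used_x or j in used_y:
            continue
        used_x.add(i)
        used_y.add(j)
        matches += 1
    return matches


def co_peak_frequency(
    x: Sequence[float],
    y: Sequence[float],
    scheme: FractionScheme,
    tol: float = 1.0,
    peaks_x: list[PeakCall] | None = None,
    peaks_y: list[PeakCall] | None = None,
) -> float:
    """Fraction of peak apexes co-occurring within ``tol`` fractions.

    Peaks are detected with the default peak caller on each trace; the score
    is |greedy apex matches within +-tol| / max(#peaks_x, #peaks_y), 0 when
    either trace has no peaks.  Symmetric in (x, y).
    """
    px = peaks_x if peaks_x is not None else detect_peaks(x, scheme)
    py = peaks_y if peaks_y is not None else detect_peaks(y, scheme)
    if not px or not py:
        return 0.0
    ax = [p.apex_fraction for p in px]
    ay = [p.apex_fraction for p in py]
    return _match_apexes(ax, ay, tol) / max(len(ax), len(ay))


@dataclass(frozen=True)
class FeatureParams:
    """Tunable knobs of the feature computation."""

    smooth_window: int = 3
    wcc_window: int = 1
    co_peak_tol: float = 1.0


def compute_pair_features(
    x: Sequence[float],
    y: Sequence[float],
    scheme: FractionScheme,
    params: FeatureParams = FeatureParams(),
    peaks_x: list[PeakCall] | None = None,
    peaks_y: list[PeakCall] | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one trace pair."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != scheme.n_fractions or len(yv) != scheme.n_fractions:
        raise FormatError("trace length must equal scheme.n_fractions")
    joint = ~np.isnan(xv) & ~np.isnan(yv)
    n_valid = int(joint.sum())
    flags: set[str] = set()

    if n_valid < 3:
        pr, ps = 0.0, 0.0
        flags.add(FLAG_LOW_SUPPORT)
    else:
        pr, deg_r = _pearson(xv[joint], yv[joint])
        xs = smooth_profile(xv, params.smooth_window)
        ys = smooth_profile(yv, params.smooth_window)
        ps, deg_s = _pearson(xs[joint], ys[joint])
        if deg_r or deg_s:
            flags.add(FLAG_DEGENERATE)

    x0 = np.nan_to_num(xv)
    y0 = np.nan_to_num(yv)
    xm = x0 / x0.max() if x0.max() > 0 else x0
    ym = y0 / y0.max() if y0.max() > 0 else y0
    euclidean = float(np.linalg.norm(xm - ym))
    co_peak = co_peak_frequency(
        x0, y0, scheme, tol=params.co_peak_tol, peaks_x=peaks_x, peaks_y=peaks_y
    )
    wcc_score = wcc(x0, y0, params.wcc_window)
    if not np.any(x0 > 0) or not np.any(y0 > 0):
        flags.add(FLAG_DEGENERATE)
    return FeatureVector(
        pearson_raw=pr,
        pearson_smoothed=ps,
        euclidean=euclidean,
        co_peak=co_peak,
        wcc=wcc_score,
        n_valid=n_valid,
        flags=frozenset(flags),
    )


def pair_feature_table(
    matrix: ProfileMatrix,
    pairs: Iterable[tuple[str, str]],
    condition: str | None = None,
    params: FeatureParams = FeatureParams(),
) -> pd.DataFrame:
    """Feature table for many pairs, on across-replicate mean traces.

    Traces are averaged over the replicates of ``condition`` (default: the
    matrix's first condition); per-protein traces and peak calls are cached,
    so the cost is linear in proteins plus pairs.  Returns a DataFrame
    indexed by (protein_a, protein_b) with the five features, ``n_valid``
    and a ``flags`` column.
    """
    cond = condition if condition is not None else matrix.conditions()[0]
    pair_list = [tuple(sorted(p)) for p in pairs]
    needed = sorted({p for pair in pair_list for p in pair})
    traces = {p: matrix.mean_trace(p, cond) for p in needed}
    peaks = {p: detect_peaks(np.nan_to_num(traces[p]), matrix.scheme) for p in needed}
    rows = []
    for a, b in pair_list:
        fv = compute_pair_features(
            traces[a], traces[b], matrix.scheme, params,
            peaks_x=peaks[a], peaks_y=peaks[b],
        )
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                **{name: getattr(fv, name) for name in FEATURE_NAMES},
                "n_valid": fv.n_valid,
                "flags": ";".join(sorted(fv.flags)),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["protein_a", "protein_b", *FEATURE_NAMES, "n_valid", "flags"]
        )
    return table.set_index(["protein_a", "protein_b"])
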