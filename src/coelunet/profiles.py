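"""Protein x fraction elution matrices: I/O, peak calling, retention time, QC.

The central container is :class:`ProfileMatrix`, a wide pandas DataFrame with
one row per protein and a (condition, replicate, fraction) column MultiIndex.
Missing intensities are stored as NaN and are never coerced to zero at read
time; zeros only appear transiently inside smoothing and peak integration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .exceptions import ConfigurationError, FormatError, InsufficientDataError
from .scheme import FractionScheme

log = logging.getLogger(__name__)

#: default regex for wide-TSV fraction columns, e.g. ``control_1_F17``
DEFAULT_COLUMN_PATTERN = r"(?P<condition>.+)_(?P<replicate>[^_]+)_F(?P<fraction>\d+)"


@dataclass
class ProfileMatrix:
    """Protein x fraction intensities for one or more (condition, replicate) samples.

    ``data`` has protein accessions as the index and a three-level column
    MultiIndex ``(condition, replicate, fraction)`` with fractions 1..n.
    """

    data: pd.DataFrame
    scheme: FractionScheme

    def __post_init__(self) -> None:
        if self.data.columns.nlevels != 3:
            raise FormatError("ProfileMatrix columns must be (condition, replicate, fraction)")
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy(dtype=float) < 0).any():
                raise FormatError("negative intensities are not allowed")
        # fast numpy access paths; trace() is called in tight loops downstream
        self._row: dict[str, int] = {p: i for i, p in enumerate(self.data.index)}
        self._blocks: dict[tuple[str, str], np.ndarray] = {}
        for sample in self.samples():
            cond, rep = sample
            cols = [
                (cond, rep, f) for f in range(1, self.scheme.n_fractions + 1)
            ]
            self._blocks[sample] = self.data.loc[:, cols].to_numpy(dtype=float)

    # -- accessors -----------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    def samples(self) -> list[tuple[str, str]]:
        """All (condition, replicate) sample keys, in column order."""
        seen: dict[tuple[str, str], None] = {}
        for cond, rep, _ in self.data.columns:
            seen.setdefault((cond, rep), None)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _, _ in self.data.columns:
            seen.setdefault(cond, None)
        return list(seen)

    def replicates(self, condition: str) -> list[str]:
        seen: dict[str, None] = {}
        for cond, rep, _ in self.data.columns:
            if cond == condition:
                seen.setdefault(rep, None)
        return list(seen)

    def sample_block(self, sample: tuple[str, str]) -> pd.DataFrame:
        """Protein x fraction DataFrame for one (condition, replicate)."""
        return pd.DataFrame(
            self._blocks[sample],
            index=self.data.index,
            columns=range(1, self.scheme.n_fractions + 1),
        )

    def trace(self, protein: str, sample: tuple[str, str]) -> np.ndarray:
        """Elution trace (length n_fractions, NaN = missing) of one protein."""
        return self._blocks[sample][self._row[protein]]

    def mean_trace(self, protein: str, condition: str) -> np.ndarray:
        """Across-replicate mean trace; positions missing everywhere stay NaN."""
        reps = self.replicates(condition)
        stack = np.vstack([self.trace(protein, (condition, r)) for r in reps])
        counts = (~np.isnan(stack)).sum(axis=0)
        sums = np.nansum(stack, axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # -- serialization -------------------------------------------------
    def to_tsv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{c}_{r}_F{f}" for c, r, f in flat.columns]
        flat.index.name = "protein"
        flat.to_csv(path, sep="\t", na_rep="NA")


def read_protein_matrix(
    path,
    scheme: FractionScheme,
    column_pattern: str = DEFAULT_COLUMN_PATTERN,
) -> ProfileMatrix:
    """Read a wide TSV protein matrix.

    Column 1 holds protein accessions; every remaining column must match
    ``column_pattern`` with named groups condition / replicate / fraction.
    Missing cells (blank or ``NA``) are preserved as NaN.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    pat = re.compile(column_pattern)
    tuples = []
    for col in raw.columns:
        m = pat.fullmatch(col)
        if m is None:
            raise FormatError(f"column {col!r} does not match pattern {column_pattern!r}")
        tuples.append((m.group("condition"), m.group("replicate"), int(m.group("fraction"))))
    dup = raw.index[raw.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate protein rows: {dup}")
    raw.columns = pd.MultiIndex.from_tuples(tuples, names=["condition", "replicate", "fraction"])
    # every sample must carry exactly the scheme's fractions
    for cond, rep, _ in raw.columns:
        fracs = sorted(f for c, r, f in raw.columns if (c, r) == (cond, rep))
        if fracs != list(range(1, scheme.n_fractions + 1)):
            raise FormatError(
                f"sample {cond}/{rep}: fractions {fracs[:3]}...{fracs[-1:]} "
                f"do not cover 1..{scheme.n_fractions}"
            )
    return ProfileMatrix(raw.astype(float), scheme)


def fraction_to_rt(f: int | float, scheme: FractionScheme) -> float:
    """Retention time (s) of fraction ``f`` under the midpoint convention."""
    return scheme.fraction_to_rt(f)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

@dataclass
class PeakCall:
    """One chromatographic peak of a single trace."""

    apex_fraction: int
    apex_rt_s: float
    area: float
    left: int
    right: int
    protein: str | None = None
    sample: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.left <= self.apex_fraction <= self.right:
            raise ValueError("peak boundaries must bracket the apex")


def interpolate_missing(trace: Sequence[float]) -> np.ndarray:
    """Reconstruct a chromatogram by linear interpolation over interior
    missing fractions; leading and trailing missing stretches stay missing.

    Used before peak-area integration so that a single dropped fraction near
    an apex does not split the peak or truncate its integration region.
    """
    x = np.asarray(trace, dtype=float).copy()
    obs = np.flatnonzero(~np.isnan(x))
    if len(obs) < 2:
        return x
    lo, hi = obs[0], obs[-1]
    inner = np.arange(lo, hi + 1)
    gaps = inner[np.isnan(x[inner])]
    if len(gaps):
        x[gaps] = np.interp(gaps, obs, x[obs])
    return x


def _smooth3_for_peaks(x: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication (peak detection only)."""
    padded = np.pad(x, 1, mode="edge")
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


def detect_peaks(
    trace: Sequence[float],
    scheme: FractionScheme,
    min_prominence_frac: float = 0.1,
    boundary_frac: float = 0.1,
    protein: str | None = None,
    sample: tuple[str, str] | None = None,
) -> list[PeakCall]:
    """Call peaks on one elution trace.

    The trace is 3-point smoothed (missing treated as 0); local maxima with
    prominence >= ``min_prominence_frac`` x the smoothed global maximum become
    apexes (edge maxima allowed).  Each peak region runs from the apex out to
    the nearest local minimum or the first fraction below
    ``boundary_frac`` x the apex value, and its area is the trapezoidal
    integral of the raw trace over that region in intensity x seconds.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) != scheme.n_fractions:
        raise FormatError(f"trace length {len(x)} != n_fractions {scheme.n_fractions}")
    raw = np.nan_to_num(x, nan=0.0)
    if not np.any(raw > 0):
        return []
    s = _smooth3_for_peaks(raw)
    smax = s.max()
    # zero-pad so that edge maxima are detectable by find_peaks
    padded = np.concatenate(([0.0], s, [0.0]))
    idx, _ = _signal.find_peaks(padded, prominence=min_prominence_frac * smax)
    calls: list[PeakCall] = []
    for i in idx - 1:
        apex_val = s[i]
        lo = i
        while lo > 0 and s[lo - 1] <= s[lo]:
            lo -= 1
            if s[lo] < boundary_frac * apex_val:
                break
        hi = i
        while hi < len(s) - 1 and s[hi + 1] <= s[hi]:
            hi += 1
            if s[hi] < boundary_frac * apex_val:
                break
        area = float(np.trapezoid(raw[lo : hi + 1], dx=scheme.width_s)) if hi > lo else 0.0
        calls.append(
            PeakCall(
                apex_fraction=int(i + 1),
                apex_rt_s=scheme.fraction_to_rt(i + 1),
                area=area,
                left=int(lo + 1),
                right=int(hi + 1),
                protein=protein,
                sample=sample,
            )
        )
    return calls


def dominant_peak(
    trace: Sequence[float], scheme: FractionScheme, **kwargs
) -> PeakCall | None:
    """The largest-area peak of a trace, or None for an empty trace."""
    calls = detect_peaks(trace, scheme, **kwargs)
    if not calls:
        return None
    return max(calls, key=lambda c: c.area)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Replicate agreement statistics per condition."""

    jaccard: pd.DataFrame   # condition, replicate_a, replicate_b, jaccard
    spearman: pd.DataFrame  # condition, replicate_a, replicate_b, spearman, n_shared
    cv: pd.DataFrame        # protein, condition, cv_percent

    def to_json_dict(self) -> dict:
        return {
            "jaccard": self.jaccard.to_dict(orient="records"),
            "spearman": self.spearman.to_dict(orient="records"),
            "cv_percent_median": (
                self.cv.groupby("condition")["cv_percent"].median().to_dict()
            ),
        }


def _abundance(block: pd.DataFrame) -> pd.Series:
    """Per-protein summed trace intensity; NaN where the protein is absent."""
    present = block.notna().any(axis=1)
    total = block.sum(axis=1, min_count=1)
    return total.where(present)


def replicate_qc(matrix: ProfileMatrix) -> QCReport:
    """Jaccard of identified-protein sets, Spearman of shared abundances and
    per-protein CV of summed intensity, per condition across replicates."""
    jac_rows, rho_rows, cv_rows = [], [], []
    for cond in matrix.conditions():
        reps = matrix.replicates(cond)
        if len(reps) < 2:
            raise InsufficientDataError(f"condition {cond!r} has fewer than 2 replicates")
        abund = {r: _abundance(matrix.sample_block((cond, r))) for r in reps}
        ids = {r: set(abund[r].dropna().index) for r in reps}
        for i, ra in enumerate(reps):
            for rb in reps[i + 1 :]:
                union = ids[ra] | ids[rb]
                inter = ids[ra] & ids[rb]
                jac = len(inter) / len(union) if union else np.nan
                jac_rows.append((cond, ra, rb, jac))
                shared = sorted(inter)
                if len(shared) >= 2:
                    rho = _stats.spearmanr(
                        abund[ra][shared], abund[rb][shared]
                    ).statistic
                else:
                    rho = np.nan
                rho_rows.append((cond, ra, rb, rho, len(shared)))
        stack = pd.concat(abund, axis=1)
        mean = stack.mean(axis=1)
        sd = stack.std(axis=1, ddof=1)
        cv = (sd / mean * 100.0).where(stack.notna().sum(axis=1) >= 2)
        for prot, v in cv.dropna().items():
            cv_rows.append((prot, cond, float(v)))
    return QCReport(
        jaccard=pd.DataFrame(jac_rows, columns=["condition", "replicate_a", "replicate_b", "jaccard"]),
        spearman=pd.DataFrame(rho_rows, columns=["condition", "replicate_a", "replicate_b", "spearman", "n_shared"]),
        cv=pd.DataFrame(cv_rows, columns=["protein", "condition", "cv_percent"]),
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_trace(matrix: ProfileMatrix, mode: str) -> ProfileMatrix:
    """Normalize intensities within each (condition, replicate) sample.

    ``per_fraction_total`` divides each cell by its fraction-column total
    (all proteins at that time point); ``per_protein_total`` divides each
    cell by the row total of that protein's trace.  Missing stays missing;
    zero denominators leave the cell missing with a warning.
    """
    if mode not in ("per_fraction_total", "per_protein_total"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    out = matrix.data.copy()
    for sample in matrix.samples():
        cond, rep = sample
        block = matrix.sample_block(sample)
        if mode == "per_fraction_total":
            denom = block.sum(axis=0, min_count=1)
            normed = block.div(denom, axis=1)
        else:
            denom = block.sum(axis=1, min_count=1)
            normed = block.div(denom, axis=0)
        n_zero = int((denom.fillna(0.0) == 0).sum())
        if n_zero:
            log.warning("%s/%s: %d zero denominators set to missing", cond, rep, n_zero)
        normed = normed.replace([np.inf, -np.inf], np.nan)
        for f in normed.columns:
            out[(cond, rep, f)] = normed[f]
    return ProfileMatrix(out, matrix.scheme)
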