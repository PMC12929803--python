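"""Synthetic complexome generator.

Plants protein complexes as Gaussian co-elution bumps across SEC fractions,
with replicate-level multiplicative noise, completely-at-random dropout and
per-complex condition fold changes, plus matching complex-database tables,
a proteome FASTA, and molecular-weight reference tables.  Every downstream
stage of the pipeline is testable against the recorded ground truth.

The elution position of a complex is tied to its total mass through a
log-linear SEC calibration (large assemblies elute early), so the
molecular-weight filter of the differential stage has a well-defined truth:
complex members elute at an apparent mass at or above their annotated
monomer mass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .profiles import ProfileMatrix
from .scheme import FractionScheme

# log10(kDa) = MW_INTERCEPT + MW_SLOPE * fraction; spans ~5 MDa at fraction 1
# down to ~10 kDa at fraction 60 for the default 60-fraction scheme.
MW_INTERCEPT = 3.7447
MW_SLOPE = -0.045748


def fraction_to_mw_kda(f: float) -> float:
    """Apparent molecular weight (kDa) at a fraction, default calibration."""
    return 10.0 ** (MW_INTERCEPT + MW_SLOPE * f)


def mw_kda_to_fraction(mw: float) -> float:
    """Fraction at which a species of the given mass (kDa) elutes."""
    return (math.log10(mw) - MW_INTERCEPT) / MW_SLOPE


def _default_differential() -> dict[str, float]:
    # first five planted complexes double in the case condition
    return {f"C{i:03d}": 2.0 for i in range(1, 6)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic complexome.

    Defaults emulate one three-replicate case/control SEC-MS comparison:
    300 proteins, 40 planted complexes of 3-6 subunits, ~10% multiplicative
    intensity noise (CV), 5% missing-at-random dropout and a two-fold
    abundance change planted on five complexes in the case condition.
    """

    n_proteins: int = 300
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (3, 6)
    apex_jitter_sd: float = 0.4
    peak_sigma_range: tuple[float, float] = (1.5, 2.5)
    noise_cv: float = 0.1
    dropout_rate: float = 0.05
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "case")
    differential_complexes: dict[str, float] = field(default_factory=_default_differential)
    monomer_mw_range_kda: tuple[float, float] = (20.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("complex_size_range must satisfy 2 <= lo <= hi")
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if any(fc <= 0 for fc in self.differential_complexes.values()):
            raise ConfigurationError("fold changes must be > 0")
        if self.n_complexes * hi > self.n_proteins:
            raise ConfigurationError(
                f"{self.n_complexes} complexes of up to {hi} members "
                f"exceed {self.n_proteins} proteins"
            )
        known = {f"C{i:03d}" for i in range(1, self.n_complexes + 1)}
        unknown = set(self.differential_complexes) - known
        if unknown:
            raise ConfigurationError(f"differential complexes not planted: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth of one simulated complexome."""

    complexes: dict[str, list[str]]            # complex id -> member accessions
    apex: dict[str, float]                     # protein -> apex fraction
    sigma: dict[str, float]                    # protein -> Gaussian peak width (fractions)
    abundance: dict[str, float]                # protein -> base peak height
    monomer_mw_kda: dict[str, float]           # protein -> annotated monomer mass
    fold_change: dict[str, float]              # complex id -> case/control fold change
    member_complex: dict[str, str]             # protein -> owning complex id
    seed: int = 0

    def truth_pairs(self) -> set[tuple[str, str]]:
        """All within-complex unordered pairs, deduplicated across complexes."""
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            ms = sorted(members)
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    pairs.add((a, b))
        return pairs

    def differential_pairs(self) -> set[tuple[str, str]]:
        """Truth pairs belonging to complexes with a planted fold change != 1."""
        out: set[tuple[str, str]] = set()
        for cid, fc in self.fold_change.items():
            if fc != 1.0:
                ms = sorted(self.complexes[cid])
                for i, a in enumerate(ms):
                    for b in ms[i + 1 :]:
                        out.add((a, b))
        return out


def simulate_complexome(
    config: SimConfig, scheme: FractionScheme | None = None
) -> tuple[ProfileMatrix, SimTruth]:
    """Simulate a complexome as one ProfileMatrix spanning all samples.

    Each complex elutes at the fraction dictated by its total mass under the
    default SEC calibration; members share the complex apex (plus per-protein
    jitter) and the complex peak width, so in the noise-free limit member
    profiles are exactly proportional.  Profiles are Gaussian bumps scaled by
    protein abundance x condition fold change, with log-normal multiplicative
    noise (CV = ``noise_cv``) and missing-at-random dropout.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    scheme = scheme or FractionScheme()
    rng = np.random.default_rng(config.seed)
    n = scheme.n_fractions

    proteins = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    mono_lo, mono_hi = config.monomer_mw_range_kda
    mw = {p: float(rng.uniform(mono_lo, mono_hi)) for p in proteins}

    pool = list(proteins)
    rng.shuffle(pool)
    lo, hi = config.complex_size_range
    complexes: dict[str, list[str]] = {}
    member_complex: dict[str, str] = {}
    cursor = 0
    for i in range(1, config.n_complexes + 1):
        k = int(rng.integers(lo, hi + 1))
        cid = f"C{i:03d}"
        members = pool[cursor : cursor + k]
        cursor += k
        complexes[cid] = members
        for m in members:
            member_complex[m] = cid

    apex: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for cid, members in complexes.items():
        total_mw = sum(mw[m] for m in members)
        base = float(np.clip(mw_kda_to_fraction(total_mw), 3.0, n - 2.0))
        width = float(rng.uniform(*config.peak_sigma_range))
        for m in members:
            apex[m] = float(np.clip(base + rng.normal(0.0, config.apex_jitter_sd), 1.0, n))
            sigma[m] = width
    for p in pool[cursor:]:  # background monomers elute at their own mass
        apex[p] = float(np.clip(mw_kda_to_fraction(mw[p]) + rng.normal(0.0, config.apex_jitter_sd), 1.0, n))
        sigma[p] = float(rng.uniform(*config.peak_sigma_range))

    abundance = {p: float(10.0 ** rng.uniform(6.0, 9.0)) for p in proteins}
    fold_change = {
        cid: float(config.differential_complexes.get(cid, 1.0)) for cid in complexes
    }

    fractions = np.arange(1, n + 1, dtype=float)
    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv**2))
    blocks: dict[tuple[str, str, int], np.ndarray] = {}
    for ci, cond in enumerate(config.conditions):
        clean = np.empty((len(proteins), n))
        for pi, p in enumerate(proteins):
            fc = 1.0
            cid = member_complex.get(p)
            if cid is not None and ci > 0:
                fc = fold_change[cid]
            clean[pi] = (
                abundance[p] * fc
                * np.exp(-0.5 * ((fractions - apex[p]) / sigma[p]) ** 2)
            )
        for rep in range(1, config.n_replicates + 1):
            if config.noise_cv > 0:
                noise = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=clean.shape)
            else:
                noise = 1.0
            values = clean * noise
            if config.dropout_rate > 0:
                mask = rng.random(size=clean.shape) < config.dropout_rate
                values = np.where(mask, np.nan, values)
            for f in range(n):
                blocks[(cond, str(rep), f + 1)] = values[:, f]

    cols = pd.MultiIndex.from_tuples(blocks.keys(), names=["condition", "replicate", "fraction"])
    data = pd.DataFrame(np.column_stack(list(blocks.values())), index=proteins, columns=cols)
    truth = SimTruth(
        complexes=complexes,
        apex=apex,
        sigma=sigma,
        abundance=abundance,
        monomer_mw_kda=mw,
        fold_change=fold_change,
        member_complex=member_complex,
        seed=config.seed,
    )
    return ProfileMatrix(data, scheme), truth


# ---------------------------------------------------------------------------
# companion fixtures: complex tables, FASTA, MW references
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: column layout of each emitted complex-table dialect
DIALECT_COLUMNS = {
    "corum-like": ("complex_id", "complex_name", "subunits_uniprot", ";"),
    "humap-like": ("cluster_id", "members", ","),
    "portal-like": ("complex_ac", "participants", ";"),
}


@dataclass
class SyntheticDatabases:
    """Three complex-table dialects plus a matching proteome FASTA."""

    tables: dict[str, pd.DataFrame]
    fasta: list[tuple[str, str]]          # (accession, sequence)
    decoy_accessions: set[str]
    annotated_mw: pd.DataFrame            # accession, mw_kda
    calibration_standards: pd.DataFrame   # fraction, mw_kda

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for dialect, table in self.tables.items():
            p = outdir / f"complexes_{dialect.replace('-like', '')}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths[dialect] = p
        fasta_path = outdir / "proteome.fasta"
        with open(fasta_path, "w") as fh:
            for acc, seq in self.fasta:
                fh.write(f">sp|{acc}|{acc}_SYNTH synthetic protein {acc}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["fasta"] = fasta_path
        mw_path = outdir / "annotated_mw.tsv"
        self.annotated_mw.to_csv(mw_path, sep="\t", index=False)
        paths["annotated_mw"] = mw_path
        cal_path = outdir / "calibration.tsv"
        self.calibration_standards.to_csv(cal_path, sep="\t", index=False)
        paths["calibration"] = cal_path
        return paths


def simulate_databases(
    truth: SimTruth, decoy_fraction: float = 0.1, seed: int = 0
) -> SyntheticDatabases:
    """Emit three overlapping complex-table dialects and a proteome FASTA.

    Every planted complex appears in at least one table; a ``decoy_fraction``
    share of additional entries references decoy accessions deliberately
    absent from the FASTA, so gold-standard refinement has something to
    remove.  Deterministic given ``seed``.
    """
    if not truth.complexes:
        raise ConfigurationError("truth contains no complexes")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ConfigurationError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_decoy_cplx = int(round(decoy_fraction * len(truth.complexes)))
    decoys: set[str] = set()
    decoy_complexes: dict[str, list[str]] = {}
    for i in range(1, n_decoy_cplx + 1):
        k = int(rng.integers(2, 4))
        members = [f"D{len(decoys) + j + 1:04d}" for j in range(k)]
        decoys.update(members)
        decoy_complexes[f"DC{i:03d}"] = members

    # each real complex lands in each table with p=0.7 (at least one table);
    # a few real complexes additionally carry one decoy member, so member
    # removal (not just whole-complex removal) is exercised.
    dialects = list(DIALECT_COLUMNS)
    membership: dict[str, list[str]] = {d: [] for d in dialects}
    contaminated: dict[str, str] = {}
    for cid in truth.complexes:
        chosen = [d for d in dialects if rng.random() < 0.7]
        if not chosen:
            chosen = [dialects[int(rng.integers(len(dialects)))]]
        for d in chosen:
            membership[d].append(cid)
        if decoy_fraction > 0 and rng.random() < decoy_fraction / 2:
            acc = f"D{len(decoys) + 1:04d}"
            decoys.add(acc)
            contaminated[cid] = acc
    for cid in decoy_complexes:
        d = dialects[int(rng.integers(len(dialects)))]
        membership[d].append(cid)

    def members_of(cid: str) -> list[str]:
        base = list(truth.complexes.get(cid) or decoy_complexes[cid])
        if cid in contaminated:
            base.append(contaminated[cid])
        return base

    tables: dict[str, pd.DataFrame] = {}
    for d in dialects:
        layout = DIALECT_COLUMNS[d]
        sep = layout[-1]
        rows = []
        for cid in membership[d]:
            mem = sep.join(members_of(cid))
            if d == "corum-like":
                rows.append({"complex_id": cid, "complex_name": f"{cid} complex", "subunits_uniprot": mem})
            elif d == "humap-like":
                rows.append({"cluster_id": cid, "members": mem})
            else:
                rows.append({"complex_ac": cid, "participants": mem})
        tables[d] = pd.DataFrame(rows, columns=list(layout[:-1]))

    fasta = []
    for p in sorted(truth.apex):
        length = int(rng.integers(80, 301))
        seq = "".join(rng.choice(_AA, size=length))
        fasta.append((p, seq))

    annotated = pd.DataFrame(
        sorted(truth.monomer_mw_kda.items()), columns=["accession", "mw_kda"]
    )
    std_fracs = np.linspace(5, 55, 6)
    standards = pd.DataFrame(
        {"fraction": std_fracs, "mw_kda": [fraction_to_mw_kda(f) for f in std_fracs]}
    )
    return SyntheticDatabases(
        tables=tables,
        fasta=fasta,
        decoy_accessions=decoys,
        annotated_mw=annotated,
        calibration_standards=standards,
    )


def write_simulation(matrix: ProfileMatrix, truth: SimTruth, outdir) -> dict[str, Path]:
    """Serialize a simulated matrix plus its truth tables and seed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": outdir / "matrix.tsv"}
    matrix.to_tsv(paths["matrix"])
    rows = [
        {"complex_id": cid, "members": ";".join(members), "fold_change": truth.fold_change[cid]}
        for cid, members in truth.complexes.items()
    ]
    paths["truth_complexes"] = outdir / "truth_complexes.tsv"
    pd.DataFrame(rows).to_csv(paths["truth_complexes"], sep="\t", index=False)
    prot_rows = [
        {
            "accession": p,
            "apex_fraction": truth.apex[p],
            "sigma": truth.sigma[p],
            "abundance": truth.abundance[p],
            "monomer_mw_kda": truth.monomer_mw_kda[p],
            "complex_id": truth.member_complex.get(p, ""),
        }
        for p in sorted(truth.apex)
    ]
    paths["truth_proteins"] = outdir / "truth_proteins.tsv"
    pd.DataFrame(prot_rows).to_csv(paths["truth_proteins"], sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": truth.seed, "n_truth_pairs": len(truth.truth_pairs())}, fh, indent=1)
    return paths
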