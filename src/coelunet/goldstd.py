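"""Gold-standard curation: complex tables -> refined, labeled protein pairs.

Complex databases (CORUM-, hu.MAP- and Complex Portal-style TSV dialects)
are parsed into :class:`ComplexRecord` lists, refined against a proteome
FASTA (members absent from the proteome are removed, complexes left with
fewer than two members are dropped), expanded into a deduplicated set of
within-complex pairs, and finally used to label the N(N-1)/2 observable
pairs of a protein matrix as positive / negative / unknown:

* positive - the pair is a within-complex gold-standard pair;
* negative - both proteins occur in the refined gold standard but the
  pair is not positive (the PrInCE-style convention);
* unknown - at least one protein is absent from the gold standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, InsufficientDataError

log = logging.getLogger(__name__)

Pair = tuple[str, str]


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered pair (lexicographic order)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ComplexRecord:
    complex_id: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members or any(not m.strip() for m in self.members):
            raise FormatError(f"complex {self.complex_id}: blank or empty member set")


#: dialect name -> (id column, members column, delimiter)
DIALECTS = {
    "corum-like": ("complex_id", "subunits_uniprot", ";"),
    "humap-like": ("cluster_id", "members", ","),
    "portal-like": ("complex_ac", "participants", ";"),
    "synthetic": ("complex_id", "members", ";"),
}


def parse_complex_table(path, dialect: str) -> list[ComplexRecord]:
    """Parse one complex table in the given dialect.

    Member strings are split on the dialect's delimiter, trimmed and
    deduplicated; rows with an empty member cell are skipped with a warning.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    id_col, mem_col, sep = DIALECTS[dialect]
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_col, mem_col):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r} for dialect {dialect}")
    records: list[ComplexRecord] = []
    for _, row in table.iterrows():
        raw = row[mem_col]
        members = frozenset(
            m.strip() for m in str(raw).split(sep) if m and m.strip()
        ) if pd.notna(raw) else frozenset()
        if not members:
            log.warning("%s: complex %s has no members, skipped", path, row[id_col])
            continue
        records.append(ComplexRecord(str(row[id_col]).strip(), dialect, members))
    return records


def write_complex_table(records: Sequence[ComplexRecord], path, dialect: str = "synthetic") -> None:
    id_col, mem_col, sep = DIALECTS[dialect]
    rows = [
        {id_col: r.complex_id, mem_col: sep.join(sorted(r.members))} for r in records
    ]
    pd.DataFrame(rows, columns=[id_col, mem_col]).to_csv(path, sep="\t", index=False)


def _fasta_accession(record) -> str:
    """Extract the accession from a UniProt-style ``sp|ACC|NAME`` header."""
    ident = record.id
    if "|" in ident:
        parts = ident.split("|")
        if len(parts) < 3 or not parts[1]:
            raise FormatError(f"unparseable FASTA header {ident!r}")
        return parts[1]
    return ident


def strip_isoform(acc: str) -> str:
    """``P12345-2`` -> ``P12345``; plain accessions are returned unchanged."""
    base, dash, suffix = acc.rpartition("-")
    if dash and suffix.isdigit():
        return base
    return acc


def refine_against_proteome(
    records: Iterable[ComplexRecord],
    fasta_path,
    keep_monomeric: bool = False,
    strip_isoforms: bool = True,
) -> list[ComplexRecord]:
    """Drop complex members absent from the proteome FASTA.

    Isoform suffixes are stripped from record members before matching (the
    FASTA is assumed to carry canonical accessions).  Records left with
    fewer than two members are dropped unless ``keep_monomeric``.
    Idempotent: refining an already refined list is a no-op.
    """
    proteome = {_fasta_accession(r) for r in SeqIO.parse(str(fasta_path), "fasta")}
    refined: list[ComplexRecord] = []
    removed: dict[str, int] = {}
    for rec in records:
        kept = frozenset(
            m for m in rec.members
            if (strip_isoform(m) if strip_isoforms else m) in proteome
        )
        n_removed = len(rec.members) - len(kept)
        if n_removed:
            removed[rec.source] = removed.get(rec.source, 0) + n_removed
        if len(kept) >= 2 or (keep_monomeric and kept):
            refined.append(ComplexRecord(rec.complex_id, rec.source, kept))
    for source, n in sorted(removed.items()):
        log.info("refinement removed %d member entries from %s records", n, source)
    return refined


class PairSet(NamedTuple):
    """Within-complex pairs plus flagged monomeric self-pairs."""

    pairs: frozenset[Pair]
    monomeric: frozenset[str]


def expand_to_pairs(*record_sets: Iterable[ComplexRecord]) -> PairSet:
    """Union of all unordered within-complex pairs across sources.

    Single-member records yield monomeric entries, flagged separately and
    excluded from the modeling positive set (a self-pair has no pairwise
    elution features).  Order-invariant and deduplicated.
    """
    pairs: set[Pair] = set()
    monomeric: set[str] = set()
    for records in record_sets:
        for rec in records:
            members = sorted(rec.members)
            if len(members) == 1:
                monomeric.add(members[0])
                continue
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pairs.add((a, b))
    return PairSet(frozenset(pairs), frozenset(monomeric))


@dataclass
class LabelTable:
    """Positive / negative / unknown labels over all pairs of a matrix."""

    proteins: list[str]
    table: pd.DataFrame  # columns: protein_a, protein_b, label

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def pairs_with_label(self, label: str) -> list[Pair]:
        sub = self.table[self.table["label"] == label]
        return list(zip(sub["protein_a"], sub["protein_b"]))

    def label_of(self, pair: Pair) -> str:
        a, b = pair_key(*pair)
        hit = self.table[(self.table["protein_a"] == a) & (self.table["protein_b"] == b)]
        if hit.empty:
            raise KeyError(pair)
        return str(hit["label"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LabelTable":
        table = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
        proteins = sorted(set(table["protein_a"]) | set(table["protein_b"]))
        return cls(proteins, table)


def label_pairs(
    matrix_proteins: Iterable[str],
    positives: Iterable[Pair],
    gold_proteins: Iterable[str] | None = None,
) -> LabelTable:
    """Label all N(N-1)/2 pairs over the matrix proteins.

    ``gold_proteins`` is the refined gold-standard universe; if omitted it is
    inferred as the proteins occurring in any positive pair.
    """
    proteins = sorted(set(matrix_proteins))
    if not proteins:
        raise InsufficientDataError("matrix protein set is empty")
    pos = {pair_key(*p) for p in positives}
    if not pos:
        log.warning("empty positive set: labels will be unknown/negative only")
    if gold_proteins is None:
        gold = {p for pair in pos for p in pair}
    else:
        gold = set(gold_proteins)

    arr = np.array(proteins)
    ia, ib = np.triu_indices(len(proteins), k=1)
    a, b = arr[ia], arr[ib]
    in_gold = np.isin(arr, sorted(gold))
    both_gold = in_gold[ia] & in_gold[ib]
    is_pos = np.fromiter(
        ((x, y) in pos for x, y in zip(a, b)), dtype=bool, count=len(a)
    )
    label = np.where(is_pos, "positive", np.where(both_gold, "negative", "unknown"))
    table = pd.DataFrame({"protein_a": a, "protein_b": b, "label": label})
    return LabelTable(proteins, table)
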