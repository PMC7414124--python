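"""Alignment treatments: SR4 recoding, chi-square site pruning, concatenation.

The compositional-heterogeneity statistic used for pruning is the
classical contingency chi-square on the taxon x character-state count
table of the alignment (gaps ``-`` and unknowns ``X`` excluded from the
counts, expected values from row/column marginals, cells with zero
expectation contributing zero). Pruning removes columns greedily: at
each step the column whose removal most decreases the total chi-square
goes first, with the statistic recomputed after every removal and ties
broken toward the leftmost column; a one-shot ranking variant is
available. This targets exactly the sites whose composition differs
most between taxa — the sites that drive long-branch artefacts in trees
of compositionally divergent lineages.

SR4 recoding collapses the 20 amino acids into four groups
(AGNPST / CHWY / DEKQR / FILMV -> A/C/G/T), a standard reduction that
dampens compositional bias while keeping most of the phylogenetic
signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Alignment",
    "SR4_SCHEME",
    "sr4_recode",
    "recode",
    "total_chi2",
    "prune_heterogeneous",
    "SiteScoreTable",
    "concatenate",
    "PartitionRecord",
    "write_partitions",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED = frozenset(AA20) | {"-", "X"}

#: the four-state reduction map; gap and X pass through untouched
SR4_SCHEME: dict[str, str] = {}
for _grp, _to in (("AGNPST", "A"), ("CHWY", "C"), ("DEKQR", "G"), ("FILMV", "T")):
    for _aa in _grp:
        SR4_SCHEME[_aa] = _to


@dataclass(frozen=True)
class Alignment:
    """An aligned protein matrix over the 20-letter alphabet plus '-' and 'X'."""

    labels: tuple
    sequences: tuple

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if not self.labels:
            raise ValueError("empty alignment")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for ri, seq in enumerate(self.sequences):
            for ci, ch in enumerate(seq):
                if ch not in ALLOWED:
                    raise ValueError(
                        f"invalid residue {ch!r} at row {self.labels[ri]!r} "
                        f"column {ci + 1}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.sequences)

    def take_columns(self, keep: Sequence[int]) -> "Alignment":
        return Alignment(self.labels,
                         tuple("".join(seq[j] for j in keep)
                               for seq in self.sequences))

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO
        labels, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not labels:
            raise ValueError(f"no sequences in {path}")
        return cls(tuple(labels), tuple(seqs))

    def to_fasta(self, path=None, width: int = 80) -> str:
        chunks = []
        for lab, seq in zip(self.labels, self.sequences):
            chunks.append(f">{lab}")
            for i in range(0, len(seq), width):
                chunks.append(seq[i:i + width])
        out = "\n".join(chunks) + "\n"
        if path is not None:
            Path(path).write_text(out)
        return out


def recode(aln: Alignment, scheme: Mapping[str, str]) -> Alignment:
    """Apply a residue recoding scheme; '-' and 'X' always pass through."""
    table = dict(scheme)
    table.setdefault("-", "-")
    table.setdefault("X", "X")
    try:
        seqs = tuple("".join(table[ch] for ch in seq) for seq in aln.sequences)
    except KeyError as exc:
        raise ValueError(f"scheme lacks a mapping for residue {exc}") from exc
    return Alignment(aln.labels, seqs)


def sr4_recode(aln: Alignment) -> Alignment:
    """Recode amino acids into the four SR4 states {A,C,G,T}."""
    return recode(aln, SR4_SCHEME)


# ---------------------------------------------------------------------------
# chi-square heterogeneity
# ---------------------------------------------------------------------------

def _state_indices(aln: Alignment):
    """Per-cell state index matrix (-1 for '-' and 'X') plus the state list."""
    states = sorted({ch for seq in aln.sequences for ch in seq} - {"-", "X"})
    lut = np.full(128, -1, dtype=np.int64)
    for i, s in enumerate(states):
        lut[ord(s)] = i
    mat = np.array([[lut[ord(ch)] for ch in seq] for seq in aln.sequences],
                   dtype=np.int64)
    return mat, states


def _counts_from_indices(mat: np.ndarray, n_states: int) -> np.ndarray:
    n_taxa = mat.shape[0]
    counts = np.zeros((n_taxa, n_states), dtype=np.float64)
    for t in range(n_taxa):
        row = mat[t]
        row = row[row >= 0]
        if row.size:
            counts[t] = np.bincount(row, minlength=n_states)
    return counts


def _chi2_stat(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        raise ValueError("all-gap alignment: no countable residues")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def total_chi2(aln: Alignment) -> float:
    """Total contingency chi-square of the taxon x state count table."""
    if aln.n_taxa < 2:
        raise ValueError("need >=2 taxa")
    mat, states = _state_indices(aln)
    if not states:
        raise ValueError("all-gap alignment: no countable residues")
    return _chi2_stat(_counts_from_indices(mat, len(states)))


def _chi2_batch(tables: np.ndarray) -> np.ndarray:
    """Chi-square statistic for a stack of count tables, vectorized."""
    n = tables.sum(axis=(1, 2), keepdims=True)
    rows = tables.sum(axis=2, keepdims=True)
    cols = tables.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / n
        terms = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=(1, 2))


@dataclass(frozen=True)
class SiteScoreTable:
    """Removal order and scores of the pruned columns (1-based indices)."""

    removed_columns: tuple     # original column numbers in removal order
    chi2_before: tuple         # total chi2 before each removal
    chi2_after: tuple          # total chi2 after each removal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "removal_order": range(1, len(self.removed_columns) + 1),
            "column": self.removed_columns,
            "chi2_before": self.chi2_before,
            "chi2_after": self.chi2_after,
        })


def prune_heterogeneous(aln: Alignment, fraction: float,
                        recompute: bool = True):
    """Remove the floor(fraction * n_sites) most heterogeneous columns.

    Greedy stepwise removal (default): at each step drop the column
    whose removal most decreases the total chi-square, recomputing after
    every removal; ties go to the leftmost column. ``recompute=False``
    ranks columns once by their removal effect on the full alignment.

    Returns ``(pruned_alignment, SiteScoreTable)``; reported column
    indices are 1-based.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_remove = math.floor(fraction * aln.n_sites)
    if n_remove < 1:
        raise ValueError(
            f"fraction {fraction} removes no columns from {aln.n_sites} sites")
    if aln.n_taxa < 2:
        raise ValueError("need >=2 taxa")

    mat, states = _state_indices(aln)
    if not states:
        raise ValueError("all-gap alignment: no countable residues")
    n_states = len(states)
    n_taxa, n_sites = mat.shape
    # per-column count tables C[j, taxon, state]
    col_counts = np.zeros((n_sites, n_taxa, n_states), dtype=np.float64)
    tx = np.arange(n_taxa)
    for j in range(n_sites):
        col = mat[:, j]
        ok = col >= 0
        col_counts[j, tx[ok], col[ok]] = 1.0
    total = col_counts.sum(axis=0)

    remaining = np.ones(n_sites, dtype=bool)
    removed: list[int] = []
    before: list[float] = []
    after: list[float] = []

    if recompute:
        for _step in range(n_remove):
            current = _chi2_stat(total)
            idx = np.flatnonzero(remaining)
            cand = _chi2_batch(total[None] - col_counts[idx])
            j = idx[int(np.argmin(cand))]  # argmin is leftmost on ties
            removed.append(int(j) + 1)
            before.append(current)
            after.append(float(cand[int(np.argmin(cand))]))
            total -= col_counts[j]
            remaining[j] = False
    else:
        current = _chi2_stat(total)
        cand = _chi2_batch(total[None] - col_counts)
        order = np.argsort(cand, kind="stable")  # stable => leftmost on ties
        for j in order[:n_remove]:
            removed.append(int(j) + 1)
            before.append(current)
            after.append(float(cand[j]))
            remaining[j] = False

    keep = [j for j in range(n_sites) if remaining[j]]
    return aln.take_columns(keep), SiteScoreTable(tuple(removed),
                                                  tuple(before), tuple(after))


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionRecord:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


def concatenate(alns, taxa_superset: Sequence[str] | None = None):
    """Concatenate marker alignments into a supermatrix with partitions.

    ``alns`` is a mapping name -> Alignment (or a plain sequence, which
    gets names ``p1, p2, ...``). Taxa missing from a marker get a
    gap-only segment. Returns ``(supermatrix, [PartitionRecord, ...])``.
    """
    if isinstance(alns, Mapping):
        items = list(alns.items())
    else:
        items = [(f"p{i + 1}", a) for i, a in enumerate(alns)]
    if not items:
        raise ValueError("no alignments to concatenate")
    if taxa_superset is None:
        taxa: list[str] = []
        seen = set()
        for _name, a in items:
            for lab in a.labels:
                if lab not in seen:
                    taxa.append(lab)
                    seen.add(lab)
        taxa = sorted(taxa)
    else:
        taxa = list(taxa_superset)
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate labels in taxa_superset")
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for name, a in items:
        idx = {lab: i for i, lab in enumerate(a.labels)}
        width = a.n_sites
        for t in taxa:
            rows[t].append(a.sequences[idx[t]] if t in idx else "-" * width)
        partitions.append(PartitionRecord(name, pos, pos + width - 1))
        pos += width
    return (Alignment(tuple(taxa), tuple("".join(rows[t]) for t in taxa)),
            partitions)


def write_partitions(partitions: Sequence[PartitionRecord], path=None) -> str:
    """RAxML-style partition text: ``name = start-end`` per line."""
    out = "".join(f"{p.name} = {p.start}-{p.end}\n" for p in partitions)
    if path is not None:
        Path(path).write_text(out)
    return out
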