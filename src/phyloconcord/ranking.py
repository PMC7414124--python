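"""Bootstrap-aware marker-congruence scoring ("split counting") and ranking.

A *split* is a taxon that fails to group with its expected taxonomic
clade in a given (bootstrap) tree. Markers whose bootstrap samples show
few splits are topologically congruent with the accepted taxonomy and
are preferred when assembling concatenation supermatrices; markers with
many splits are candidates for horizontal transfer or phylogenetic
artefacts.

Scoring conventions (all configurable, all deterministic):

* splits are counted over bootstrap replicates only; the ML tree is used
  for leaf-set validation and reported separately,
* a clade counts as split for a marker when it is split in a strict
  majority (>50%) of that marker's bootstrap trees,
* the taxon-level attribution uses the clade's largest monophyletic
  component; ties on component size are broken toward the component
  containing the lexicographically smallest taxon,
* taxa absent from the taxon map are pruned (made transparent) before
  component analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .trees import (
    MarkerSet,
    TaxonMap,
    ensure_rooted,
    is_clan,
    is_rooted,
    leaf_labels,
    node_leaf_sets,
)

__all__ = [
    "monophyletic_components",
    "count_splits",
    "SplitCount",
    "exclude_domain_violations",
    "MarkerScore",
    "RankReport",
    "score_and_rank_markers",
    "select_fraction",
]


def _component_nodes(tree: dendropy.Tree, taxa: frozenset,
                     restrict: frozenset | None = None,
                     leaf_sets: dict | None = None) -> list:
    """Maximal nodes whose (restricted) leaf sets are nonempty subsets of taxa.

    ``restrict``, when given, is the universe of taxa considered present:
    leaves outside it are transparent, which is equivalent to pruning
    them from the tree before the decomposition.
    """
    if leaf_sets is None:
        leaf_sets = node_leaf_sets(tree)
    universe = leaf_sets[tree.seed_node]
    if restrict is not None:
        universe = universe & restrict
    missing = taxa - universe
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")

    def rel(node) -> frozenset:
        s = leaf_sets[node]
        return s & restrict if restrict is not None else s

    def pure(node) -> bool:
        r = rel(node)
        return bool(r) and r <= taxa

    nodes = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if pure(node) and (parent is None or not pure(parent)):
            nodes.append(node)
    nodes.sort(key=lambda n: min(rel(n)))
    return nodes


def monophyletic_components(tree: dendropy.Tree, taxa: Iterable[str],
                            restrict: Iterable[str] | None = None) -> list[frozenset]:
    """Decompose ``taxa`` into the maximal clades of the rooted tree.

    Returns disjoint leaf sets that partition ``taxa``; a single
    component means the taxa are monophyletic in the rooted tree.
    Components are sorted by their lexicographically smallest member.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    restrict_fs = frozenset(restrict) if restrict is not None else None
    leaf_sets = node_leaf_sets(tree)
    nodes = _component_nodes(tree, taxa, restrict_fs, leaf_sets)
    out = []
    for n in nodes:
        s = leaf_sets[n]
        if restrict_fs is not None:
            s = s & restrict_fs
        out.append(frozenset(s))
    return out


def _largest_component(components: Sequence[frozenset]) -> frozenset:
    """Largest component; size ties broken toward the one holding the
    lexicographically smallest taxon among the tied components."""
    return sorted(components, key=lambda c: (-len(c), min(c)))[0]


@dataclass
class SplitCount:
    """Split bookkeeping for one (rooted) tree under one taxon map."""

    clade_components: dict  # clade -> list of components (frozensets)
    clade_split: dict       # clade -> bool (components > 1)
    taxon_split: dict       # taxon -> 0/1 (not in the clade's largest component)
    unmapped: frozenset     # leaves present but absent from the taxon map

    @property
    def total_taxon_splits(self) -> int:
        return sum(self.taxon_split.values())

    @property
    def n_split_clades(self) -> int:
        return sum(self.clade_split.values())


def count_splits(tree: dendropy.Tree, taxon_map: TaxonMap) -> SplitCount:
    """Count, for one rooted tree, which taxa fail to group with their clade.

    Clades with a single member present are never split; unmapped taxa
    are transparent for the decomposition and reported in ``unmapped``.
    """
    if not is_rooted(tree):
        raise ValueError("count_splits requires a rooted tree "
                         "(root the tree first, e.g. via ensure_rooted)")
    leaves = leaf_labels(tree)
    mapped = frozenset(t for t in leaves if t in taxon_map)
    if not mapped:
        raise ValueError("no mapped taxa present in tree")
    leaf_sets = node_leaf_sets(tree)
    clade_components: dict = {}
    clade_split: dict = {}
    taxon_split: dict = {}
    for clade, members in sorted(taxon_map.clades().items()):
        present = members & mapped
        if not present:
            continue
        comps = [frozenset(leaf_sets[n] & mapped)
                 for n in _component_nodes(tree, present, mapped, leaf_sets)]
        clade_components[clade] = comps
        clade_split[clade] = len(comps) > 1
        if len(present) == 1:
            taxon_split[next(iter(present))] = 0
            continue
        keep = _largest_component(comps)
        for t in present:
            taxon_split[t] = 0 if t in keep else 1
    return SplitCount(clade_components, clade_split, taxon_split,
                      frozenset(leaves - mapped))


def exclude_domain_violations(markers: MarkerSet, taxon_map: TaxonMap):
    """Drop markers whose archaeal+eukaryotic taxa do not form a clan.

    The test runs on each marker's unrooted ML tree: a marker is
    excluded iff the union of its archaeal and eukaryotic taxa cannot be
    separated from the bacterial taxa by cutting one edge (i.e. some
    archaeal/eukaryotic sequence nests within Bacteria). Markers with
    fewer than 3 leaves are skipped with a warning.

    Returns ``(retained_ids, report)`` where ``report`` is a DataFrame
    with one row per marker (status retained/excluded/skipped and the
    offending taxa for exclusions).
    """
    rows = []
    retained = []
    for mid, (ml, _boots) in markers:
        leaves = leaf_labels(ml)
        if len(leaves) < 3:
            warnings.warn(f"marker {mid!r} has <3 leaves; skipped", UserWarning,
                          stacklevel=2)
            rows.append({"marker": mid, "status": "skipped", "offending_taxa": ""})
            continue
        unlabeled = [t for t in leaves
                     if t in taxon_map.clade_of and t not in taxon_map.domain_of]
        if unlabeled:
            raise ValueError(
                f"marker {mid!r}: mapped taxa without domain labels: "
                f"{sorted(unlabeled)[:5]}")
        ae = frozenset(t for t in leaves
                       if taxon_map.domain_of.get(t) in ("archaea", "eukaryote"))
        if is_clan(ml, ae):
            retained.append(mid)
            rows.append({"marker": mid, "status": "retained", "offending_taxa": ""})
        else:
            bac = sorted(t for t in leaves
                         if taxon_map.domain_of.get(t) == "bacteria")
            rooted = ensure_rooted(ml, outgroup=bac[:1])
            comps = monophyletic_components(rooted, ae)
            offenders = sorted(set().union(*(c for c in comps
                                             if c != _largest_component(comps))))
            rows.append({"marker": mid, "status": "excluded",
                         "offending_taxa": ",".join(offenders)})
    report = pd.DataFrame(rows, columns=["marker", "status", "offending_taxa"])
    return retained, report


@dataclass(frozen=True)
class MarkerScore:
    marker_id: str
    percent_split_clades: float  # % of present clades split in >majority of boots
    normalized_splits: float     # mean split taxa per bootstrap tree / n_taxa
    total_taxon_splits: int      # raw split count summed over all bootstrap trees
    n_taxa: int
    n_clades_present: int
    k_boots: int
    rank: int = 0


@dataclass
class RankReport:
    scores: list = field(default_factory=list)
    majority: float = 0.5

    def __iter__(self):
        return iter(self.scores)

    def __len__(self):
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.scores])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_and_rank_markers(markers: MarkerSet, taxon_map: TaxonMap,
                           majority: float = 0.5,
                           outgroup: Iterable[str] | None = None) -> RankReport:
    """Score every marker over its bootstrap sample and rank ascending.

    Per marker, ``count_splits`` runs on each of the K bootstrap trees
    (rooted via the default policy). ``percent_split_clades`` counts
    clades split in more than ``majority`` of the K replicates;
    ``normalized_splits`` is the grand total of per-taxon split
    indicators divided by K and by the number of mapped taxa. Ranking is
    ascending lexicographically by (percent_split_clades,
    normalized_splits, marker id); rank 1 is the most congruent marker.
    """
    if not 0 <= majority < 1:
        raise ValueError("majority must be in [0, 1)")
    scores = []
    for mid, (ml, boots) in markers:
        if not boots:
            raise ValueError(f"marker {mid!r}: K=0")
        n_taxa = len([t for t in leaf_labels(ml) if t in taxon_map])
        if n_taxa == 0:
            raise ValueError(f"marker {mid!r}: no mapped taxa")
        clade_split_counts: dict = {}
        total = 0
        k = len(boots)
        for bt in boots:
            sc = count_splits(ensure_rooted(bt, outgroup=outgroup), taxon_map)
            total += sc.total_taxon_splits
            for clade, split in sc.clade_split.items():
                clade_split_counts[clade] = clade_split_counts.get(clade, 0) + split
        n_clades = len(clade_split_counts)
        n_split = sum(1 for c, v in clade_split_counts.items()
                      if v > majority * k)
        scores.append(MarkerScore(
            marker_id=mid,
            percent_split_clades=100.0 * n_split / n_clades,
            normalized_splits=total / k / n_taxa,
            total_taxon_splits=total,
            n_taxa=n_taxa,
            n_clades_present=n_clades,
            k_boots=k,
        ))
    scores.sort(key=lambda s: (s.percent_split_clades, s.normalized_splits,
                               s.marker_id))
    ranked = [MarkerScore(**{**vars(s), "rank": i + 1})
              for i, s in enumerate(scores)]
    return RankReport(ranked, majority)


def select_fraction(report: RankReport, fraction: float,
                    end: str = "top") -> list[str]:
    """Pick the ceil(fraction*N) best- or worst-ranked marker ids.

    ``end="top"`` returns the most congruent markers (lowest ranks),
    ``end="bottom"`` the least congruent; both are returned in ascending
    rank order.
    """
    if not report.scores:
        raise ValueError("empty rank report")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if end not in ("top", "bottom"):
        raise ValueError("end must be 'top' or 'bottom'")
    n = math.ceil(fraction * len(report.scores))
    ordered = sorted(report.scores, key=lambda s: s.rank)
    chosen = ordered[:n] if end == "top" else ordered[-n:]
    return [s.marker_id for s in chosen]
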