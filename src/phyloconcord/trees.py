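"""Newick I/O, taxon maps, rooting and bipartition primitives.

All downstream scoring modules work on :class:`dendropy.Tree` objects with
string leaf labels. This module is the only place that touches Newick
syntax; it also provides the small set of exact topological primitives
(leaf sets, bipartitions, clan tests) that the scoring code and its
brute-force test oracles are built from.

Trees are treated as *rooted* whenever the seed node has exactly two
children; trees read from typical ML output (basal trifurcation) are
unrooted and must be rooted via :func:`root_tree` / :func:`ensure_rooted`
before clade-based scoring.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "TaxonMap",
    "MarkerSet",
    "parse_newick",
    "read_newick",
    "write_newick",
    "read_taxon_map",
    "leaf_labels",
    "is_rooted",
    "node_leaf_sets",
    "bipartitions",
    "is_clan",
    "root_tree",
    "ensure_rooted",
]

DOMAINS = ("archaea", "bacteria", "eukaryote")


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """A parsed tree violates a structural invariant (e.g. duplicate leaves)."""


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _validate_tree(tree: dendropy.Tree, source: str = "<tree>") -> dendropy.Tree:
    labels = [lf.taxon.label if lf.taxon is not None else None
              for lf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise TreeValidationError(f"{source}: tree contains unlabeled leaves")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeValidationError(f"{source}: duplicate leaf label {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeValidationError(
                f"{source}: negative branch length {edge.length}")
    return tree


def _parse_statements(text: str, source: str = "<string>") -> list[dendropy.Tree]:
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        from dendropy.dataio.newickreader import NewickReader
        if isinstance(exc, NewickReader.NewickReaderDuplicateTaxonError):
            raise TreeValidationError(f"{source}: duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"{source}: {exc}") from exc
    trees = [_validate_tree(t, source) for t in tree_list]
    if not trees:
        raise NewickParseError(f"{source}: no Newick statement found")
    return trees


def parse_newick(text: str):
    """Parse one or more semicolon-terminated Newick statements.

    Returns a single tree when the input holds exactly one statement,
    otherwise a list. Internal node labels (including IQ-TREE style
    ``"aLRT/UFboot"`` dual supports) are kept as opaque node labels and
    never influence topology operations.
    """
    trees = _parse_statements(text)
    return trees[0] if len(trees) == 1 else trees


def read_newick(path):
    """Read a Newick file; one tree per semicolon-terminated statement."""
    path = Path(path)
    return parse_newick(path.read_text())


def read_newick_list(path) -> list[dendropy.Tree]:
    """Like :func:`read_newick` but always returns a list (bootstrap files)."""
    path = Path(path)
    return _parse_statements(path.read_text(), str(path))


def write_newick(trees, path=None) -> str:
    """Serialize a tree (or list of trees) to Newick; optionally write a file."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    out = "".join(
        t.as_string(schema="newick", suppress_rooting=True,
                    unquoted_underscores=True)
        for t in trees
    )
    if path is not None:
        Path(path).write_text(out)
    return out


# ---------------------------------------------------------------------------
# Taxon map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonMap:
    """taxon id -> clade label, with optional domain labels and outgroup flags.

    The clade labels are the taxonomic units whose monophyly is scored
    (order/class/phylum-level bins); the optional domain column supports
    the archaea/eukaryote-vs-bacteria exclusion screen.
    """

    clade_of: Mapping[str, str]
    domain_of: Mapping[str, str] = field(default_factory=dict)
    outgroup: frozenset = frozenset()

    def __post_init__(self):
        for taxon, clade in self.clade_of.items():
            if not clade:
                raise ValueError(f"empty clade label for taxon {taxon!r}")
        for taxon, dom in self.domain_of.items():
            if dom not in DOMAINS:
                raise ValueError(
                    f"domain for {taxon!r} must be one of {DOMAINS}, got {dom!r}")

    def clades(self) -> dict[str, frozenset]:
        """clade label -> frozenset of member taxa."""
        out: dict[str, set] = {}
        for taxon, clade in self.clade_of.items():
            out.setdefault(clade, set()).add(taxon)
        return {c: frozenset(m) for c, m in out.items()}

    def members(self, clade: str) -> frozenset:
        return frozenset(t for t, c in self.clade_of.items() if c == clade)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.clade_of

    def __len__(self) -> int:
        return len(self.clade_of)


def read_taxon_map(path) -> TaxonMap:
    """Read a TSV taxon map: taxon, clade_label[, domain[, outgroup]].

    Identical repeated rows are deduplicated; conflicting rows are an error.
    Lines starting with ``#`` and blank lines are skipped.
    """
    clade_of: dict[str, str] = {}
    domain_of: dict[str, str] = {}
    outgroup: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"taxon map row needs >=2 columns: {row!r}")
            taxon, clade = row[0].strip(), row[1].strip()
            if not clade:
                raise ValueError(f"empty clade label for taxon {taxon!r}")
            if taxon in clade_of and clade_of[taxon] != clade:
                raise ValueError(
                    f"conflicting clade labels for taxon {taxon!r}: "
                    f"{clade_of[taxon]!r} vs {clade!r}")
            clade_of[taxon] = clade
            if len(row) >= 3 and row[2].strip():
                dom = row[2].strip().lower()
                if taxon in domain_of and domain_of[taxon] != dom:
                    raise ValueError(f"conflicting domains for taxon {taxon!r}")
                domain_of[taxon] = dom
            if len(row) >= 4 and row[3].strip().lower() in ("1", "true", "yes"):
                outgroup.add(taxon)
    return TaxonMap(clade_of, domain_of, frozenset(outgroup))


def write_taxon_map(tmap: TaxonMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for taxon in sorted(tmap.clade_of):
            row = [taxon, tmap.clade_of[taxon]]
            if tmap.domain_of or tmap.outgroup:
                row.append(tmap.domain_of.get(taxon, ""))
                row.append("1" if taxon in tmap.outgroup else "")
            w.writerow(row)


# ---------------------------------------------------------------------------
# Topological primitives
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def is_rooted(tree: dendropy.Tree) -> bool:
    """A tree is treated as rooted iff its seed node has exactly two children."""
    return len(tree.seed_node.child_nodes()) == 2


def node_leaf_sets(tree: dendropy.Tree) -> dict:
    """node -> frozenset of leaf labels below it, for every node (postorder)."""
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset((node.taxon.label,))
        else:
            acc: set = set()
            for ch in node.child_nodes():
                acc |= sets[ch]
            sets[node] = frozenset(acc)
    return sets


def bipartitions(tree: dendropy.Tree) -> set:
    """The leaf-set bipartitions of the tree, one per internal edge.

    Each bipartition is represented canonically as the side *not*
    containing the lexicographically smallest leaf, as a frozenset.
    The root's own edge contributes nothing; for a rooted (two-child
    seed) tree the two seed edges induce the same bipartition and are
    deduplicated.
    """
    leaves = leaf_labels(tree)
    if len(leaves) < 3:
        raise TreeValidationError("bipartitions need >=3 leaves")
    ref = min(leaves)
    sets = node_leaf_sets(tree)
    out: set = set()
    for node, side in sets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        canon = frozenset(leaves - side) if ref in side else side
        if canon and canon != leaves:
            out.add(canon)
    return out


def is_clan(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff ``taxa`` can be separated from the rest by cutting one edge.

    This is the unrooted notion of monophyly; singletons, the empty set
    and (co-)complete sets are trivially clans.
    """
    taxa = frozenset(taxa)
    leaves = leaf_labels(tree)
    missing = taxa - leaves
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) <= 1 or len(leaves - taxa) <= 1:
        return True
    ref = min(leaves)
    canon = frozenset(leaves - taxa) if ref in taxa else taxa
    return canon in bipartitions(tree)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=tree.as_string(schema="newick", suppress_rooting=True),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def _has_any_lengths(tree: dendropy.Tree) -> bool:
    return any(e.length is not None
               for e in tree.preorder_edge_iter()
               if e.head_node is not tree.seed_node)


def _midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    t = _clone(tree)
    if not _has_any_lengths(t):
        raise TreeValidationError(
            "midpoint rooting requires branch lengths (tree is fully lengthless)")
    for e in t.preorder_edge_iter():
        if e.length is None:
            e.length = 0.0
    t.reroot_at_midpoint(update_bipartitions=False)
    _force_bifurcating_root(t)
    t.is_rooted = True
    return t


def _force_bifurcating_root(tree: dendropy.Tree) -> None:
    """If the midpoint landed exactly on a node (>2 root children), group
    all but the first child under a zero-length internal node."""
    seed = tree.seed_node
    children = seed.child_nodes()
    if len(children) <= 2:
        return
    grouped = dendropy.Node()
    for ch in children[1:]:
        seed.remove_child(ch)
        grouped.add_child(ch)
    seed.add_child(grouped)
    grouped.edge.length = 0.0


def _root_on_edge_above(tree: dendropy.Tree, node) -> dendropy.Tree:
    edge = node.edge
    if edge.length is not None:
        length1 = length2 = edge.length / 2.0
    else:
        length1 = length2 = None
    tree.reroot_at_edge(edge, length1=length1, length2=length2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def root_tree(tree: dendropy.Tree, outgroup: Iterable[str] | None = None,
              midpoint: bool = False) -> dendropy.Tree:
    """Return a rooted copy of ``tree``.

    Outgroup mode roots on the edge separating the outgroup clan; if the
    outgroup taxa do not form a clan the function falls back to midpoint
    rooting and emits a warning. Midpoint mode requires at least one
    branch length; missing lengths are treated as zero.
    """
    if outgroup is not None:
        og = frozenset(outgroup)
        if not og:
            raise ValueError("empty outgroup set")
        if not is_clan(tree, og):
            warnings.warn(
                f"outgroup {sorted(og)} is not a clan; falling back to "
                "midpoint rooting", UserWarning, stacklevel=2)
            return _midpoint_root(tree)
        t = _clone(tree)
        sets = node_leaf_sets(t)
        leaves = leaf_labels(t)
        target = None
        for node, side in sets.items():
            if node is t.seed_node:
                continue
            if side == og:
                target = node
                break
            if side == leaves - og:
                target = node  # root on the same edge, seen from the other end
                break
        if target is None:  # og is all leaves: nothing to separate
            raise ValueError("outgroup covers the entire leaf set")
        return _root_on_edge_above(t, target)
    if midpoint:
        return _midpoint_root(tree)
    raise ValueError("specify an outgroup or midpoint=True")


def ensure_rooted(tree: dendropy.Tree,
                  outgroup: Iterable[str] | None = None) -> dendropy.Tree:
    """Deterministic default rooting policy for the scoring modules.

    Already-rooted trees (two-child seed node) are returned unchanged.
    Otherwise: root on the configured outgroup if given; else midpoint if
    any branch length is present; else root on the first leaf's pendant
    edge (first in parse order) so the result is still deterministic.
    """
    if is_rooted(tree):
        return tree
    if outgroup:
        return root_tree(tree, outgroup=outgroup)
    if _has_any_lengths(tree):
        return _midpoint_root(tree)
    t = _clone(tree)
    first_leaf = next(t.leaf_node_iter())
    return _root_on_edge_above(t, first_leaf)


# ---------------------------------------------------------------------------
# Marker sets
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    """marker id -> (ML tree, list of bootstrap trees), shared leaf namespace.

    Every bootstrap tree must carry exactly the ML tree's leaf set; the
    bootstrap sample size K may differ between markers but must be >=1.
    """

    markers: dict

    def __post_init__(self):
        for mid, (ml, boots) in self.markers.items():
            if not boots:
                raise ValueError(f"marker {mid!r}: needs >=1 bootstrap tree")
            ml_leaves = leaf_labels(ml)
            for i, bt in enumerate(boots):
                if leaf_labels(bt) != ml_leaves:
                    raise ValueError(
                        f"marker {mid!r}: bootstrap tree {i} leaf set differs "
                        "from ML tree")

    def __iter__(self):
        return iter(self.markers.items())

    def __len__(self):
        return len(self.markers)

    def ids(self) -> list[str]:
        return list(self.markers)

    def ml_tree(self, marker_id: str) -> dendropy.Tree:
        return self.markers[marker_id][0]

    def bootstrap_trees(self, marker_id: str) -> list[dendropy.Tree]:
        return self.markers[marker_id][1]

    @classmethod
    def from_dirs(cls, trees_dir, boots_dir,
                  tree_suffixes=(".treefile", ".nwk", ".tree"),
                  boot_suffixes=(".ufboot", ".boottrees", ".trees")) -> "MarkerSet":
        """Pair ``<id>.treefile``-style ML trees with ``<id>.ufboot`` files."""
        trees_dir, boots_dir = Path(trees_dir), Path(boots_dir)
        markers: dict = {}
        for p in sorted(trees_dir.iterdir()):
            if p.suffix not in tree_suffixes:
                continue
            mid = p.stem
            boot_path = None
            for suf in boot_suffixes:
                cand = boots_dir / (mid + suf)
                if cand.exists():
                    boot_path = cand
                    break
            if boot_path is None:
                raise FileNotFoundError(
                    f"no bootstrap file for marker {mid!r} in {boots_dir}")
            ml = read_newick(p)
            if isinstance(ml, list):
                raise ValueError(f"{p}: expected a single ML tree")
            markers[mid] = (ml, read_newick_list(boot_path))
        if not markers:
            raise ValueError(f"no marker trees found in {trees_dir}")
        return cls(markers)

    def write(self, trees_dir, boots_dir) -> None:
        trees_dir, boots_dir = Path(trees_dir), Path(boots_dir)
        trees_dir.mkdir(parents=True, exist_ok=True)
        boots_dir.mkdir(parents=True, exist_ok=True)
        for mid, (ml, boots) in self.markers.items():
            write_newick(ml, trees_dir / f"{mid}.treefile")
            write_newick(boots, boots_dir / f"{mid}.ufboot")
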