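"""Synthetic benchmark generators with planted, recoverable signal.

Every downstream stage of the pipeline has a generator here that emits
inputs with the statistical structure the stage assumes, together with
a truth record of what was planted:

* a labeled species tree whose clade labels are monophyletic by
  construction (random sequential-join topologies per clade and for the
  backbone, exponential branch lengths — a Yule-style shape),
* gene trees in which a controlled fraction of markers carries one
  donor->recipient transfer, plus bootstrap replicates perturbed by
  random NNI moves as a cheap stand-in for bootstrap uncertainty,
* alignments with a planted fraction of compositionally biased columns,
* read-mapping tables whose genomes follow lognormal latent abundances
  with planted proportional partner/focal groups.

All generators are pure functions of their seed and parameters: the
same call produces byte-identical Newick/FASTA/TSV output.

The default transfer model regrafts the *whole* recipient clade onto an
edge strictly inside the donor clan: the gene's recipient copies then
show the donor as closest sister (the transfer route), and the donor
clade itself becomes paraphyletic, which is what the split-counting
ranking detects. Moving only some recipient leaves (``n_moved``) is
also supported and splits the recipient clade instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .alignments import AA20, Alignment
from .trees import (
    MarkerSet,
    TaxonMap,
    leaf_labels,
    node_leaf_sets,
    parse_newick,
    write_newick,
)

__all__ = [
    "SimTruth",
    "simulate_species_tree_with_clades",
    "distant_pair",
    "inject_hgt",
    "random_nni",
    "simulate_marker_set",
    "simulate_biased_alignment",
    "simulate_abundance_table",
    "DESK_SCALE",
]

#: benchmark preset sized so the full suite runs in minutes on one core
DESK_SCALE = {"n_taxa": 32, "n_clades": 8, "n_markers": 40, "k_boots": 50}


@dataclass
class SimTruth:
    """What a generator planted, for recovery tests downstream."""

    seed: int
    markers: dict | None = None          # id -> {transferred, donor, recipient, moved_taxa}
    biased_columns: tuple | None = None  # 1-based column numbers
    biased_taxa: tuple | None = None
    planted_pairs: tuple | None = None   # ((partner, focal), ...)
    noise_sd: float | None = None
    active_samples: tuple | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {k: v for k, v in vars(self).items() if v is not None}
        out = json.dumps(payload, indent=2, default=list, sort_keys=True)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(out + "\n")
        return out


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _yule_join(frags: list[str], rng: np.random.Generator,
               scale: float) -> str:
    """Random sequential pairwise joins with exponential branch lengths."""
    frags = list(frags)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        la, lb = rng.exponential(scale, size=2)
        frags.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return frags[0]


def simulate_species_tree_with_clades(n_taxa: int, n_clades: int, seed: int,
                                      branch_scale: float = 0.1):
    """Rooted species tree plus a taxon map with every clade monophyletic.

    Taxa are split near-evenly over ``n_clades`` labels ``C1..Ck``; each
    clade is a random subtree and the clade roots are joined by a random
    backbone, so every label is a clan by construction.
    """
    if n_taxa < 4:
        raise ValueError("need n_taxa >= 4")
    if not 1 <= n_clades <= n_taxa:
        raise ValueError("need 1 <= n_clades <= n_taxa")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_taxa, n_clades)
    clade_of: dict[str, str] = {}
    clade_frags = []
    for ci in range(n_clades):
        label = f"C{ci + 1}"
        size = base + (1 if ci < extra else 0)
        taxa = [f"{label}_t{k + 1:02d}" for k in range(size)]
        for t in taxa:
            clade_of[t] = label
        clade_frags.append(_yule_join(taxa, rng, branch_scale))
    newick = _yule_join(clade_frags, rng, branch_scale) + ";"
    tree = parse_newick(newick)
    if isinstance(tree, list):  # pragma: no cover - single statement by construction
        raise RuntimeError("expected a single tree")
    return tree, TaxonMap(clade_of)


def distant_pair(species_tree: dendropy.Tree, taxon_map: TaxonMap):
    """A deterministic (donor, recipient) clade pair that are not sisters.

    Planted-transfer recovery benchmarks need the donor's baseline
    sister frequency toward the recipient to be zero, otherwise the
    species-tree signal and the transfer signal are confounded. Returns
    the first label pair (in sorted order) whose clades do not appear in
    each other's species-tree sister sets.
    """
    from .sisters import sister_observations

    obs = sister_observations(species_tree, taxon_map)
    sisters: dict[str, set] = {}
    for o in obs:
        sisters.setdefault(o.focal, set()).add(o.partner)
    labels = sorted(taxon_map.clades())
    for recipient in labels:
        for donor in labels:
            if donor == recipient:
                continue
            if donor in sisters.get(recipient, set()):
                continue
            if recipient in sisters.get(donor, set()):
                continue
            return donor, recipient
    raise ValueError("no non-sister clade pair exists in this species tree")


# ---------------------------------------------------------------------------
# tree surgery
# ---------------------------------------------------------------------------

def _reparse(tree: dendropy.Tree) -> dendropy.Tree:
    return parse_newick(write_newick(tree))


def _detach(tree: dendropy.Tree, node) -> None:
    parent = node.parent_node
    parent.remove_child(node)
    tree.suppress_unifurcations()


def _largest_pure_component(tree: dendropy.Tree, taxa: frozenset):
    """Node of the largest maximal subtree whose leaves are all in ``taxa``."""
    sets = node_leaf_sets(tree)
    best = None
    for node in tree.preorder_node_iter():
        s = sets[node]
        if s and s <= taxa:
            parent = node.parent_node
            if parent is None or not (sets[parent] <= taxa):
                if best is None or len(s) > len(sets[best]):
                    best = node
    return best, sets


def _graft_sister(target, subtree, stem_length: float) -> None:
    """Insert ``subtree`` as sister to ``target`` on target's edge."""
    parent = target.parent_node
    elen = target.edge.length if target.edge.length is not None else 0.0
    new = dendropy.Node()
    parent.remove_child(target)
    parent.add_child(new)
    new.edge.length = elen / 2.0
    new.add_child(target)
    target.edge.length = elen / 2.0
    new.add_child(subtree)
    subtree.edge.length = stem_length


def inject_hgt(tree: dendropy.Tree, donor: str, recipient: str,
               taxon_map: TaxonMap, n_moved: int | None = None,
               seed: int = 0) -> dendropy.Tree:
    """Plant one donor->recipient transfer into a copy of ``tree``.

    With ``n_moved=None`` the whole recipient clade is pruned and
    regrafted onto a random edge strictly inside the donor clan (the
    donor becomes paraphyletic; the recipient keeps its clanhood but its
    closest sister becomes the donor). With an integer
    ``0 <= n_moved < |recipient|`` that many randomly chosen recipient
    leaves are regrafted individually, splitting the recipient clade.
    The leaf set is unchanged either way.
    """
    t, _moved = _inject_hgt_impl(tree, donor, recipient, taxon_map,
                                 n_moved, seed)
    return t


def _inject_hgt_impl(tree, donor, recipient, taxon_map, n_moved, seed):
    rng = np.random.default_rng(seed)
    t = _reparse(tree)
    leaves = leaf_labels(t)
    donor_taxa = frozenset(taxon_map.members(donor) & leaves)
    recip_taxa = frozenset(taxon_map.members(recipient) & leaves)
    if not donor_taxa:
        raise ValueError(f"donor label {donor!r} absent from tree")
    if not recip_taxa:
        raise ValueError(f"recipient label {recipient!r} absent from tree")

    if n_moved is None:
        moving_sets = [recip_taxa]
    else:
        if not 0 <= n_moved < len(recip_taxa):
            raise ValueError("need 0 <= n_moved < |recipient|")
        if n_moved == 0:
            return t, []
        chosen = rng.choice(sorted(recip_taxa), size=n_moved, replace=False)
        moving_sets = [frozenset((x,)) for x in sorted(chosen)]

    for mv in moving_sets:
        sets = node_leaf_sets(t)
        sub_node = next((n for n, s in sets.items() if s == mv), None)
        if sub_node is None:
            raise ValueError(
                f"taxa {sorted(mv)} are not a clade; cannot move as a unit")
        _detach(t, sub_node)
        clan, sets = _largest_pure_component(t, donor_taxa)
        if clan is None:
            raise ValueError(f"donor clan {donor!r} absent after prior edits")
        candidates = [n for n in clan.preorder_iter() if n is not clan]
        if not candidates:       # single-leaf donor clan: graft at the leaf
            candidates = [clan]
        target = candidates[int(rng.integers(len(candidates)))]
        _graft_sister(target, sub_node, float(rng.exponential(0.05)))
    return _reparse(t), sorted(set().union(*moving_sets))


def random_nni(tree: dendropy.Tree, nni_prob: float,
               rng: np.random.Generator) -> dendropy.Tree:
    """Apply an independent random NNI move per internal edge with prob p."""
    if not 0 <= nni_prob <= 1:
        raise ValueError("nni_prob must be in [0, 1]")
    t = _reparse(tree)
    if nni_prob == 0:
        return t
    edges = [n for n in t.preorder_node_iter()
             if n.parent_node is not None and not n.is_leaf()]
    for c in edges:
        if rng.random() >= nni_prob:
            continue
        p = c.parent_node
        if p is None or c.is_leaf():
            continue
        siblings = [s for s in p.child_nodes() if s is not c]
        children = c.child_nodes()
        if not siblings or len(children) < 2:
            continue
        s = siblings[int(rng.integers(len(siblings)))]
        g = children[int(rng.integers(len(children)))]
        p.remove_child(s)
        c.remove_child(g)
        p.add_child(g)
        c.add_child(s)
    return _reparse(t)


def simulate_marker_set(species_tree: dendropy.Tree, taxon_map: TaxonMap,
                        n_markers: int, transfer_fraction: float,
                        donor: str, recipient: str, k_boots: int,
                        nni_prob: float, seed: int,
                        n_moved: int | None = None):
    """Gene trees with planted transfers plus NNI-perturbed bootstrap sets.

    ``floor(transfer_fraction * n_markers)`` randomly chosen markers get
    one transfer; each of the K bootstrap replicates of every marker is
    the marker's ML tree with independent random NNI moves applied at
    per-edge probability ``nni_prob``. Returns ``(MarkerSet, SimTruth)``.
    """
    if not 0 <= transfer_fraction <= 1:
        raise ValueError("transfer_fraction must be in [0, 1]")
    if not 0 <= nni_prob <= 1:
        raise ValueError("nni_prob must be in [0, 1]")
    if k_boots < 1:
        raise ValueError("need k_boots >= 1")
    rng = np.random.default_rng(seed)
    n_transfer = int(np.floor(transfer_fraction * n_markers))
    transferred = set(rng.choice(n_markers, size=n_transfer, replace=False)
                      .tolist())
    markers: dict = {}
    truth_markers: dict = {}
    for mi in range(n_markers):
        mid = f"m{mi + 1:03d}"
        if mi in transferred:
            ml, moved = _inject_hgt_impl(species_tree, donor, recipient,
                                         taxon_map, n_moved,
                                         int(rng.integers(2 ** 31)))
            truth_markers[mid] = {"transferred": True, "donor": donor,
                                  "recipient": recipient, "moved_taxa": moved}
        else:
            ml = _reparse(species_tree)
            truth_markers[mid] = {"transferred": False, "donor": None,
                                  "recipient": None, "moved_taxa": []}
        boots = [random_nni(ml, nni_prob, rng) for _ in range(k_boots)]
        markers[mid] = (ml, boots)
    return MarkerSet(markers), SimTruth(seed=seed, markers=truth_markers)


# ---------------------------------------------------------------------------
# biased alignments
# ---------------------------------------------------------------------------

# a fixed, moderately uneven global amino-acid composition; the four
# bias-target residues (below) are absent from the background so the
# planted heterogeneity is compositionally distinct and truth recovery
# is well-defined
_BASE_FREQS = np.array([
    8.3, 0.0, 5.4, 6.2, 4.0, 7.3, 0.0, 5.7, 5.8, 9.4,
    0.0, 4.3, 4.9, 3.7, 5.2, 6.6, 5.5, 6.9, 0.0, 3.3])
_BASE_FREQS = _BASE_FREQS / _BASE_FREQS.sum()
_SKEW_TARGET = np.zeros(20)
for _aa in "WCMH":
    _SKEW_TARGET[AA20.index(_aa)] = 0.25


def simulate_biased_alignment(n_taxa: int, n_sites: int,
                              biased_fraction: float,
                              biased_taxa_fraction: float,
                              skew: float, seed: int):
    """Alignment with a planted fraction of compositionally biased sites.

    Unbiased sites draw every residue i.i.d. from one global composition
    for all taxa. Biased sites use, for a fixed random subset of taxa,
    the mixture ``(1-skew)*global + skew*target`` where the target
    composition concentrates on four rare residues; the other taxa keep
    the global composition, so those columns carry genuine
    between-taxon heterogeneity. Truth lists the biased columns
    (1-based) and the biased taxa.
    """
    for name, v in (("biased_fraction", biased_fraction),
                    ("biased_taxa_fraction", biased_taxa_fraction),
                    ("skew", skew)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_taxa < 2 or n_sites < 1:
        raise ValueError("need n_taxa >= 2 and n_sites >= 1")
    rng = np.random.default_rng(seed)
    labels = tuple(f"t{i + 1:02d}" for i in range(n_taxa))
    n_biased = int(np.floor(biased_fraction * n_sites))
    biased_cols = np.sort(rng.choice(n_sites, size=n_biased, replace=False))
    n_btaxa = int(np.floor(biased_taxa_fraction * n_taxa))
    biased_taxa = np.sort(rng.choice(n_taxa, size=n_btaxa, replace=False))
    skewed = (1.0 - skew) * _BASE_FREQS + skew * _SKEW_TARGET

    aa = np.array(list(AA20))
    mat = rng.choice(20, size=(n_taxa, n_sites), p=_BASE_FREQS)
    if n_biased and n_btaxa:
        biased_draw = rng.choice(20, size=(n_btaxa, n_biased), p=skewed)
        mat[np.ix_(biased_taxa, biased_cols)] = biased_draw
    seqs = tuple("".join(aa[row]) for row in mat)
    truth = SimTruth(seed=seed,
                     biased_columns=tuple(int(c) + 1 for c in biased_cols),
                     biased_taxa=tuple(labels[i] for i in biased_taxa))
    return Alignment(labels, seqs), truth


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def simulate_abundance_table(n_samples: int, n_genomes: int, n_focal: int,
                             planted_links: Mapping[str, Sequence[str]] | None,
                             noise_sd: float, seed: int,
                             n_active_samples: int | None = None):
    """Read-mapping statistics with planted proportional genome groups.

    Genomes are ``MAG01..`` (focal) and ``G001..`` (others). Each genome
    follows a lognormal latent abundance (per-genome location ~
    N(2, 0.3), per-sample deviation ~ N(0, 1)). Every partner genome in
    ``planted_links`` shares one latent series with its linked focal
    genomes, each copy jittered by multiplicative lognormal noise of
    s.d. ``noise_sd``. Abundances are converted to mapped-read counts,
    Lander-Waterman covered fractions (with 2% jitter) and per-sample
    read totals so the full filter -> Ar -> CLR -> rho path is
    exercised. In the ``n_samples - n_active_samples`` inactive samples
    the focal genomes are rare (normalized abundance << 1), so the
    sample-inclusion rule drops those samples.

    Returns ``(stats DataFrame, SimTruth)``.
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < n_focal < n_genomes:
        raise ValueError("need 0 < n_focal < n_genomes")
    if n_active_samples is None:
        n_active_samples = n_samples
    if not 0 <= n_active_samples <= n_samples:
        raise ValueError("need 0 <= n_active_samples <= n_samples")
    rng = np.random.default_rng(seed)

    focal_ids = [f"MAG{i + 1:02d}" for i in range(n_focal)]
    other_ids = [f"G{i + 1:03d}" for i in range(n_genomes - n_focal)]
    genomes = focal_ids + other_ids
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    active = np.sort(rng.choice(n_samples, size=n_active_samples,
                                replace=False))
    active_set = set(active.tolist())

    links: dict[str, list[str]] = {}
    if planted_links:
        used_focal: set[str] = set()
        for partner, focals in planted_links.items():
            if partner not in other_ids:
                raise ValueError(f"partner {partner!r} is not a non-focal genome")
            focals = list(focals)
            for f in focals:
                if f not in focal_ids:
                    raise ValueError(f"{f!r} is not a focal genome")
                if f in used_focal:
                    raise ValueError(f"focal genome {f!r} linked twice")
                used_focal.add(f)
            links[partner] = focals

    mu = {g: rng.normal(2.0, 0.3) for g in genomes}
    z = {g: rng.normal(0.0, 1.0, size=n_samples) for g in genomes}
    for partner, focals in links.items():
        host = rng.normal(0.0, 1.0, size=n_samples)
        z[partner] = host + rng.normal(0.0, noise_sd, size=n_samples)
        for f in focals:
            z[f] = host + rng.normal(0.0, noise_sd, size=n_samples)

    genome_size = {g: int(rng.integers(1_500_000, 3_500_000)) for g in genomes}
    read_len = 100.0
    ns = rng.integers(5_000_000, 20_000_000, size=n_samples).astype(float)
    nm = float(ns.max())

    rows = []
    for si, sample in enumerate(samples):
        for g in genomes:
            log_a = mu[g] + z[g][si]
            if g in focal_ids and si not in active_set:
                log_a -= 6.0
            a = float(np.exp(log_a))
            r = int(round(a * (ns[si] / nm) * genome_size[g] / read_len))
            depth = r * read_len / genome_size[g]
            cf = float(np.clip((-np.expm1(-depth))
                               * (1.0 + rng.normal(0.0, 0.02)), 0.0, 1.0))
            if r == 0:
                cf = 0.0
            rows.append({"sample": sample, "genome": g, "r": r,
                         "l": read_len, "g": genome_size[g],
                         "covered_fraction": cf, "Ns": int(ns[si])})
    stats = pd.DataFrame(rows, columns=["sample", "genome", "r", "l", "g",
                                        "covered_fraction", "Ns"])
    pairs = tuple((p, f) for p in sorted(links) for f in links[p])
    truth = SimTruth(seed=seed, planted_pairs=pairs, noise_sd=noise_sd,
                     active_samples=tuple(samples[i] for i in active),
                     extras={"focal_ids": focal_ids})
    return stats, truth
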