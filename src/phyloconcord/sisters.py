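"""Sister-clade frequency profiling over gene trees and bootstrap samples.

For every taxonomic label (clade) in a rooted gene tree, the clade is
first decomposed into monophyletic components; each component's sister
group is the union of the other subtrees hanging off the component's
parent node. When a sister set mixes several labels, the observation
weight (1 per component per tree) is shared among those labels in
proportion to their leaf counts. Pooling the weighted observations over
all bootstrap trees of all markers, and normalizing per focal label,
yields a frequency profile of "who shows up next to whom" — recurrent
unexpected sisterhood (e.g. a symbiont clade repeatedly next to its
host's clade) is the signature of inter-lineage gene transfer.

A structural subtlety inherited from the component construction: a
monophyletic focal clade can never be sister to itself — self-label
weight can arise only via mixed sister sets or split clades, and is kept
in the normalizing denominator but excluded from partner calls.

Leaves without a clade label are assigned a pseudo-label from their
domain (``domain:bacteria`` etc.) when the taxon map carries domains,
else ``unassigned``; they contribute sister weight but are never focal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import pandas as pd

from .trees import MarkerSet, TaxonMap, ensure_rooted, is_rooted, node_leaf_sets
from .ranking import _component_nodes

__all__ = [
    "SisterObservation",
    "SisterProfile",
    "sister_observations",
    "aggregate_profile",
    "call_partners",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class SisterObservation:
    marker_id: str
    tree_index: int
    focal: str
    component_index: int       # 1-based within the tree, ordered by min member
    component: frozenset       # leaves of the focal component
    partner: str
    weight: float              # in (0,1]; weights of one component sum to 1


def _leaf_label(taxon: str, taxon_map: TaxonMap) -> str:
    if taxon in taxon_map.clade_of:
        return taxon_map.clade_of[taxon]
    dom = taxon_map.domain_of.get(taxon)
    return f"domain:{dom}" if dom else "unassigned"


def sister_observations(tree: dendropy.Tree, taxon_map: TaxonMap,
                        marker_id: str = "", tree_index: int = 0
                        ) -> list[SisterObservation]:
    """All weighted sister observations of one rooted tree.

    For each focal clade label present, each monophyletic component
    contributes one unit of weight, spread over the labels of its sister
    set (all non-component subtrees at its parent, merged) in proportion
    to leaf counts. Components whose parent is the root of a two-child
    tree have the remaining half of the tree as sister; a component that
    *is* the root yields no observation.
    """
    if not is_rooted(tree):
        raise ValueError("sister_observations requires a rooted tree")
    leaf_sets = node_leaf_sets(tree)
    all_leaves = leaf_sets[tree.seed_node]
    present_labels = sorted({taxon_map.clade_of[t] for t in all_leaves
                             if t in taxon_map.clade_of})
    if len({_leaf_label(t, taxon_map) for t in all_leaves}) < 2:
        raise ValueError("need >=2 distinct labels present in tree")
    obs: list[SisterObservation] = []
    for focal in present_labels:
        members = frozenset(t for t in all_leaves
                            if taxon_map.clade_of.get(t) == focal)
        comp_nodes = _component_nodes(tree, members, None, leaf_sets)
        for ci, node in enumerate(comp_nodes, start=1):
            parent = node.parent_node
            if parent is None:
                continue
            sister = leaf_sets[parent] - leaf_sets[node]
            if not sister:
                continue
            counts: dict[str, int] = {}
            for t in sorted(sister):
                lab = _leaf_label(t, taxon_map)
                counts[lab] = counts.get(lab, 0) + 1
            total = len(sister)
            for lab in sorted(counts):
                obs.append(SisterObservation(
                    marker_id, tree_index, focal, ci,
                    frozenset(leaf_sets[node]), lab, counts[lab] / total))
    return obs


@dataclass
class SisterProfile:
    """Normalized sister-frequency profile of one focal clade label."""

    focal: str
    occurrences: dict           # partner label -> normalized occurrence in [0,1]
    total_observations: float   # pooled weight = number of (component, tree) units
    n_trees: int                # trees (marker x replicate) containing the focal
    self_weight: float = 0.0    # share of weight pointing back at the focal label
    components: dict = field(default_factory=dict)
    # components: frozenset(component leaves) -> {partner: normalized occurrence}


def aggregate_profile(markers: MarkerSet, taxon_map: TaxonMap,
                      outgroup: Iterable[str] | None = None,
                      include_ml: bool = False,
                      per_tree_average: bool = False) -> dict[str, SisterProfile]:
    """Pool sister observations over all bootstrap trees of all markers.

    By default weights are pooled over every (marker x replicate) tree
    and normalized once per focal label; ``per_tree_average=True``
    instead normalizes within each tree and averages the per-tree
    distributions. The ML trees contribute only when ``include_ml``.

    Focal labels absent from every tree are omitted with a warning.
    Per-component sub-profiles are keyed by the component's leaf set so
    recurrent sub-clades (e.g. a stable transferred subgroup) can be
    profiled on their own.
    """
    pooled: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    n_trees: dict[str, int] = {}
    comp_pooled: dict[str, dict] = {}
    per_tree: dict[str, list] = {}

    def consume(tree, mid, idx):
        rooted = ensure_rooted(tree, outgroup=outgroup)
        obs = sister_observations(rooted, taxon_map, mid, idx)
        seen = set()
        tree_w: dict[str, dict[str, float]] = {}
        for o in obs:
            seen.add(o.focal)
            pooled.setdefault(o.focal, {})
            pooled[o.focal][o.partner] = pooled[o.focal].get(o.partner, 0.0) + o.weight
            totals[o.focal] = totals.get(o.focal, 0.0) + o.weight
            cp = comp_pooled.setdefault(o.focal, {}).setdefault(o.component, {})
            cp[o.partner] = cp.get(o.partner, 0.0) + o.weight
            tw = tree_w.setdefault(o.focal, {})
            tw[o.partner] = tw.get(o.partner, 0.0) + o.weight
        for focal in seen:
            n_trees[focal] = n_trees.get(focal, 0) + 1
        for focal, w in tree_w.items():
            s = sum(w.values())
            per_tree.setdefault(focal, []).append(
                {p: v / s for p, v in w.items()})

    for mid, (ml, boots) in markers:
        idx = 0
        if include_ml:
            consume(ml, mid, idx)
            idx += 1
        for bt in boots:
            consume(bt, mid, idx)
            idx += 1

    missing = sorted(set(c for c in taxon_map.clade_of.values())
                     - set(pooled))
    if missing:
        import warnings
        warnings.warn(f"focal labels absent from all trees: {missing}",
                      UserWarning, stacklevel=2)

    profiles: dict[str, SisterProfile] = {}
    for focal, weights in pooled.items():
        if per_tree_average:
            dists = per_tree[focal]
            acc: dict[str, float] = {}
            for d in dists:
                for p, v in d.items():
                    acc[p] = acc.get(p, 0.0) + v
            occ = {p: v / len(dists) for p, v in acc.items()}
        else:
            total = totals[focal]
            occ = {p: v / total for p, v in weights.items()}
        comps = {}
        for comp, w in comp_pooled[focal].items():
            s = sum(w.values())
            comps[comp] = {p: v / s for p, v in w.items()}
        profiles[focal] = SisterProfile(
            focal=focal,
            occurrences=occ,
            total_observations=totals[focal],
            n_trees=n_trees[focal],
            self_weight=occ.get(focal, 0.0),
            components=comps,
        )
    return profiles


def call_partners(profile: SisterProfile, threshold: float = 0.3) -> list[str]:
    """Partner labels with normalized occurrence strictly above threshold.

    The focal's own label is excluded from calls (self-weight stays in
    the denominator); results are sorted by descending occurrence.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    calls = [(p, v) for p, v in profile.occurrences.items()
             if p != profile.focal and v > threshold]
    calls.sort(key=lambda pv: (-pv[1], pv[0]))
    return [p for p, _ in calls]


def profiles_to_frame(profiles: dict[str, SisterProfile]) -> pd.DataFrame:
    """Long-format table (focal, partner, occurrence, n_obs, n_trees)."""
    rows = []
    for focal in sorted(profiles):
        pr = profiles[focal]
        for partner in sorted(pr.occurrences, key=lambda p: (-pr.occurrences[p], p)):
            rows.append({
                "focal": focal,
                "partner": partner,
                "occurrence": pr.occurrences[partner],
                "n_obs": pr.total_observations,
                "n_trees": pr.n_trees,
            })
    return pd.DataFrame(rows, columns=["focal", "partner", "occurrence",
                                       "n_obs", "n_trees"])


def plot_profiles(profiles: dict[str, SisterProfile], path,
                  threshold: float | None = 0.3) -> None:
    """Stacked-bar plot of sister frequencies per focal clade (one bar each)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    focals = sorted(profiles)
    partners = sorted({p for f in focals for p in profiles[f].occurrences})
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(focals)), 4.5))
    bottoms = [0.0] * len(focals)
    for pi, partner in enumerate(partners):
        vals = [profiles[f].occurrences.get(partner, 0.0) for f in focals]
        ax.bar(focals, vals, bottom=bottoms, color=cmap(pi % 20), label=partner)
        bottoms = [b + v for b, v in zip(bottoms, vals)]
    if threshold is not None:
        ax.axhline(threshold, ls="--", lw=0.8, color="k")
    ax.set_ylabel("normalized sister occurrence")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    for f, x in zip(focals, range(len(focals))):
        ax.text(x, 1.0, f"n={profiles[f].total_observations:.0f}\n"
                        f"t={profiles[f].n_trees}",
                ha="center", va="bottom", fontsize=5)
    plt.xticks(rotation=60, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
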