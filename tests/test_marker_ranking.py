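"""Split counting, domain-violation exclusion, marker ranking and selection."""

import numpy as np
import pytest

from phyloconcord import (
    MarkerSet,
    TaxonMap,
    count_splits,
    exclude_domain_violations,
    monophyletic_components,
    parse_newick,
    score_and_rank_markers,
    select_fraction,
    simulate_marker_set,
    simulate_species_tree_with_clades,
)
from phyloconcord.ranking import RankReport, MarkerScore

from conftest import all_clades, brute_components, random_rooted_tree


class TestComponents:
    def test_monophyletic_pair(self):
        t = parse_newick("((a1,a2),(b1,b2));")
        assert monophyletic_components(t, {"a1", "a2"}) == [{"a1", "a2"}]

    def test_interleaved_pair_splits(self):
        t = parse_newick("((a1,b1),(a2,b2));")
        assert monophyletic_components(t, {"a1", "a2"}) == [{"a1"}, {"a2"}]

    def test_all_leaves_single_component(self):
        t = parse_newick("((a1,b1),(a2,b2));")
        leaves = {"a1", "a2", "b1", "b2"}
        assert monophyletic_components(t, leaves) == [leaves]

    def test_missing_taxa_error_lists_offenders(self):
        t = parse_newick("((a1,a2),(b1,b2));")
        with pytest.raises(ValueError, match="zz"):
            monophyletic_components(t, {"a1", "zz"})

    def test_transparent_unmapped_taxa(self):
        # with x unmapped (outside the restrict universe) the decomposition
        # equals the one on the pruned tree, so A stays in one piece
        t = parse_newick("((a1,x),(a2,a3));")
        mapped = {"a1", "a2", "a3"}
        assert monophyletic_components(t, mapped, restrict=mapped) == [mapped]
        assert monophyletic_components(t, mapped) == [{"a1"}, {"a2", "a3"}]

    def test_oracle_equivalence_on_random_trees(self):
        """Component decomposition matches the brute-force clade oracle."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            t = random_rooted_tree(rng, int(rng.integers(4, 13)))
            leaves = sorted({lf.taxon.label for lf in t.leaf_node_iter()})
            k = int(rng.integers(1, len(leaves) + 1))
            taxa = frozenset(rng.choice(leaves, size=k, replace=False))
            got = set(map(frozenset, monophyletic_components(t, taxa)))
            assert got == brute_components(t, taxa)
            # split flag: single component iff taxa form a rooted clade
            assert (len(got) == 1) == (taxa in all_clades(t))


class TestCountSplits:
    def test_clean_tree_scores_zero(self, quartet_map):
        t = parse_newick("((a1,a2),(b1,b2));")
        sc = count_splits(t, quartet_map)
        assert sc.total_taxon_splits == 0
        assert sc.clade_split == {"A": False, "B": False}

    def test_interleaved_tree_tie_break(self, quartet_map):
        # both clades split into singletons: the component holding the
        # lexicographically smallest member wins, so a2 and b2 are the splits
        t = parse_newick("((a1,b1),(a2,b2));")
        sc = count_splits(t, quartet_map)
        assert sc.clade_components["A"] == [{"a1"}, {"a2"}]
        assert sc.taxon_split == {"a1": 0, "a2": 1, "b1": 0, "b2": 1}
        assert sc.total_taxon_splits == 2
        assert sc.n_split_clades == 2

    def test_singleton_clade_never_split(self):
        tmap = TaxonMap({"a1": "A", "a2": "A", "c1": "C"})
        t = parse_newick("((a1,c1),(a2,x));")
        sc = count_splits(t, tmap)
        assert sc.clade_split["C"] is False
        assert sc.taxon_split["c1"] == 0
        assert sc.unmapped == {"x"}

    def test_no_mapped_taxa_is_error(self, quartet_map):
        t = parse_newick("((x1,x2),(x3,x4));")
        with pytest.raises(ValueError, match="no mapped taxa"):
            count_splits(t, quartet_map)

    def test_unrooted_tree_rejected(self, quartet_map):
        t = parse_newick("(a1,a2,(b1,b2));")
        with pytest.raises(ValueError, match="rooted"):
            count_splits(t, quartet_map)

    def test_leaf_order_permutation_invariance(self, quartet_map):
        a = count_splits(parse_newick("((a1,b1),(a2,b2));"), quartet_map)
        b = count_splits(parse_newick("((b2,a2),(b1,a1));"), quartet_map)
        assert a.total_taxon_splits == b.total_taxon_splits
        assert a.taxon_split == b.taxon_split


class TestDomainExclusion:
    @pytest.fixture()
    def domain_map(self):
        return TaxonMap(
            {"arc1": "A1", "arc2": "A2", "bac1": "B1", "bac2": "B2"},
            {"arc1": "archaea", "arc2": "archaea",
             "bac1": "bacteria", "bac2": "bacteria"})

    @staticmethod
    def _ms(newick):
        t = parse_newick(newick)
        return MarkerSet({"m1": (t, [parse_newick(newick)])})

    def test_clean_marker_retained(self, domain_map):
        kept, report = exclude_domain_violations(
            self._ms("((arc1,arc2),(bac1,bac2));"), domain_map)
        assert kept == ["m1"]
        assert report.loc[0, "status"] == "retained"

    def test_nested_archaeon_excluded(self, domain_map):
        kept, report = exclude_domain_violations(
            self._ms("((arc1,bac1),(arc2,bac2));"), domain_map)
        assert kept == []
        assert report.loc[0, "status"] == "excluded"
        assert report.loc[0, "offending_taxa"] != ""

    def test_archaea_only_marker_vacuously_retained(self):
        tmap = TaxonMap({"arc1": "A1", "arc2": "A2", "arc3": "A3"},
                        {"arc1": "archaea", "arc2": "archaea",
                         "arc3": "archaea"})
        kept, _ = exclude_domain_violations(
            self._ms("((arc1,arc2),arc3);"), tmap)
        assert kept == ["m1"]

    def test_tiny_marker_skipped_with_warning(self, domain_map):
        t = parse_newick("(arc1,bac1);")
        ms = MarkerSet({"m1": (t, [parse_newick("(arc1,bac1);")])})
        with pytest.warns(UserWarning, match="skipped"):
            kept, report = exclude_domain_violations(ms, domain_map)
        assert kept == []
        assert report.loc[0, "status"] == "skipped"


class TestScoreAndRank:
    def test_clean_marker_ranks_first(self, quartet_map):
        clean = "((a1,a2),(b1,b2));"
        dirty = "((a1,b1),(a2,b2));"
        ms = MarkerSet({
            "dirty": (parse_newick(dirty), [parse_newick(dirty)] * 3),
            "clean": (parse_newick(clean), [parse_newick(clean)] * 3),
        })
        rep = score_and_rank_markers(ms, quartet_map)
        by_id = {s.marker_id: s for s in rep}
        assert by_id["clean"].percent_split_clades == 0.0
        assert by_id["clean"].normalized_splits == 0.0
        assert by_id["clean"].rank == 1
        assert by_id["dirty"].percent_split_clades == 100.0
        assert by_id["dirty"].normalized_splits == 2 / 4
        assert by_id["dirty"].rank == 2

    def test_one_regrafted_taxon_normalizes_to_one_eighth(self):
        # 8 leaves, 4 clades; a2 sits as sister to the B clade in every
        # bootstrap tree: exactly one split taxon per tree -> 1/8
        tmap = TaxonMap({f"{c.lower()}{i}": c
                         for c in "ABCD" for i in (1, 2)})
        moved = "((a1,(a2,(b1,b2))),((c1,c2),(d1,d2)));"
        ms = MarkerSet({"m": (parse_newick(moved),
                              [parse_newick(moved) for _ in range(5)])})
        rep = score_and_rank_markers(ms, tmap)
        s = rep.scores[0]
        assert s.normalized_splits == pytest.approx(1 / 8)
        assert s.percent_split_clades == pytest.approx(100 / 4)

    def test_tie_broken_by_normalized_splits(self):
        ms_scores = [
            MarkerScore("mA", 25.0, 0.10, 0, 8, 4, 3, 0),
            MarkerScore("mB", 25.0, 0.05, 0, 8, 4, 3, 0),
        ]
        # rebuild through the public path: equal percent, lower normalized wins
        ordered = sorted(ms_scores,
                         key=lambda s: (s.percent_split_clades,
                                        s.normalized_splits, s.marker_id))
        assert ordered[0].marker_id == "mB"

    def test_bootstrap_leafset_mismatch_rejected(self, quartet_map):
        with pytest.raises(ValueError, match="leaf set differs"):
            MarkerSet({"m": (parse_newick("((a1,a2),(b1,b2));"),
                             [parse_newick("((a1,a2),(b1,x));")])})

    def test_null_simulation_scores_exactly_zero(self, small_species):
        tree, tmap = small_species
        ms, _ = simulate_marker_set(tree, tmap, n_markers=5,
                                    transfer_fraction=0.0, donor="C1",
                                    recipient="C2", k_boots=5, nni_prob=0.0,
                                    seed=3)
        rep = score_and_rank_markers(ms, tmap)
        assert all(s.percent_split_clades == 0.0 for s in rep)
        assert all(s.normalized_splits == 0.0 for s in rep)

    def test_transfer_enrichment_in_top_half(self, small_species):
        """Markers carrying a planted transfer sink to the bottom ranks."""
        tree, tmap = small_species
        ms, truth = simulate_marker_set(tree, tmap, n_markers=16,
                                        transfer_fraction=0.5, donor="C2",
                                        recipient="C7", k_boots=10,
                                        nni_prob=0.02, seed=8)
        rep = score_and_rank_markers(ms, tmap)
        clean = {m for m, info in truth.markers.items()
                 if not info["transferred"]}
        top = set(select_fraction(rep, 0.5, "top"))
        assert len(clean & top) >= 0.8 * len(clean)


class TestSelectFraction:
    @pytest.fixture()
    def report8(self):
        scores = [MarkerScore(f"m{i}", float(i), 0.0, 0, 8, 4, 3, i)
                  for i in range(1, 9)]
        return RankReport(scores)

    def test_top_quarter(self, report8):
        assert select_fraction(report8, 0.25, "top") == ["m1", "m2"]

    def test_full_fraction_returns_all(self, report8):
        assert len(select_fraction(report8, 1.0, "top")) == 8

    def test_ceiling_on_odd_counts(self):
        scores = [MarkerScore(f"m{i}", float(i), 0.0, 0, 8, 4, 3, i)
                  for i in range(1, 8)]
        got = select_fraction(RankReport(scores), 0.5, "top")
        assert len(got) == 4  # ceil(3.5)

    def test_bottom_end(self, report8):
        assert select_fraction(report8, 0.25, "bottom") == ["m7", "m8"]

    def test_empty_report_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_fraction(RankReport([]), 0.5, "top")
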