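"""Determinism, truth-consistency and null calibration of the generators."""

import numpy as np
import pytest

from phyloconcord import (
    aggregate_profile,
    bipartitions,
    inject_hgt,
    is_clan,
    leaf_labels,
    monophyletic_components,
    parse_newick,
    random_nni,
    score_and_rank_markers,
    simulate_abundance_table,
    simulate_biased_alignment,
    simulate_marker_set,
    simulate_species_tree_with_clades,
    sister_observations,
    total_chi2,
    write_newick,
)


class TestSpeciesTree:
    def test_every_clade_is_a_clan(self):
        tree, tmap = simulate_species_tree_with_clades(16, 4, seed=0)
        assert len(leaf_labels(tree)) == 16
        clades = tmap.clades()
        assert len(clades) == 4
        for members in clades.values():
            assert is_clan(tree, members)

    def test_singleton_clades(self):
        tree, tmap = simulate_species_tree_with_clades(4, 4, seed=0)
        assert all(len(m) == 1 for m in tmap.clades().values())

    def test_same_seed_same_newick(self):
        a, _ = simulate_species_tree_with_clades(20, 5, seed=9)
        b, _ = simulate_species_tree_with_clades(20, 5, seed=9)
        assert write_newick(a) == write_newick(b)

    def test_infeasible_partition_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree_with_clades(4, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_species_tree_with_clades(3, 2, seed=0)


class TestInjectHGT:
    @pytest.fixture()
    def base(self):
        return simulate_species_tree_with_clades(24, 6, seed=14)

    def test_whole_clade_transfer_points_at_donor(self, base):
        tree, tmap = base
        g = inject_hgt(tree, "C3", "C5", tmap, seed=2)
        assert leaf_labels(g) == leaf_labels(tree)
        obs = [o for o in sister_observations(g, tmap) if o.focal == "C5"]
        partners = {o.partner for o in obs}
        assert partners == {"C3"}

    def test_whole_clade_transfer_splits_donor(self, base):
        tree, tmap = base
        g = inject_hgt(tree, "C3", "C5", tmap, seed=2)
        assert len(monophyletic_components(g, tmap.members("C3"))) >= 2
        assert is_clan(g, tmap.members("C5"))

    def test_partial_move_splits_recipient(self, base):
        tree, tmap = base
        g = inject_hgt(tree, "C3", "C5", tmap, n_moved=2, seed=2)
        assert leaf_labels(g) == leaf_labels(tree)
        assert len(monophyletic_components(g, tmap.members("C5"))) >= 2

    def test_zero_moves_is_identity(self, base):
        tree, tmap = base
        g = inject_hgt(tree, "C3", "C5", tmap, n_moved=0, seed=2)
        assert bipartitions(g) == bipartitions(tree)

    def test_moving_all_members_rejected(self, base):
        tree, tmap = base
        n = len(tmap.members("C5"))
        with pytest.raises(ValueError, match="n_moved"):
            inject_hgt(tree, "C3", "C5", tmap, n_moved=n, seed=2)


class TestMarkerSet:
    def test_null_set_replicates_identical_to_species_tree(self, small_species):
        tree, tmap = small_species
        ms, truth = simulate_marker_set(tree, tmap, 3, 0.0, "C1", "C2",
                                        k_boots=4, nni_prob=0.0, seed=6)
        for _mid, (ml, boots) in ms:
            for bt in boots:
                assert bipartitions(bt) == bipartitions(tree)
        assert all(not v["transferred"] for v in truth.markers.values())

    def test_transfer_count_matches_fraction(self, small_species):
        tree, tmap = small_species
        ms, truth = simulate_marker_set(tree, tmap, 8, 0.5, "C1", "C4",
                                        k_boots=2, nni_prob=0.0, seed=6)
        n_tr = sum(v["transferred"] for v in truth.markers.values())
        assert n_tr == 4

    def test_truth_references_existing_taxa(self, small_species):
        tree, tmap = small_species
        ms, truth = simulate_marker_set(tree, tmap, 6, 0.5, "C1", "C4",
                                        k_boots=2, nni_prob=0.0, seed=6)
        leaves = leaf_labels(tree)
        for mid, info in truth.markers.items():
            assert mid in ms.markers
            assert set(info["moved_taxa"]) <= leaves

    def test_nni_perturbs_some_replicates(self, small_species):
        tree, tmap = small_species
        ms, _ = simulate_marker_set(tree, tmap, 2, 0.0, "C1", "C2",
                                    k_boots=20, nni_prob=0.05, seed=6)
        changed = sum(bipartitions(bt) != bipartitions(tree)
                      for _mid, (ml, boots) in ms for bt in boots)
        assert changed > 0

    def test_determinism(self, small_species):
        tree, tmap = small_species
        a, _ = simulate_marker_set(tree, tmap, 3, 0.5, "C1", "C4", 3, 0.05,
                                   seed=99)
        b, _ = simulate_marker_set(tree, tmap, 3, 0.5, "C1", "C4", 3, 0.05,
                                   seed=99)
        for mid in a.ids():
            assert write_newick(a.ml_tree(mid)) == write_newick(b.ml_tree(mid))
            assert [write_newick(t) for t in a.bootstrap_trees(mid)] == \
                   [write_newick(t) for t in b.bootstrap_trees(mid)]


class TestRandomNNI:
    def test_leafset_preserved(self):
        tree, _ = simulate_species_tree_with_clades(16, 4, seed=3)
        rng = np.random.default_rng(0)
        out = random_nni(tree, 0.5, rng)
        assert leaf_labels(out) == leaf_labels(tree)

    def test_zero_probability_is_identity(self):
        tree, _ = simulate_species_tree_with_clades(16, 4, seed=3)
        rng = np.random.default_rng(0)
        assert write_newick(random_nni(tree, 0.0, rng)) == write_newick(tree)


class TestBiasedAlignment:
    def test_determinism(self):
        a, _ = simulate_biased_alignment(8, 60, 0.1, 0.5, 1.0, seed=4)
        b, _ = simulate_biased_alignment(8, 60, 0.1, 0.5, 1.0, seed=4)
        assert a.to_fasta() == b.to_fasta()

    def test_no_bias_means_empty_truth_and_low_chi2(self):
        aln, truth = simulate_biased_alignment(10, 200, 0.0, 0.5, 1.0, seed=4)
        assert truth.biased_columns == ()
        # null chi2 ~ chi-square with (taxa-1)(states-1) d.o.f. per scale;
        # a generous cap distinguishes it from planted inflation
        aln2, _ = simulate_biased_alignment(10, 200, 0.2, 0.5, 1.0, seed=4)
        assert total_chi2(aln) < total_chi2(aln2)

    def test_planted_columns_score_higher(self):
        aln, truth = simulate_biased_alignment(16, 300, 0.1, 0.5, 1.0, seed=8)
        cols = {j: sum(1 for ch in aln.column(j - 1) if ch in "WCMH")
                for j in range(1, aln.n_sites + 1)}
        planted = [cols[j] for j in truth.biased_columns]
        rest = [cols[j] for j in cols if j not in set(truth.biased_columns)]
        assert np.mean(planted) > np.mean(rest)

    def test_invalid_skew_rejected(self):
        with pytest.raises(ValueError, match="skew"):
            simulate_biased_alignment(8, 60, 0.1, 0.5, 1.2, seed=4)


class TestAbundanceTable:
    def test_determinism(self):
        a, _ = simulate_abundance_table(6, 10, 3, {"G001": ["MAG01"]}, 0.1,
                                        seed=5)
        b, _ = simulate_abundance_table(6, 10, 3, {"G001": ["MAG01"]}, 0.1,
                                        seed=5)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_zero_noise_pairs_are_perfectly_proportional(self):
        from phyloconcord import coproportionality_screen
        stats, truth = simulate_abundance_table(
            12, 20, 5, {"G001": ["MAG01"]}, noise_sd=0.0, seed=5)
        res = coproportionality_screen(stats, truth.extras["focal_ids"],
                                       min_focal=1)
        rt = res.rho.set_index(["genome", "focal"])["rho"]
        # read counts are integers, so "exact" proportionality is limited
        # only by rounding
        assert rt.loc[("G001", "MAG01")] >= 0.999

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_abundance_table(6, 10, 3, None, -0.1, seed=5)

    def test_invalid_links_rejected(self):
        with pytest.raises(ValueError, match="not a non-focal"):
            simulate_abundance_table(6, 10, 3, {"MAG01": ["MAG02"]}, 0.1,
                                     seed=5)
        with pytest.raises(ValueError, match="linked twice"):
            simulate_abundance_table(
                6, 10, 3, {"G001": ["MAG01"], "G002": ["MAG01"]}, 0.1, seed=5)


def test_null_calibration_across_stages(small_species):
    """With every plant parameter at zero, all stages report clean data:
    zero marker scores, species-tree sister profiles, no partner calls."""
    tree, tmap = small_species
    ms, _ = simulate_marker_set(tree, tmap, 4, 0.0, "C1", "C2",
                                k_boots=5, nni_prob=0.0, seed=30)
    rep = score_and_rank_markers(ms, tmap)
    assert all(s.normalized_splits == 0.0 for s in rep)

    profs = aggregate_profile(ms, tmap)
    expected = {}
    for o in sister_observations(tree, tmap):
        expected.setdefault(o.focal, {})
        expected[o.focal][o.partner] = \
            expected[o.focal].get(o.partner, 0.0) + o.weight
    for focal, weights in expected.items():
        total = sum(weights.values())
        for partner, w in weights.items():
            assert profs[focal].occurrences[partner] == \
                pytest.approx(w / total)

    from phyloconcord import coproportionality_screen
    stats, truth = simulate_abundance_table(12, 20, 5, None, 0.1, seed=30)
    res = coproportionality_screen(stats, truth.extras["focal_ids"],
                                   min_focal=1)
    assert res.partners == []
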