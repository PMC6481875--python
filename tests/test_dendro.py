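import math

import numpy as np
import pytest
from scipy import stats

from coexpair.correlation import cross_correlation_matrix
from coexpair.dendro import (
    SampleDistanceMatrix,
    cophenetic_correlation,
    dendrogram_equivalence,
    hierarchical_dendrogram,
    high_coexpression_gene_sets,
    mantel_test,
    sample_distance_matrix,
)
from coexpair.simulate import SimulationConfig, generate_paired_study
from conftest import make_matrix


def random_distance(rng, n=5):
    x = rng.normal(size=(n, 30))
    d = 1 - np.corrcoef(x)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return SampleDistanceMatrix([f"P{i+1}" for i in range(n)], d)


class TestHighCoexpressionGeneSets:
    def test_threshold_above_max_empty(self, tiny_study):
        R = cross_correlation_matrix(tiny_study["EET"], tiny_study["CAR"])
        set_a, set_b, report = high_coexpression_gene_sets(R, 0.9999999)
        assert not set_a and not set_b and report["n_a"] == 0

    def test_noiseless_planted_recovers_module_genes(self, planted_study):
        cfg, study, truth = planted_study
        R = cross_correlation_matrix(study["EET"], study["CAR"])
        set_a, set_b, _ = high_coexpression_gene_sets(R, 0.9999)
        expect_a = set(truth[(truth.tissue == "EET") & (truth.module_id != "null")].gene_id)
        expect_b = set(truth[(truth.tissue == "CAR") & (truth.module_id != "null")].gene_id)
        assert set_a == expect_a and set_b == expect_b

    def test_single_pair_and_overlap_report(self):
        a = make_matrix("EET", [[1, 2, 3, 4, 5], [4, 1, 2, 2, 3]], genes=["g1", "gx"])
        b = make_matrix("CAR", [[2, 4, 6, 8, 10], [5, 0, 3, 1, 2]], genes=["g2", "gy"])
        R = cross_correlation_matrix(a, b)
        set_a, set_b, report = high_coexpression_gene_sets(R, 0.999)
        assert set_a == {"g1"} and set_b == {"g2"}
        assert report["shared"] == []
        assert report["n_exclusive_a"] == 1 and report["n_exclusive_b"] == 1


class TestSampleDistanceMatrix:
    def test_identical_unit_profiles_distance_zero(self):
        m = make_matrix("X", [[1, 1, 5], [2, 2, 9], [3, 3, 1]])
        dm = sample_distance_matrix(m)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_units_distance_two(self):
        m = make_matrix("X", [[1, 5, 2], [2, 4, 1], [3, 3, 3], [4, 2, 5], [5, 1, 4]])
        dm = sample_distance_matrix(m)
        assert dm.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_entries_match_scalar_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(0, 1, size=(4, 3))
        m = make_matrix("X", values)
        dm = sample_distance_matrix(m)
        for u in range(3):
            for v in range(3):
                if u == v:
                    continue
                expected = 1 - stats.pearsonr(values[:, u], values[:, v]).statistic
                assert dm.d[u, v] == pytest.approx(expected, abs=1e-10)

    def test_gene_subset_restriction_and_errors(self):
        rng = np.random.default_rng(7)
        m = make_matrix("X", rng.lognormal(0, 1, size=(6, 4)))
        dm = sample_distance_matrix(m, gene_subset={"X_g0", "X_g3", "X_g5"})
        assert dm.n_units == 4
        with pytest.raises(ValueError, match="fewer than 2"):
            sample_distance_matrix(m, gene_subset={"X_g0"})

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SampleDistanceMatrix(["u", "v"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestHierarchicalDendrogram:
    def test_two_units_single_merge_at_their_distance(self):
        dm = SampleDistanceMatrix(["u", "v"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = hierarchical_dendrogram(dm)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(0.7)

    def test_equidistant_triple_ties_broken_lexicographically(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = SampleDistanceMatrix(["c", "a", "b"], d)
        tree = hierarchical_dendrogram(dm)
        # units are ordered lexicographically, so the first merge joins a and b
        assert tree.unit_ids == ["a", "b", "c"]
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_five_unit_tree_matches_manual_complete_linkage(self):
        # hand agglomeration: merge (P1,P2)@0.1; (P3,P4)@0.2;
        # P5 joins (P3,P4) at max(0.35,0.4)=0.4; final merge at max cross = 0.9
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.85, 0.9],
                [0.1, 0.0, 0.75, 0.8, 0.85],
                [0.8, 0.75, 0.0, 0.2, 0.35],
                [0.85, 0.8, 0.2, 0.0, 0.4],
                [0.9, 0.85, 0.35, 0.4, 0.0],
            ]
        )
        dm = SampleDistanceMatrix(["P1", "P2", "P3", "P4", "P5"], d)
        tree = hierarchical_dendrogram(dm, "complete")
        heights = tree.linkage[:, 2]
        np.testing.assert_allclose(heights, [0.1, 0.2, 0.4, 0.9])
        assert (np.diff(heights) >= 0).all()

    def test_newick_export_parses_and_preserves_leaves(self):
        rng = np.random.default_rng(2)
        dm = random_distance(rng)
        tree = hierarchical_dendrogram(dm)
        newick = tree.to_newick()
        import io

        from Bio import Phylo

        parsed = Phylo.read(io.StringIO(newick), "newick")
        leaves = sorted(t.name for t in parsed.get_terminals())
        assert leaves == sorted(map(str, dm.unit_ids))
        # root-to-leaf depth equals the tree height for an ultrametric tree
        depths = parsed.depths()
        leaf_depths = {t.name: h for t, h in depths.items() if t.name}
        assert np.allclose(list(leaf_depths.values()), tree.linkage[-1, 2], atol=1e-9)


class TestMantel:
    def test_identity_gives_statistic_one_and_exhaustive_floor(self):
        rng = np.random.default_rng(11)
        dm = random_distance(rng, n=5)
        res = mantel_test(dm, dm)
        assert res.statistic == pytest.approx(1.0)
        assert res.exhaustive and res.n_permutations == 120
        assert res.p == pytest.approx(1 / 120)

    def test_linear_transform_invariance(self):
        rng = np.random.default_rng(12)
        dm = random_distance(rng, n=5)
        d2 = 3.0 + 2.0 * dm.d
        np.fill_diagonal(d2, 0.0)
        # bypass the [0,2] bound of 1-r distances with a raw matrix
        from coexpair.dendro import _corr, _upper

        stat = _corr(_upper(dm.d), _upper(d2))
        assert stat == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(13)
        d1, d2 = random_distance(rng), random_distance(rng)
        r12 = mantel_test(d1, d2)
        r21 = mantel_test(d2, d1)
        assert r12.statistic == pytest.approx(r21.statistic)
        assert r12.p == pytest.approx(r21.p)

    def test_sampled_mode_agrees_with_skbio(self):
        """Independent oracle: scikit-bio's Mantel on the same matrices."""
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(14)
        d1 = random_distance(rng, n=8)
        d2 = random_distance(rng, n=8)
        ours = mantel_test(d1, d2, n_permutations=999, seed=1, exhaustive_limit=100)
        corr, p, _ = skbio_mantel(
            DistanceMatrix(d1.d, [str(u) for u in d1.unit_ids]),
            DistanceMatrix(d2.d, [str(u) for u in d2.unit_ids]),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.statistic == pytest.approx(corr, abs=1e-12)
        # both p estimates target the same tail probability
        se = 3 * math.sqrt(p * (1 - p) / 999)
        assert abs(ours.p - p) < max(0.02, se)

    def test_unit_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        d1 = random_distance(rng)
        d2 = SampleDistanceMatrix(["Q1", "Q2", "Q3", "Q4", "Q5"], d1.d.copy())
        with pytest.raises(ValueError, match="unit sets"):
            mantel_test(d1, d2)


class TestDendrogramEquivalence:
    def test_shared_factor_orders_units_identically(self):
        """One strong module whose latent factor dominates both tissues ->
        the two 5x5 distance matrices agree and p hits the exhaustive floor."""
        cfg = SimulationConfig(
            n_units=5, tissues=("EET", "CAR"), n_modules=1,
            genes_per_module_per_tissue=30, loading_range=(0.95, 1.0),
            negative_fraction=0.0, noise_sd=0.0, n_null_genes_per_tissue=0,
            subthreshold_fraction=0.0, log2_scale=True, seed=23,
        )
        study, truth = generate_paired_study(cfg)
        genes_a = set(truth[truth.tissue == "EET"].gene_id)
        genes_b = set(truth[truth.tissue == "CAR"].gene_id)
        equiv = dendrogram_equivalence(study, "EET", "CAR", genes_a, genes_b)
        assert equiv.mantel.exhaustive
        assert equiv.mantel.p == pytest.approx(1 / 120)
        assert equiv.mantel.statistic > 0.99
        assert equiv.cophenetic_r == pytest.approx(1.0, abs=1e-6)

    def test_cophenetic_one_for_identical_distances(self):
        rng = np.random.default_rng(16)
        dm = random_distance(rng)
        t1 = hierarchical_dendrogram(dm)
        t2 = hierarchical_dendrogram(dm)
        assert cophenetic_correlation(t1, t2) == pytest.approx(1.0)

    def test_null_gene_sets_give_non_extreme_p(self):
        cfg = SimulationConfig(
            n_units=5, tissues=("EET", "CAR"), n_modules=0,
            genes_per_module_per_tissue=0, n_null_genes_per_tissue=50,
            subthreshold_fraction=0.0, log2_scale=True, seed=24,
        )
        study, truth = generate_paired_study(cfg)
        equiv = dendrogram_equivalence(
            study, "EET", "CAR",
            set(study["EET"].gene_ids), set(study["CAR"].gene_ids),
        )
        assert 1 / 120 <= equiv.mantel.p <= 1.0
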