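import math

import numpy as np
import pytest

from coexpair.enrichment import (
    GeneSetCollection,
    bh_adjust,
    bootstrap_enrichment_validation,
    enrichment_test,
    read_gmt,
    write_gmt,
)


def collection(**sets):
    return GeneSetCollection({k: ("desc", tuple(v)) for k, v in sets.items()})


def genes(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = collection(S1=genes("a", 4), S2=genes("b", 2))
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tonly-description\n")
        with pytest.raises(ValueError, match="need id"):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            collection(S1=[])

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            collection(S1=["g1", "g1"])


class TestEnrichmentTest:
    def test_test_equals_background_gives_p_one(self):
        bg = set(genes("g", 30))
        coll = collection(S1=genes("g", 5), S2=genes("g", 30)[10:20])
        res = enrichment_test(bg, bg, coll)
        assert all(r.p == pytest.approx(1.0) for r in res)

    def test_hand_worked_hypergeometric_tail(self):
        # background 100, set 10, test 20, overlap 6:
        # p = sum_{x=6..10} C(10,x) C(90,20-x) / C(100,20)
        bg = set(genes("g", 100))
        members = genes("g", 10)
        test = set(genes("g", 100)[4:10]) | set(genes("g", 100)[80:94])
        coll = collection(S1=members)
        (res,) = enrichment_test(test, bg, coll)
        assert res.overlap == 6
        expected = sum(
            math.comb(10, x) * math.comb(90, 20 - x) for x in range(6, 11)
        ) / math.comb(100, 20)
        assert res.p == pytest.approx(expected, rel=1e-12)

    def test_matches_combinatorial_oracle_on_small_backgrounds(self):
        """Exhaustive check against the exact tail sum for N in a spread of
        background sizes, all set sizes, draw sizes and overlaps."""
        from scipy.stats import hypergeom

        for N in (2, 9, 23, 41, 60):
            comb = [[math.comb(a, b) for b in range(N + 1)] for a in range(N + 1)]
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    lo, hi = max(0, n + K - N), min(K, n)
                    ks = np.arange(lo, hi + 1)
                    exact = np.array(
                        [
                            sum(
                                comb[K][x] * comb[N - K][n - x]
                                for x in range(k, hi + 1)
                            )
                            / comb[N][n]
                            for k in ks
                        ]
                    )
                    got = hypergeom.sf(ks - 1, N, K, n)
                    assert np.abs(got - exact).max() < 1e-12, (N, K, n)

    def test_zero_overlap_p_is_one(self):
        bg = set(genes("g", 50))
        coll = collection(S1=genes("g", 50)[:10])
        res = enrichment_test(set(genes("g", 50)[40:45]), bg, coll)
        assert res[0].overlap == 0
        assert res[0].p == pytest.approx(1.0)

    def test_set_outside_background_skipped(self):
        bg = set(genes("g", 20))
        coll = collection(S1=genes("x", 5), S2=genes("g", 3))
        res = enrichment_test({"g000"}, bg, coll)
        assert [r.set_id for r in res] == ["S2"]

    def test_errors(self):
        bg = set(genes("g", 10))
        coll = collection(S1=genes("g", 3))
        with pytest.raises(ValueError, match="empty"):
            enrichment_test(set(), bg, coll)
        with pytest.raises(ValueError, match="absent"):
            enrichment_test({"zzz"}, bg, coll)

    def test_uniform_bias_weights_reduce_to_central(self):
        rng = np.random.default_rng(3)
        bg = set(genes("g", 60))
        coll = collection(S1=genes("g", 15), S2=genes("g", 60)[30:50])
        test = set(rng.choice(sorted(bg), 12, replace=False))
        plain = enrichment_test(test, bg, coll)
        weighted = enrichment_test(test, bg, coll, bias_weights={g: 2.5 for g in bg})
        for a, b in zip(plain, weighted):
            assert a.p == pytest.approx(b.p, abs=1e-9)

    def test_biased_weights_shift_p(self):
        bg = set(genes("g", 60))
        members = genes("g", 15)
        coll = collection(S1=members)
        test = set(members[:6])
        weights = {g: (5.0 if g in set(members) else 1.0) for g in bg}
        plain = enrichment_test(test, bg, coll)
        weighted = enrichment_test(test, bg, coll, bias_weights=weights)
        # overlap is less surprising when in-set genes are easier to sample
        assert weighted[0].p > plain[0].p


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.3, 0.3, 0.3])
        np.testing.assert_allclose(out, 0.3)

    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_textbook_formula_equivalence(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1, 25)
        out = bh_adjust(p)
        order = np.argsort(p)
        m = p.size
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            ks = np.arange(rank_pos, m)
            expected[idx] = min(
                1.0, (m * np.sort(p)[ks] / (ks + 1)).min()
            )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_vectorized_column_bh_matches_statsmodels(self):
        from coexpair.enrichment import _bh_columns

        rng = np.random.default_rng(9)
        p = rng.uniform(0.001, 1, size=(12, 7))
        cols = _bh_columns(p.copy())
        for c in range(7):
            np.testing.assert_allclose(cols[:, c], bh_adjust(p[:, c]), atol=1e-12)


class TestBootstrapValidation:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        bg = genes("g", 200)
        sets = {}
        for s in range(6):
            members = rng.choice(bg, size=30, replace=False)
            sets[f"S{s}"] = tuple(members)
        return set(bg), collection(**sets)

    def test_unbeatable_observation_gives_zero(self):
        bg, coll = self._fixture()
        test = set(coll.members("S0"))  # perfect overlap: smallest possible p
        res = enrichment_test(test, bg, coll)
        probs = bootstrap_enrichment_validation(res, len(test), bg, coll,
                                                rounds=100, seed=1)
        assert probs["S0"] == 0.0

    def test_observed_fdr_one_counts_strictly_lower_rounds(self):
        bg, coll = self._fixture()
        rng = np.random.default_rng(5)
        test = set(rng.choice(sorted(bg), 30, replace=False))
        res = enrichment_test(test, bg, coll)
        res_by = {r.set_id: r for r in res}
        target = max(res, key=lambda r: r.fdr)
        if target.fdr == 1.0:
            probs = bootstrap_enrichment_validation(res, 30, bg, coll,
                                                    rounds=100, seed=2)
            assert 0.0 <= probs[target.set_id] <= 1.0

    def test_probability_reflects_rank_of_observed_fdr(self):
        bg, coll = self._fixture(seed=3)
        # an enriched observation should rarely be beaten by random draws
        test = set(list(coll.members("S1"))[:20]) | set(sorted(bg)[:10])
        res = enrichment_test(test, bg, coll)
        probs = bootstrap_enrichment_validation(res, 30, bg, coll,
                                                rounds=200, seed=4)
        assert probs["S1"] < 0.05

    def test_rounds_and_size_validation(self):
        bg, coll = self._fixture()
        res = enrichment_test({"g000"}, bg, coll)
        with pytest.raises(ValueError, match="rounds"):
            bootstrap_enrichment_validation(res, 1, bg, coll, rounds=0)
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_enrichment_validation(res, 1000, bg, coll, rounds=10)
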