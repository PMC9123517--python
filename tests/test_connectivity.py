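"""Connectivity scoring: ES oracle equivalence, permutation calibration, ranking."""

import numpy as np
import pandas as pd
import pytest

from pvrsig.connectivity import (
    EnrichmentResult,
    enrichment_score,
    permutation_null,
    rank_drugs,
    score_drug,
)
from pvrsig.drugs import DrugProfile
from pvrsig.signature import GeneSet, RankedSignature

from oracles import es_bruteforce, ks_statistic


def make_ranked(scores, genes=None):
    if genes is None:
        genes = [f"g{i}" for i in range(len(scores))]
    return RankedSignature(genes, scores)


def make_drug(name, down, **kwargs):
    defaults = dict(
        drug_id=name, targets=frozenset(), organism="Humans",
        known_action="yes", groups=frozenset({"approved"}),
        down_genes=GeneSet(name, frozenset(down)),
    )
    defaults.update(kwargs)
    return DrugProfile(name=name, **defaults)


class TestEnrichmentScore:
    def test_top_hit_unweighted_is_one(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, _, leading = enrichment_score(ranked, GeneSet("s", frozenset({"g0"})), 0.0)
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_bottom_hit_unweighted_is_minus_one(self):
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, _, leading = enrichment_score(ranked, GeneSet("s", frozenset({"g3"})), 0.0)
        assert es == pytest.approx(-1.0)
        assert leading == ["g3"]

    def test_weighted_two_hit_example(self):
        """Scores (4,3,2,1), members {g0,g2}, weight 1: peak of the running sum is 2/3."""
        ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
        es, running, _ = enrichment_score(ranked, GeneSet("s", frozenset({"g0", "g2"})), 1.0)
        assert es == pytest.approx(2 / 3, abs=1e-12)
        assert running == pytest.approx([4 / 6, 4 / 6 - 1 / 2, 4 / 6 - 1 / 2 + 2 / 6, 0.0])

    @pytest.mark.parametrize("weight_exponent", [0.0, 1.0])
    def test_matches_bruteforce_oracle(self, rng, weight_exponent):
        for _ in range(200):
            n = int(rng.integers(3, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = frozenset(rng.choice(genes, size=k, replace=False))
            ranked = make_ranked(scores, genes)
            es, _, _ = enrichment_score(ranked, GeneSet("s", members), weight_exponent)
            expected = es_bruteforce(ranked.genes, ranked.scores, members, weight_exponent)
            assert es == pytest.approx(expected, abs=1e-12)

    def test_unweighted_equals_ks_statistic(self, rng):
        """With weight 0 the |ES| is the two-sample KS distance of hit vs miss ranks."""
        for _ in range(50):
            n = int(rng.integers(4, 40))
            genes = [f"g{i}" for i in range(n)]
            ranked = make_ranked(np.sort(rng.normal(size=n))[::-1], genes)
            k = int(rng.integers(1, n))
            members = frozenset(rng.choice(genes, size=k, replace=False))
            es, _, _ = enrichment_score(ranked, GeneSet("s", members), 0.0)
            hit_ranks = [ranked.rank_of(g) for g in members]
            miss_ranks = [i for i in range(n) if ranked.genes[i] not in members]
            assert abs(es) == pytest.approx(ks_statistic(hit_ranks, miss_ranks), abs=1e-12)

    def test_invariant_to_order_preserving_score_change(self):
        genes = list("abcdef")
        members = GeneSet("s", frozenset({"b", "e"}))
        es1, _, _ = enrichment_score(make_ranked([6, 5, 4, 3, 2, 1], genes), members, 0.0)
        es2, _, _ = enrichment_score(make_ranked([60, 50, 40, 30, 20, 10], genes), members, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_degenerate_memberships_rejected(self):
        ranked = make_ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="no gene-set member"):
            enrichment_score(ranked, GeneSet("s", frozenset({"zz"})))
        with pytest.raises(ValueError, match="entire ranking"):
            enrichment_score(ranked, GeneSet("s", frozenset({"g0", "g1", "g2"})))


class TestPermutationNull:
    def test_length_and_determinism(self):
        ranked = make_ranked(np.linspace(3, -3, 50))
        assert permutation_null(ranked, 5, n_perm=1, seed=0).shape == (1,)
        a = permutation_null(ranked, 5, n_perm=100, seed=7)
        b = permutation_null(ranked, 5, n_perm=100, seed=7)
        assert np.array_equal(a, b)

    def test_matches_single_set_scores(self, rng):
        """Null draws equal enrichment_score evaluated on the same random sets."""
        n = 40
        genes = [f"g{i}" for i in range(n)]
        ranked = make_ranked(np.sort(rng.normal(size=n))[::-1], genes)
        null = permutation_null(ranked, 6, n_perm=50, weight_exponent=1.0, seed=3)
        # recompute by brute force from the same seeded position draws
        check_rng = np.random.default_rng(3)
        pos = np.argpartition(check_rng.random((50, n)), 5, axis=1)[:, :6]
        for es_val, row in zip(null, pos):
            members = frozenset(genes[i] for i in row)
            expected = es_bruteforce(ranked.genes, ranked.scores, members, 1.0)
            assert es_val == pytest.approx(expected, abs=1e-12)

    def test_sign_symmetry_on_random_scores(self, rng):
        """On an effect-free ranking the null ES is positive about half the time."""
        scores = np.sort(rng.normal(size=2000))[::-1]
        ranked = make_ranked(scores)
        null = permutation_null(ranked, 30, n_perm=2000, seed=11)
        assert 0.4 <= (null > 0).mean() <= 0.6

    def test_set_size_bounds(self):
        ranked = make_ranked([2.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            permutation_null(ranked, 0, n_perm=10, seed=0)
        with pytest.raises(ValueError):
            permutation_null(ranked, 3, n_perm=10, seed=0)


class TestScoreDrug:
    def test_missing_genes_silently_dropped(self, rng):
        ranked = make_ranked(np.linspace(2, -2, 30))
        drug = make_drug("d", ["g0", "g5", "not-a-gene"])
        res = score_drug(ranked, drug, n_perm=50, seed=0)
        assert res.set_size == 2

    def test_empty_intersection_flagged_unscorable(self):
        ranked = make_ranked(np.linspace(2, -2, 10))
        drug = make_drug("d", ["absent1", "absent2"])
        with pytest.warns(UserWarning, match="unscorable"):
            res = score_drug(ranked, drug, n_perm=50, seed=0)
        assert not res.scorable

    def test_bottom_concentrated_set_negative_es(self):
        ranked = make_ranked(np.linspace(2, -2, 100))
        drug = make_drug("d", [f"g{i}" for i in range(90, 100)])
        res = score_drug(ranked, drug, n_perm=100, seed=0)
        assert res.es < 0

    def test_p_honors_permutation_lower_bound(self, rng):
        ranked = make_ranked(np.linspace(3, -3, 200))
        drug = make_drug("top", [f"g{i}" for i in range(10)])
        n_perm = 40
        res = score_drug(ranked, drug, n_perm=n_perm, seed=1)
        assert res.p >= 1 / (n_perm + 1)

    def test_planted_signal_recovered(self, rng):
        """A down-set inside the top-50 of a 1000-gene ranking scores NES>1, p<0.05."""
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1] + np.linspace(3, 0, n)
        ranked = make_ranked(scores, genes)
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            down = local.choice(genes[:50], size=30, replace=False)
            res = score_drug(ranked, make_drug("planted", down), n_perm=500, seed=seed)
            if res.nes > 1 and res.p < 0.05:
                hits += 1
        assert hits >= 19

    def test_type_one_error_calibrated(self, rng):
        """Random down-sets on a random ranking give uniform p (quick check)."""
        n = 500
        genes = [f"g{i}" for i in range(n)]
        ranked = make_ranked(np.sort(rng.normal(size=n))[::-1], genes)
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            local = np.random.default_rng(10_000 + seed)
            down = local.choice(genes, size=20, replace=False)
            res = score_drug(ranked, make_drug("d", down), n_perm=200, seed=seed)
            if res.p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09


class TestRankDrugs:
    def result(self, name, nes, p=0.01, es=0.5):
        return EnrichmentResult(name, es, nes, p, None, 10, [])

    def test_reported_nes_ordering(self):
        """NES 1.58/1.37/1.31/1.27 order aminocaproic acid before the TOP2A inhibitors."""
        results = [
            self.result("doxorubicin", 1.31, p=0.015),
            self.result("aminocaproic acid", 1.58, p=0.0001),
            self.result("etoposide", 1.27, p=0.017),
            self.result("mitoxantrone", 1.37, p=0.005),
        ]
        table = rank_drugs(results)
        assert table["drug"].tolist() == [
            "aminocaproic acid", "mitoxantrone", "doxorubicin", "etoposide",
        ]

    def test_single_result_padj_equals_p(self):
        table = rank_drugs([self.result("only", 1.2, p=0.03)])
        assert table.loc[0, "padj"] == pytest.approx(0.03)

    def test_equal_nes_tie_broken_by_padj_then_name(self):
        results = [
            self.result("zeta", 1.0, p=0.04),
            self.result("alpha", 1.0, p=0.04),
            self.result("beta", 1.0, p=0.01),
        ]
        table = rank_drugs(results)
        assert table["drug"].tolist() == ["beta", "alpha", "zeta"]

    def test_unscorable_excluded(self):
        bad = EnrichmentResult("bad", np.nan, np.nan, np.nan, None, 0, [], scorable=False)
        table = rank_drugs([self.result("ok", 1.1), bad])
        assert table["drug"].tolist() == ["ok"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_drugs([])

    def test_padj_is_bh_over_scorable(self):
        results = [self.result(f"d{i}", 1.0 + i / 10, p=p)
                   for i, p in enumerate([0.01, 0.02, 0.03])]
        table = rank_drugs(results)
        assert sorted(table["padj"]) == pytest.approx([0.03, 0.03, 0.03])
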