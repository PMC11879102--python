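"""Running-sum enrichment, ETS, permutation null, NETS and pooled FDR."""

from fractions import Fraction  # noqa: F401 - used by the exact oracles

import numpy as np
import pytest

from cmtarget.connectivity import (
    NullStore,
    RankedQuery,
    enrichment_score,
    ets,
    fdr,
    nets,
    p_value,
    permutation_null,
    score_query,
)
from cmtarget.signatures import TargetGeneSignature


def es_oracle(hit_ranks: set[int], n_total: int) -> float:
    """Exact-rational brute-force prefix-sum enumeration of the running sum."""
    h = len(hit_ranks)
    s = Fraction(0)
    prefix = [s]
    for i in range(n_total):
        s += Fraction(1, h) if i in hit_ranks else -Fraction(1, n_total - h)
        prefix.append(s)
    es_pos, es_neg = max(prefix), min(prefix)
    return float(es_pos) if es_pos >= -es_neg else float(es_neg)


def query_of(n: int) -> RankedQuery:
    return RankedQuery(
        "q", [f"g{i}" for i in range(n)], np.arange(n, 0, -1, dtype=float)
    )


class TestEnrichmentScore:
    def test_set_at_top_scores_one(self, toy_query):
        assert enrichment_score(toy_query, ["g01", "g02", "g03"]) == 1.0

    def test_set_at_bottom_scores_minus_one(self, toy_query):
        assert enrichment_score(toy_query, ["g08", "g09", "g10"]) == -1.0

    def test_matches_prefix_sum_oracle_on_spread_hits(self, toy_query):
        # hits at ranks 1, 4 and 9 (1-based)
        observed = enrichment_score(toy_query, ["g01", "g04", "g09"])
        assert observed == pytest.approx(es_oracle({0, 3, 8}, 10), abs=1e-12)

    def test_no_overlap_scores_zero(self, toy_query):
        assert enrichment_score(toy_query, ["absent"]) == 0.0

    def test_bounded_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            G = int(rng.integers(5, 60))
            q = query_of(G)
            k = int(rng.integers(1, G))
            S = [f"g{i}" for i in rng.choice(G, size=k, replace=False)]
            assert abs(enrichment_score(q, S)) <= 1.0


class TestEts:
    def test_extremal_signature_scores_one(self, toy_query):
        sig = TargetGeneSignature("T", ["g01", "g02"], ["g09", "g10"], 2)
        assert ets(toy_query, sig) == 1.0

    def test_same_sign_sides_score_zero(self, toy_query):
        # both sides crowd the top of the list: ES_up > 0 and ES_down > 0
        sig = TargetGeneSignature("T", ["g01", "g02"], ["g03", "g04"], 2)
        assert ets(toy_query, sig) == 0.0

    def test_matches_composed_oracle_on_toy_signature(self):
        q = query_of(20)
        up, down = ["g0", "g5", "g11"], ["g15", "g18", "g19"]
        es_up = es_oracle({0, 5, 11}, 20)
        es_dn = es_oracle({15, 18, 19}, 20)
        expected = 0.0 if es_up * es_dn > 0 else (es_up - es_dn) / 2
        assert ets(q, TargetGeneSignature("T", up, down, 3)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_side_contributes_zero(self, toy_query):
        sig = TargetGeneSignature("T", ["g01", "g02"], ["x1", "x2"], 2)
        # ES_down = 0, ES_up = 1 -> ETS = 0.5
        assert ets(toy_query, sig) == pytest.approx(0.5)

    @staticmethod
    def _has_magnitude_tie(hit_ranks: set[int], n_total: int) -> bool:
        """True when the two running-sum extrema tie in exact arithmetic."""
        h = len(hit_ranks)
        s = Fraction(0)
        prefix = [s]
        for i in range(n_total):
            s += Fraction(1, h) if i in hit_ranks else -Fraction(1, n_total - h)
            prefix.append(s)
        return max(prefix) == -min(prefix)

    def test_antisymmetric_under_reversal_or_swap(self):
        # reversing the ranking flips the sign; so does swapping the sides;
        # doing both restores the original score (tie-free inputs: an exact
        # magnitude tie resolves positive on both sides of the identity)
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 50:
            G = int(rng.integers(10, 80))
            q = query_of(G)
            reverse = RankedQuery(
                "r", q.gene_ids[::-1], np.arange(G, 0, -1, dtype=float)
            )
            pick = rng.choice(G, size=6, replace=False)
            if any(
                self._has_magnitude_tie(s, G)
                for s in (set(pick[:3].tolist()), set(pick[3:].tolist()),
                          {G - 1 - i for i in pick[:3].tolist()},
                          {G - 1 - i for i in pick[3:].tolist()})
            ):
                continue
            up = [f"g{i}" for i in pick[:3]]
            down = [f"g{i}" for i in pick[3:]]
            sig = TargetGeneSignature("T", up, down, 3)
            swapped = TargetGeneSignature("T", down, up, 3)
            fwd = ets(q, sig)
            assert ets(reverse, sig) == pytest.approx(-fwd, abs=1e-9)
            assert ets(q, swapped) == pytest.approx(-fwd, abs=1e-9)
            assert ets(reverse, swapped) == pytest.approx(fwd, abs=1e-9)
            checked += 1


class TestPermutationNull:
    def test_seeded_determinism(self, toy_query):
        sig = TargetGeneSignature("T", ["g01", "g04"], ["g07", "g10"], 2)
        a = permutation_null(toy_query, sig, n_perm=100, seed=42)
        b = permutation_null(toy_query, sig, n_perm=100, seed=42)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 100

    def test_null_mean_is_centred(self):
        q = query_of(200)
        pick = np.random.default_rng(2).choice(200, size=20, replace=False)
        sig = TargetGeneSignature(
            "T", [f"g{i}" for i in pick[:10]], [f"g{i}" for i in pick[10:]], 10
        )
        null = permutation_null(q, sig, n_perm=1000, seed=0)
        se = null.std() / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se

    def test_rejects_nonpositive_count(self, toy_query):
        sig = TargetGeneSignature("T", ["g01"], ["g10"], 1)
        with pytest.raises(ValueError):
            permutation_null(toy_query, sig, n_perm=0)


class TestPValue:
    def test_counts_same_sign_portion(self):
        assert p_value(0.3, [0.5, 0.3, -0.2, 0.1]) == pytest.approx(2 / 3)

    def test_negative_branch(self):
        assert p_value(-0.4, [-0.5, -0.1, 0.2]) == pytest.approx(1 / 2)

    def test_floor_prevents_zero(self):
        assert p_value(0.9, [0.5, 0.3, -0.2, 0.1]) == pytest.approx(1 / 3)

    def test_empty_portion_gives_one(self):
        assert p_value(0.5, [-0.1, -0.2]) == 1.0

    def test_zero_score_gets_conventional_one(self):
        assert p_value(0.0, [0.5, -0.5, 0.1]) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            p_value(0.5, [])


class TestNets:
    def test_self_normalization(self):
        assert nets(0.2, [0.1, 0.2, 0.3, -0.4]) == pytest.approx(1.0)

    def test_positive_division(self):
        assert nets(0.6, [0.1, 0.2, 0.3, -0.9]) == pytest.approx(3.0)

    def test_sign_preserving_division(self):
        assert nets(-0.6, [-0.1, -0.2, -0.3, 0.9]) == pytest.approx(-3.0)

    def test_zero_score_and_empty_portion(self):
        assert nets(0.0, [0.5, -0.5]) == 0.0
        assert nets(0.4, [-0.1, -0.2]) == 0.0

    def test_sign_matches_ets_on_random_inputs(self):
        rng = np.random.default_rng(3)
        null = rng.normal(size=500)
        for _ in range(100):
            actual = float(rng.normal())
            assert np.sign(nets(actual, null)) == np.sign(actual)


class TestFdr:
    @pytest.fixture
    def toy_store(self):
        return NullStore(
            null_ets={},
            actual_nets=np.sort([3.0, 1.0, -2.0]),
            pooled_null_nets=np.sort([2.0, 1.0, -1.0, -2.0, 0.5, -0.5]),
        )

    def test_score_beyond_every_null_has_fdr_zero(self, toy_store):
        assert fdr(toy_store, 3.0) == 0.0

    def test_exhaustive_counting_on_toy_store(self, toy_store):
        # nets 1: A = #{null >= 1}/#{null >= 0} = 2/3, B = #{actual >= 1}/
        # #{actual >= 0} = 2/2 -> FDR = 2/3
        assert fdr(toy_store, 1.0) == pytest.approx(2 / 3)

    def test_ratio_clipped_at_one(self):
        store = NullStore(
            null_ets={},
            actual_nets=np.sort([5.0, 0.5]),
            pooled_null_nets=np.sort([1.0, 0.9, 0.8, -1.0]),
        )
        assert fdr(store, 0.5) == 1.0

    def test_zero_nets_flagged_as_one(self, toy_store):
        assert fdr(toy_store, 0.0) == 1.0

    def test_monotone_in_magnitude_per_sign(self):
        rng = np.random.default_rng(4)
        actual = rng.normal(size=50)
        store = NullStore(
            null_ets={},
            actual_nets=np.sort(actual),
            pooled_null_nets=np.sort(rng.normal(size=2000)),
        )
        pos = np.sort(actual[actual > 0])
        fdrs = [fdr(store, x) for x in pos]
        assert all(a >= b - 1e-12 for a, b in zip(fdrs, fdrs[1:]))
        neg = np.sort(actual[actual < 0])[::-1]
        fdrs = [fdr(store, x) for x in neg]
        assert all(a >= b - 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestScoreQuery:
    def test_single_signature_pools_its_own_null(self, toy_query):
        sig = TargetGeneSignature("T", ["g01", "g02"], ["g09", "g10"], 2)
        results = score_query(toy_query, [sig], n_perm=200, seed=0)
        assert len(results) == 1
        r = results[0]
        assert r.ets == 1.0
        assert 0 < r.p <= 1
        assert 0 <= r.fdr <= 1

    def test_deterministic_for_fixed_seed(self, small_library):
        _config, _sigs, truth, library, _profiles = small_library
        from cmtarget.simulate import generate_query

        q = generate_query(truth, [("T1", +1)], seed=9)
        a = score_query(q, library, n_perm=100, seed=21)
        b = score_query(q, library, n_perm=100, seed=21)
        assert [(r.target_id, r.ets, r.p, r.nets, r.fdr) for r in a] == [
            (r.target_id, r.ets, r.p, r.nets, r.fdr) for r in b
        ]

    def test_planted_target_attains_largest_nets(self, small_scored):
        truth, _query, results = small_scored
        assert results[0].target_id == "T1"
        assert results[0].fdr <= 0.05
        nets_by_id = {r.target_id: r.nets for r in results}
        # the reversed planted target sits at the negative extreme
        assert nets_by_id["T2"] == min(nets_by_id.values())

    def test_results_sorted_by_nets_descending(self, small_scored):
        _truth, _query, results = small_scored
        nets_seq = [r.nets for r in results]
        assert nets_seq == sorted(nets_seq, reverse=True)

    def test_empty_library_rejected(self, toy_query):
        with pytest.raises(ValueError):
            score_query(toy_query, [], n_perm=10, seed=0)

    def test_disjoint_universe_rejected(self, toy_query):
        sig = TargetGeneSignature("T", ["x1"], ["x2"], 1)
        with pytest.raises(ValueError, match="overlap"):
            score_query(toy_query, [sig], n_perm=10, seed=0)
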