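import itertools

import numpy as np
import pytest

from adlseq import vector_from_runs
from adlseq.metrics import (AdjacencyRelation, CompressedActivitySequence,
                            DistanceMatrix, TransitionModel, build_adjacency,
                            compress, diff_generalized, diff_sensor,
                            diff_simple, estimate_transitions, hamming,
                            levenshtein, pairwise_matrix, sim_hamming,
                            sim_levenshtein)
from conftest import A, B, C, day_from_labels, random_activity_day

fs = frozenset


# ---------------------------------------------------------------------------
# per-slot difference functions
# ---------------------------------------------------------------------------

class TestDiffSensor:
    @pytest.mark.parametrize("si,qi,eps,expected", [
        ({"M1"}, {"M1"}, 0.7, 0),          # identical: 2 > 1.4
        ({"M1"}, {"M2"}, 0.0, 1),          # disjoint never matches
        ({"M1"}, {"M2"}, 1.0, 1),
        ({"M1", "M2"}, {"M1"}, 0.7, 1),    # 2 > 2.1 fails
        ({"M1", "M2"}, {"M1"}, 0.5, 0),    # 2 > 1.5 holds
        (set(), set(), 0.7, 0),            # two idle slots match
        (set(), {"M1"}, 0.0, 1),
    ])
    def test_epsilon_matching(self, si, qi, eps, expected):
        assert diff_sensor(fs(si), fs(qi), eps) == expected

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff_sensor(fs({"M1"}), fs({"M1"}), 1.5)

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(11)
        sensors = [f"M{i}" for i in range(5)]
        for _ in range(100):
            si = fs(rng.choice(sensors, size=rng.integers(0, 4), replace=False))
            qi = fs(rng.choice(sensors, size=rng.integers(0, 4), replace=False))
            vals = [diff_sensor(si, qi, e) for e in np.linspace(0, 1, 11)]
            assert vals == sorted(vals)  # non-decreasing in epsilon


class TestDiffActivities:
    def test_simple_is_set_equality(self):
        assert diff_simple(fs({A}), fs({A})) == 0
        assert diff_simple(fs({A}), fs({A, B})) == 1
        assert diff_simple(fs({A, B}), fs({B, A})) == 0

    def test_generalized_adjacent_pair_costs_cost(self):
        adj = AdjacencyRelation.from_pairs([("meal preparation", "eating")])
        assert diff_generalized(fs({"meal preparation"}), fs({"eating"}), adj, 0.5) == 0.5

    def test_generalized_concurrent_case(self):
        adj = AdjacencyRelation.from_pairs([(C, B)])
        assert diff_generalized(fs({A, C}), fs({B}), adj, 0.3) == 0.3

    def test_generalized_no_adjacency_costs_one(self):
        adj = AdjacencyRelation(frozenset())
        assert diff_generalized(fs({A, C}), fs({B, "x"}), adj, 0.3) == 1.0

    def test_shared_member_literal_vs_overlap_flag(self):
        adj = AdjacencyRelation(frozenset())
        assert diff_generalized(fs({A, B}), fs({A}), adj, 0.5) == 1.0
        assert diff_generalized(fs({A, B}), fs({A}), adj, 0.5, overlap_is_match=True) == 0.0

    def test_invalid_set_sizes_rejected(self):
        adj = AdjacencyRelation(frozenset())
        with pytest.raises(ValueError):
            diff_generalized(fs(), fs({A}), adj)
        with pytest.raises(ValueError):
            diff_generalized(fs({A, B, C}), fs({A}), adj)

    def test_transition_model_uses_min_cost_among_holding_pairs(self):
        model = TransitionModel({(A, B): 3, (B, A): 1, (C, B): 1},
                                {A: 3, B: 1, C: 1})
        # A~B cost 1-0.5*1-0.5*1=0... compute: p(B|A)=1, p(A|B)=1 -> 0
        # C~B: p(B|C)=1, p(C|B)=0 -> 0.5
        d = diff_generalized(fs({A, C}), fs({B}), None, model)
        assert d == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# adjacency / transitions / compression
# ---------------------------------------------------------------------------

class TestAdjacencyAndTransitions:
    def test_single_transition(self):
        day = day_from_labels([A, A, B, B])
        adj = build_adjacency([day])
        assert adj.adjacent(A, B) and adj.adjacent(B, A)
        assert len(adj) == 1

    def test_constant_day_has_no_adjacency(self):
        assert len(build_adjacency([day_from_labels([A] * 4)])) == 0

    def test_symmetric_and_deduplicated(self):
        days = [day_from_labels([A, B]), day_from_labels([B, A], 1)]
        assert len(build_adjacency(days)) == 1

    def test_transition_probabilities_and_cost(self):
        # pooled: C(A->B)=3 of C(A)=6, C(B->A)=1 of C(B)=4
        model = TransitionModel({(A, B): 3, (A, C): 3, (B, A): 1, (B, C): 3},
                                {A: 6, B: 4})
        assert model.prob(B, A) == pytest.approx(0.5)
        assert model.prob(A, B) == pytest.approx(0.25)
        assert model.cost(A, B) == pytest.approx(0.625)

    def test_reciprocal_always_costs_zero(self):
        days = [day_from_labels([A, B, A, B])]
        model = estimate_transitions(days)
        assert model.cost(A, B) == pytest.approx(0.0)

    def test_unobserved_pair_costs_one(self):
        model = estimate_transitions([day_from_labels([A, B])])
        assert model.cost(A, C) == pytest.approx(1.0)

    def test_concurrent_transition_counts_only_changes(self):
        # {A} -> {A, B}: only A->B counts (A persists)
        day = day_from_labels([{A}, {A, B}])
        model = estimate_transitions([day])
        assert model.counts == {(A, B): 1}

    def test_compress_merges_runs(self):
        assert compress(day_from_labels([A, A, A])).elements == (fs({A}),)
        assert compress(day_from_labels([A, A, B, A])).elements == \
            (fs({A}), fs({B}), fs({A}))
        assert compress(day_from_labels([{A}, {A, B}, {A, B}, {B}])).elements == \
            (fs({A}), fs({A, B}), fs({B}))


# ---------------------------------------------------------------------------
# Hamming family
# ---------------------------------------------------------------------------

class TestHamming:
    def test_identity_and_full_mismatch(self):
        a = day_from_labels([A, B, A, B])
        b = day_from_labels([C, C, C, C], 1)
        assert hamming(a, a, diff_simple) == 0
        assert hamming(a, b, diff_simple) == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming(day_from_labels([A]), day_from_labels([A, B]), diff_simple)

    def test_five_percent_mismatch_of_full_day(self):
        n = 86_400
        k = n // 20
        ref = vector_from_runs(0, [({A}, n)])
        other = vector_from_runs(1, [({B}, k), ({A}, n - k)])
        assert hamming(ref, other, diff_simple) == 4320

    def test_similarity_scale(self):
        a = day_from_labels([A, A, B, B])
        b = day_from_labels([A, A, C, C], 1)
        assert sim_hamming(a, a) == 1.0
        assert sim_hamming(a, b) == pytest.approx(0.5)
        assert sim_hamming(a, b, H=hamming(a, b, diff_simple)) == pytest.approx(0.5)


@pytest.fixture(scope="module")
def random_days():
    rng = np.random.default_rng(2)
    return [random_activity_day(rng, n=120, day_index=i) for i in range(12)]


class TestHammingProperties:
    """Randomized invariants of the Hamming family (seeded)."""

    def test_symmetry_identity_and_dominance(self, random_days):
        days = random_days
        adj = build_adjacency(days)
        model = estimate_transitions(days)
        checked = 0
        for a, b in itertools.combinations(days, 2):
            h1 = hamming(a, b, diff_simple)
            h2 = hamming(a, b, lambda x, y: diff_generalized(x, y, adj, 0.5))
            h3 = hamming(a, b, lambda x, y: diff_generalized(x, y, None, model))
            assert h1 == hamming(b, a, diff_simple)
            assert h2 == pytest.approx(
                hamming(b, a, lambda x, y: diff_generalized(x, y, adj, 0.5)))
            assert h3 == pytest.approx(
                hamming(b, a, lambda x, y: diff_generalized(x, y, None, model)))
            assert h2 <= h1 + 1e-9 and h3 <= h1 + 1e-9
            assert 0.0 <= sim_hamming(a, b, H=h1) <= 1.0
            checked += 1
        assert checked >= 60
        for d in days:
            assert hamming(d, d, diff_simple) == 0

    def test_diff_values_in_unit_interval(self, random_days):
        days = random_days
        model = estimate_transitions(days)
        seen = {s for d in days for s in set(d.slots.tolist())}
        for x, y in itertools.product(seen, repeat=2):
            assert 0.0 <= diff_generalized(x, y, None, model) <= 1.0


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

def oracle_levenshtein(x, y, ci=1.0, cd=1.0, cs=2.0):
    """Independent minimum over all monotone alignments.

    Matched element pairs cost 0 if equal else min(cs, cd+ci); unmatched
    x elements cost cd, unmatched y elements ci.  Exhaustive over all
    order-preserving matchings — tractable for tiny sequences only.
    """
    best = np.inf
    nx, ny = len(x), len(y)
    for k in range(min(nx, ny) + 1):
        for xi in itertools.combinations(range(nx), k):
            for yi in itertools.combinations(range(ny), k):
                cost = (nx - k) * cd + (ny - k) * ci
                cost += sum(0.0 if x[i] == y[j] else min(cs, cd + ci)
                            for i, j in zip(xi, yi))
                best = min(best, cost)
    return best


class TestLevenshtein:
    def test_identity_and_base_cases(self):
        x = compress(day_from_labels([A, B, A]))
        assert levenshtein(x, x) == 0
        empty = CompressedActivitySequence(0, ())
        y = compress(day_from_labels([A, B]))
        assert levenshtein(empty, y) == 2          # |y|*costI
        assert levenshtein(y, empty) == 2          # |x|*costD

    def test_swap_beats_double_substitution(self):
        x = compress(day_from_labels([A, B]))
        y = compress(day_from_labels([B, A]))
        assert levenshtein(x, y, 1, 1, 2) == 2     # delete A, insert A

    def test_set_elements_compare_as_sets(self):
        x = CompressedActivitySequence(0, (fs({A, B}),))
        y = CompressedActivitySequence(1, (fs({B, A}),))
        assert levenshtein(x, y) == 0

    def test_matches_alignment_oracle_exhaustively(self):
        alphabet = [fs({A}), fs({B}), fs({C})]
        seqs = []
        for n in range(5):
            for combo in itertools.product(range(3), repeat=n):
                if all(a != b for a, b in zip(combo, combo[1:])):
                    seqs.append(tuple(alphabet[i] for i in combo))
        assert len(seqs) > 40
        for x in seqs:
            for y in seqs:
                assert levenshtein(x, y) == pytest.approx(oracle_levenshtein(x, y))

    def test_triangle_inequality_on_random_instances(self):
        rng = np.random.default_rng(5)
        alphabet = [fs({A}), fs({B}), fs({C}), fs({A, B})]
        for _ in range(100):
            seqs = []
            for _s in range(3):
                n = int(rng.integers(0, 7))
                seqs.append(tuple(alphabet[int(i)] for i in rng.integers(0, 4, n)))
            x, y, z = seqs
            assert levenshtein(x, z) <= levenshtein(x, y) + levenshtein(y, z) + 1e-9

    def test_similarity(self):
        empty = CompressedActivitySequence(0, ())
        y = compress(day_from_labels([A, B]))
        assert sim_levenshtein(empty, y) == 0.0
        assert sim_levenshtein(empty, empty) == 1.0
        x4 = compress(day_from_labels([A, B, A, B]))
        assert sim_levenshtein(x4, x4, L=2.0) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# pairwise matrices
# ---------------------------------------------------------------------------

class TestPairwiseMatrix:
    def test_identical_days_zero_matrix(self):
        a = day_from_labels([A, B], 0)
        b = day_from_labels([A, B], 1)
        D = pairwise_matrix([a, b], "H1")
        assert np.array_equal(D.matrix, np.zeros((2, 2)))

    def test_symmetry_and_metadata(self):
        rng = np.random.default_rng(3)
        days = [random_activity_day(rng, n=60, day_index=i) for i in range(3)]
        D = pairwise_matrix(days, "H2", cost=0.4)
        assert np.array_equal(D.matrix, D.matrix.T)
        assert D.params["cost"] == 0.4

    def test_h3_dominated_by_h1(self):
        rng = np.random.default_rng(4)
        days = [random_activity_day(rng, n=100, day_index=i) for i in range(5)]
        d1 = pairwise_matrix(days, "H1").matrix
        d3 = pairwise_matrix(days, "H3").matrix
        assert (d3 <= d1 + 1e-9).all()

    def test_mixed_lengths_rejected_for_hamming(self):
        with pytest.raises(ValueError):
            pairwise_matrix([day_from_labels([A]), day_from_labels([A, B], 1)], "H1")

    def test_levenshtein_metric_ignores_durations(self):
        a = day_from_labels([A, A, A, B], 0)
        b = day_from_labels([A, B, B, B], 1)
        D = pairwise_matrix([a, b], "LEV")
        assert D.matrix[0, 1] == 0.0

    def test_sensor_metric_uses_epsilon(self):
        a = vector_from_runs(0, [({"M1", "M2"}, 4)], kind="sensor")
        b = vector_from_runs(1, [({"M1"}, 4)], kind="sensor")
        assert pairwise_matrix([a, b], "SENSOR", epsilon=0.5).matrix[0, 1] == 0
        assert pairwise_matrix([a, b], "SENSOR", epsilon=0.7).matrix[0, 1] == 4

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        days = [random_activity_day(rng, n=50, day_index=i) for i in range(3)]
        D = pairwise_matrix(days, "H2", cost=0.25)
        p = tmp_path / "dist.tsv"
        D.to_tsv(p)
        back = DistanceMatrix.from_tsv(p)
        assert back.metric == "H2"
        assert back.params["cost"] == 0.25
        np.testing.assert_allclose(back.matrix, D.matrix)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix((0, 1), np.array([[0.0, 1.0], [2.0, 0.0]]), "bad")
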