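"""EM association model: triplets, theta estimation, E scores.

The brute-force oracle here reimplements the whole EM (responsibilities,
M/K/Z bookkeeping, pinned reruns, ratio sums) with plain dict/loop Python,
independently of the vectorized implementation under test.
"""

import math

import numpy as np
import pytest

from domap.annotation_io import AnnotationCorpus
from domap.em_core import (
    EmConfig,
    ThetaMatrix,
    build_triplets,
    compute_e_scores,
    em_iterate,
    initialize_theta,
    log_likelihood,
    run_em,
)

EPS = 1e-12


# ---------------------------------------------------------------- oracle ----

def oracle_em(corpus, iterations, pinned=None):
    """Pure-python EM: returns theta dict after `iterations` iterations."""
    shared = sorted(corpus.shared_proteins())
    a_of = {}  # protein -> set of pairs
    for p in shared:
        a_of[p] = {
            (d, g)
            for d in corpus.protein_domains[p]
            for g in corpus.protein_go[p]
            if g not in corpus.roots
        }
    pairs = sorted({pr for s in a_of.values() for pr in s})
    dom_count, go_count = {}, {}
    for p in shared:
        for d in corpus.protein_domains[p]:
            dom_count[d] = dom_count.get(d, 0) + 1
        for g in corpus.protein_go[p]:
            go_count[g] = go_count.get(g, 0) + 1
    n = {pr: sum(1 for p in shared if pr in a_of[p]) for pr in pairs}
    z = {(d, g): (dom_count[d] - n[(d, g)]) + (go_count[g] - n[(d, g)]) for d, g in pairs}
    theta = {pr: n[pr] / (n[pr] + z[pr]) for pr in pairs}
    if pinned:
        theta[pinned] = 0.0
    for _ in range(iterations):
        if pinned:
            theta[pinned] = 0.0
        m = {pr: 0.0 for pr in pairs}
        for p in shared:
            prod = 1.0
            for pr in a_of[p]:
                prod *= 1.0 - theta[pr]
            denom = max(1.0 - prod, EPS)
            for pr in a_of[p]:
                m[pr] += min(1.0, theta[pr] / denom)
        theta = {pr: m[pr] / (m[pr] + (n[pr] - m[pr]) + z[pr]) for pr in pairs}
        if pinned:
            theta[pinned] = 0.0
    return theta, a_of, n, z


def oracle_e_score(corpus, pair, em_iterations, e_iterations):
    """Independent ratio-sum recomputation of the leave-one-out evidence."""
    theta_full, a_of, _, _ = oracle_em(corpus, em_iterations)
    theta_bar, _, _, _ = oracle_em(corpus, e_iterations, pinned=pair)
    total = 0.0
    for p, pairs in a_of.items():
        if pair not in pairs:
            continue
        num = 1.0
        den = 1.0
        for pr in pairs:
            num *= 1.0 - theta_full[pr]
            den *= 1.0 - theta_bar[pr]
        total += math.log(max(1.0 - num, EPS) / max(1.0 - den, EPS))
    return total


# --------------------------------------------------------------- fixtures ---

def exclusive_pair_corpus(z):
    """One co-annotated pair plus z proteins carrying only one side."""
    pd_map = {"p0": {"d1"}}
    pg_map = {"p0": {"g1"}}
    for i in range(z):
        pd_map[f"x{i}"] = {"d1"}
        pg_map[f"x{i}"] = {"gz"}
    return AnnotationCorpus(pd_map, pg_map)


@pytest.fixture()
def three_pair_corpus():
    """Three competing pairs sharing proteins, asymmetric support."""
    pd_map = {
        "p1": {"d1", "d2"},
        "p2": {"d1"},
        "p3": {"d1", "d2"},
        "p4": {"d2"},
        "p5": {"d1"},
    }
    pg_map = {
        "p1": {"g1"},
        "p2": {"g1"},
        "p3": {"g2"},
        "p4": {"g2"},
        "p5": {"g2"},
    }
    return AnnotationCorpus(pd_map, pg_map)


# ----------------------------------------------------------------- tests ----

class TestBuildTriplets:
    def test_singleton(self):
        corpus = AnnotationCorpus({"p": {"d"}}, {"p": {"g"}})
        trips = build_triplets(corpus)
        assert trips.triplets == [("d", "p", "g")]
        assert trips.per_protein_pairs() == {"p": {("d", "g")}}

    def test_cartesian_product_per_protein(self):
        corpus = AnnotationCorpus({"p": {"d1", "d2"}}, {"p": {"g1", "g2", "g3"}})
        trips = build_triplets(corpus)
        assert len(trips) == 6
        assert len(trips.per_protein_pairs()["p"]) == 6

    def test_matches_exhaustive_enumeration(self, synthetic_truth):
        corpus = synthetic_truth.corpus
        trips = build_triplets(corpus)
        expected = set()
        for p in corpus.shared_proteins():
            for d in corpus.protein_domains[p]:
                for g in corpus.protein_go[p]:
                    if g not in corpus.roots:
                        expected.add((d, p, g))
        assert set(trips.triplets) == expected

    def test_restriction_limits_pairs(self, three_pair_corpus):
        from domap.mapping_core import build_initial_mappings, filter_mappings

        table = build_initial_mappings(three_pair_corpus)
        top = filter_mappings(table, s_min=0.5, n_min=1)
        trips = build_triplets(three_pair_corpus, restrict_to=top)
        assert set(trips.pairs) == top.pairs


class TestInitializeTheta:
    def test_direct_arithmetic(self):
        pd_map = {"p1": {"d"}, "p2": {"d"}, "p3": {"d"}, "p4": {"dx"}}
        pg_map = {"p1": {"gx"}, "p2": {"g"}, "p3": {"g"}, "p4": {"g"}}
        corpus = AnnotationCorpus(pd_map, pg_map)
        trips = build_triplets(corpus)
        mat = initialize_theta(trips, corpus)
        # d on {p1,p2,p3}, g on {p2,p3,p4}: M = |{p2,p3}| = 2, Z = 1 + 1
        m, k, z = mat.counts[("d", "g")]
        assert (m, k, z) == (2, 0, 2)
        assert mat.theta[("d", "g")] == pytest.approx(0.5)

    def test_identical_protein_sets_give_theta_one(self):
        corpus = AnnotationCorpus(
            {"p1": {"d"}, "p2": {"d"}}, {"p1": {"g"}, "p2": {"g"}}
        )
        trips = build_triplets(corpus)
        mat = initialize_theta(trips, corpus)
        assert mat.theta[("d", "g")] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_theta_init_equals_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        pd_map, pg_map = {}, {}
        for i in range(40):
            pd_map[f"p{i}"] = {f"d{j}" for j in rng.choice(6, rng.integers(1, 3), replace=False)}
            pg_map[f"p{i}"] = {f"g{j}" for j in rng.choice(8, rng.integers(1, 4), replace=False)}
        corpus = AnnotationCorpus(pd_map, pg_map)
        trips = build_triplets(corpus)
        mat = initialize_theta(trips, corpus)
        for (d, g), theta in mat.theta.items():
            dp = {p for p in pd_map if d in pd_map[p]}
            gp = {p for p in pg_map if g in pg_map[p]}
            jaccard = len(dp & gp) / len(dp | gp)
            assert theta == pytest.approx(jaccard, abs=1e-12)


class TestLogLikelihood:
    def test_hand_value_single_pair(self):
        mat = ThetaMatrix(
            pairs=[("d", "g")],
            theta_arr=np.array([0.5]),
            m_arr=np.array([1.0]),
            k_arr=np.array([0.0]),
            z_arr=np.array([1.0]),
            n_arr=np.array([1.0]),
        )
        assert log_likelihood(mat, EmConfig()) == pytest.approx(2 * math.log(0.5))

    def test_saturated_maximum_is_zero(self):
        mat = ThetaMatrix(
            pairs=[("d", "g")],
            theta_arr=np.array([1.0]),
            m_arr=np.array([3.0]),
            k_arr=np.array([0.0]),
            z_arr=np.array([0.0]),
            n_arr=np.array([3.0]),
        )
        assert log_likelihood(mat, EmConfig()) == pytest.approx(0.0)

    def test_five_pair_hand_sum(self):
        thetas = [0.1, 0.3, 0.5, 0.7, 0.9]
        ms = [1.0, 2.0, 3.0, 4.0, 5.0]
        zs = [2.0, 1.0, 0.0, 1.0, 2.0]
        mat = ThetaMatrix(
            pairs=[(f"d{i}", "g") for i in range(5)],
            theta_arr=np.array(thetas),
            m_arr=np.array(ms),
            k_arr=np.zeros(5),
            z_arr=np.array(zs),
            n_arr=np.array(ms),
        )
        expected = sum(
            m * math.log(t) + z * math.log(1 - t)
            for t, m, z in zip(thetas, ms, zs)
        )
        assert log_likelihood(mat, EmConfig()) == pytest.approx(expected)

    def test_pseudocounts_enter_exponents(self):
        mat = ThetaMatrix(
            pairs=[("d", "g")],
            theta_arr=np.array([0.5]),
            m_arr=np.array([1.0]),
            k_arr=np.array([0.0]),
            z_arr=np.array([1.0]),
            n_arr=np.array([1.0]),
        )
        cfg = EmConfig(alpha=1.0, beta=2.0)
        # exponents: (M + alpha) = 2 and (K + Z + beta) = 3
        assert log_likelihood(mat, cfg) == pytest.approx(5 * math.log(0.5))


class TestEmIterate:
    def test_sole_pair_responsibility_is_one(self):
        corpus = exclusive_pair_corpus(0)
        trips = build_triplets(corpus)
        mat = initialize_theta(trips, corpus)
        em_iterate(mat, trips, EmConfig())
        assert mat.theta[("d1", "g1")] == 1.0

    @pytest.mark.parametrize("z", [0, 1, 2, 3, 5])
    def test_fixed_point_one_over_one_plus_z(self, z):
        corpus = exclusive_pair_corpus(z)
        trips = build_triplets(corpus)
        mat = initialize_theta(trips, corpus)
        em_iterate(mat, trips, EmConfig())
        assert mat.theta[("d1", "g1")] == pytest.approx(1 / (1 + z), abs=1e-15)
        em_iterate(mat, trips, EmConfig())  # stable thereafter
        assert mat.theta[("d1", "g1")] == pytest.approx(1 / (1 + z), abs=1e-15)

    def test_pinned_pair_stays_zero(self, three_pair_corpus):
        trips = build_triplets(three_pair_corpus)
        mat = initialize_theta(trips, three_pair_corpus)
        pin = ("d1", "g1")
        for _ in range(3):
            em_iterate(mat, trips, EmConfig(), pinned_zero=pin)
            assert mat.theta[pin] == 0.0

    def test_m_plus_k_conserved(self, three_pair_corpus):
        trips = build_triplets(three_pair_corpus)
        mat = initialize_theta(trips, three_pair_corpus)
        for _ in range(5):
            em_iterate(mat, trips, EmConfig())
            assert np.allclose(mat.m_arr + mat.k_arr, mat.n_arr, atol=1e-12)
            assert ((mat.theta_arr >= 0) & (mat.theta_arr <= 1)).all()


class TestRunEm:
    def test_exclusive_pairs_saturate_in_one_iteration(self):
        corpus = AnnotationCorpus(
            {"p1": {"d1"}, "p2": {"d2"}}, {"p1": {"g1"}, "p2": {"g2"}}
        )
        mat = run_em(build_triplets(corpus), corpus)
        assert mat.theta[("d1", "g1")] == 1.0
        assert mat.theta[("d2", "g2")] == 1.0

    def test_asymmetric_competition_orders_theta(self, three_pair_corpus):
        # d1-g1 has exclusive support on p2; d2-g1 only shares p1 with it
        mat = run_em(build_triplets(three_pair_corpus), three_pair_corpus)
        assert mat.theta[("d1", "g1")] > mat.theta[("d2", "g1")]

    @pytest.mark.parametrize("seed", range(3))
    def test_trace_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        pd_map, pg_map = {}, {}
        for i in range(30):
            pd_map[f"p{i}"] = {f"d{j}" for j in rng.choice(5, rng.integers(1, 3), replace=False)}
            pg_map[f"p{i}"] = {f"g{j}" for j in rng.choice(6, rng.integers(1, 3), replace=False)}
        corpus = AnnotationCorpus(pd_map, pg_map)
        mat = run_em(build_triplets(corpus), corpus)
        trace = mat.log_likelihood_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_matches_oracle_em(self, three_pair_corpus):
        trips = build_triplets(three_pair_corpus)
        mat = run_em(trips, three_pair_corpus, fixed_iterations=15)
        oracle, _, _, _ = oracle_em(three_pair_corpus, 15)
        for pair, theta in oracle.items():
            assert mat.theta[pair] == pytest.approx(theta, abs=1e-12)


class TestEScores:
    def test_uncontested_pair_is_capped_at_log_theta_over_eps(self):
        corpus = exclusive_pair_corpus(3)
        trips = build_triplets(corpus)
        cfg = EmConfig()
        mat = run_em(trips, corpus, cfg)
        ev = compute_e_scores(mat, trips, corpus, cfg, pairs=[("d1", "g1")])
        assert ("d1", "g1") in ev.capped
        theta = mat.theta[("d1", "g1")]
        assert ev[("d1", "g1")] == pytest.approx(math.log(theta / cfg.epsilon))

    def test_matches_brute_force_oracle_on_three_pair_fixture(self, three_pair_corpus):
        trips = build_triplets(three_pair_corpus)
        cfg = EmConfig(max_iterations=20, rel_tolerance=1e-14)
        mat = run_em(trips, three_pair_corpus, cfg, fixed_iterations=20)
        ev = compute_e_scores(mat, trips, three_pair_corpus, cfg)
        for pair in trips.pairs:
            expected = oracle_e_score(three_pair_corpus, pair, 20, cfg.e_score_iterations)
            assert ev[pair] == pytest.approx(expected, abs=1e-9)

    def test_higher_exclusive_support_gives_higher_evidence(self, three_pair_corpus):
        trips = build_triplets(three_pair_corpus)
        mat = run_em(trips, three_pair_corpus)
        ev = compute_e_scores(mat, trips, three_pair_corpus)
        assert ev[("d1", "g1")] > ev[("d2", "g1")]
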