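"""Gaussian score, clusters, selection schemes, injection, Hopkins."""

import itertools
import math

import numpy as np
import pytest

import rnatopo as rt
from rnatopo.errors import (
    CapacityError,
    DomainError,
    EmptyMapError,
    InsufficientPointsError,
    RequestTooLargeError,
)

from conftest import random_contact_map, reference_omega


def cmap_of(pairs, L=60, min_sep=1):
    return rt.ContactMap(L=L, contacts=frozenset(pairs), min_sep=min_sep)


class TestGaussScore:
    def test_single_contact_is_self_term_only(self):
        w = rt.gauss_weights(cmap_of({(1, 10)}))
        assert w.nu[0] == pytest.approx(1.0)
        assert w.omega[0] == pytest.approx(1.0)
        assert rt.gauss_score(cmap_of({(1, 10)})) == pytest.approx(1.0)

    def test_two_contacts_at_index_distance_two(self):
        # nu = 1 + e^-1 for both contacts, omega = 1/(1 + e^-1)
        w = rt.gauss_weights(cmap_of({(2, 10), (2, 12)}))
        np.testing.assert_allclose(w.nu, 1.0 + math.exp(-1.0))
        np.testing.assert_allclose(w.omega, 0.7310585786, atol=1e-9)
        assert rt.gauss_score(cmap_of({(2, 10), (2, 12)})) == pytest.approx(
            2.0 / (1.0 + math.exp(-1.0)), abs=1e-12
        )

    def test_distant_contacts_have_unit_weight(self):
        w = rt.gauss_weights(cmap_of({(1, 10), (30, 55)}))
        np.testing.assert_allclose(w.omega, 1.0, atol=1e-8)

    def test_isolation_limit_omega_approaches_count(self):
        pairs = {(1, 30), (10, 55), (25, 58), (2, 50)}
        assert rt.gauss_score(cmap_of(pairs)) == pytest.approx(4.0, abs=1e-8)

    def test_empty_map_raises(self):
        with pytest.raises(EmptyMapError):
            rt.gauss_score_positions(np.empty((0, 2)))

    def test_normalized_score_divides_by_length(self):
        cmap = cmap_of({(1, 30), (10, 55)})
        assert rt.normalized_gauss_score(cmap) == pytest.approx(
            rt.gauss_score(cmap) / cmap.L
        )

    def test_two_point_closed_form_is_increasing_in_distance(self):
        values = [
            rt.gauss_score_positions(np.array([[0.0, 0.0], [d, 0.0]]), sigma2=4.0)
            for d in np.arange(0.5, 10.5, 0.5)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_bounds_and_translation_invariance_on_random_maps(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            cmap = random_contact_map(rng)
            omega = rt.gauss_score(cmap)
            assert 1.0 - 1e-9 <= omega <= len(cmap) + 1e-9
            pts = cmap.positions()
            shifted = rt.gauss_score_positions(pts + np.array([3.0, 7.0]))
            assert shifted == pytest.approx(omega, abs=1e-9)

    def test_matches_independent_scalar_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            cmap = random_contact_map(rng, max_contacts=15)
            assert rt.gauss_score(cmap) == pytest.approx(
                reference_omega(cmap.contacts), abs=1e-10
            )


class TestSoftGaussScore:
    def test_binary_map_reduces_to_hard_score(self):
        pairs = {(1, 10), (3, 12), (20, 40)}
        wmap = rt.WeightedContactMap(L=60, weights={p: 1.0 for p in pairs})
        assert rt.soft_gauss_score(wmap) == pytest.approx(
            rt.gauss_score(cmap_of(pairs)), abs=1e-12
        )

    def test_all_zero_map_scores_zero(self):
        wmap = rt.WeightedContactMap(L=60, weights={(1, 10): 0.0})
        assert rt.soft_gauss_score(wmap) == 0.0

    def test_half_weight_pair_hand_evaluation(self):
        wmap = rt.WeightedContactMap(L=60, weights={(2, 10): 0.5, (2, 12): 0.5})
        expected = 2 * 0.5 / (0.5 + 0.5 * math.exp(-1.0))
        assert rt.soft_gauss_score(wmap) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(DomainError):
            rt.WeightedContactMap(L=60, weights={(1, 10): 1.5})


class TestFindClusters:
    def test_mutually_adjacent_cells_form_one_cluster(self):
        part = rt.find_clusters(cmap_of({(1, 10), (1, 11), (2, 10)}))
        assert part.sizes() == [3]

    def test_far_apart_contacts_are_singletons(self):
        part = rt.find_clusters(cmap_of({(1, 10), (5, 20)}))
        assert part.sizes() == [1, 1]

    def test_diagonal_adjacency_only_under_8_connectivity(self):
        pairs = {(1, 10), (2, 11)}
        assert rt.find_clusters(cmap_of(pairs), adjacency=8).sizes() == [2]
        assert rt.find_clusters(cmap_of(pairs), adjacency=4).sizes() == [1, 1]

    def test_matches_exhaustive_path_search_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        cmap = random_contact_map(rng, L=80, max_contacts=200)
        for adjacency, limit in ((8, 1), (4, None)):
            graph = nx.Graph()
            graph.add_nodes_from(cmap.contacts)
            for a, b in itertools.combinations(cmap.contacts, 2):
                di, dj = abs(a[0] - b[0]), abs(a[1] - b[1])
                adjacent = (
                    max(di, dj) == 1 if adjacency == 8 else di + dj == 1
                )
                if adjacent:
                    graph.add_edge(a, b)
            expected = {frozenset(c) for c in nx.connected_components(graph)}
            got = set(rt.find_clusters(cmap, adjacency=adjacency).clusters)
            assert got == expected


class TestSelectClustered:
    def test_n_equals_largest_cluster_takes_it_whole(self, two_cluster_map):
        sel = rt.select_clustered(two_cluster_map, n=5, seed=0)
        largest = rt.find_clusters(two_cluster_map).clusters[0]
        assert sel.chosen == largest

    def test_overflow_moves_to_next_cluster_in_size_order(self, two_cluster_map):
        sel = rt.select_clustered(two_cluster_map, n=6, seed=0)
        first, second = rt.find_clusters(two_cluster_map).clusters
        assert len(sel.chosen & first) == 5
        assert len(sel.chosen & second) == 1

    def test_full_request_returns_entire_map(self, two_cluster_map):
        sel = rt.select_clustered(two_cluster_map, n=len(two_cluster_map), seed=0)
        assert sel.chosen == two_cluster_map.contacts

    def test_oversized_request_rejected(self, two_cluster_map):
        with pytest.raises(RequestTooLargeError):
            rt.select_clustered(two_cluster_map, n=len(two_cluster_map) + 1, seed=0)


class TestSelectRandom:
    def test_full_request_returns_entire_map(self, two_cluster_map):
        sel = rt.select_random(two_cluster_map, n=len(two_cluster_map), seed=1)
        assert sel.chosen == two_cluster_map.contacts

    def test_same_seed_is_deterministic(self, planted_map):
        a = rt.select_random(planted_map, n=20, seed=42)
        b = rt.select_random(planted_map, n=20, seed=42)
        assert a.chosen == b.chosen

    def test_mean_omega_exceeds_clustered_selection(self, two_cluster_map):
        clustered = rt.gauss_score(
            rt.select_clustered(two_cluster_map, n=5, seed=0).as_contact_map()
        )
        random_scores = [
            rt.gauss_score(
                rt.select_random(two_cluster_map, n=5, seed=s).as_contact_map()
            )
            for s in range(200)
        ]
        assert np.mean(random_scores) > clustered


class TestSelectGaussOptimized:
    def test_single_contact_scores_one(self, two_cluster_map):
        sel = rt.select_gauss_optimized(two_cluster_map, n=1)
        assert len(sel) == 1
        assert rt.gauss_score(sel.as_contact_map()) == pytest.approx(1.0)

    def test_picks_exhaustive_optimal_pair(self):
        cmap = cmap_of({(1, 10), (1, 12), (1, 30)})
        sel = rt.select_gauss_optimized(cmap, n=2)
        assert sel.chosen == {(1, 10), (1, 30)}

    def test_output_is_single_swap_locally_optimal(self, planted_map):
        sel = rt.select_gauss_optimized(planted_map, n=15)
        omega = reference_omega(sel.chosen)
        unchosen = planted_map.contacts - sel.chosen
        for drop in sel.chosen:
            for add in unchosen:
                swapped = (sel.chosen - {drop}) | {add}
                assert reference_omega(swapped) <= omega + 1e-9

    def test_scheme_ordering_of_mean_omega(self, planted_map):
        n = 20
        gauss = rt.gauss_score(
            rt.select_gauss_optimized(planted_map, n=n).as_contact_map()
        )
        rand_scores, clus_scores = [], []
        for seed in range(30):
            rand_scores.append(
                rt.gauss_score(rt.select_random(planted_map, n=n, seed=seed).as_contact_map())
            )
            clus_scores.append(
                rt.gauss_score(rt.select_clustered(planted_map, n=n, seed=seed).as_contact_map())
            )
        assert gauss >= np.mean(rand_scores) > np.mean(clus_scores)


class TestInjectFalseContacts:
    def test_zero_lambda_leaves_selection_unchanged(self, planted_map):
        base = rt.select_random(planted_map, n=10, seed=0)
        assert rt.inject_false_contacts(planted_map, base, 0.0, seed=1) is base

    def test_counts_solve_lambda_equation_exactly(self, planted_map):
        base = rt.select_random(planted_map, n=10, seed=0)
        sel = rt.inject_false_contacts(planted_map, base, 1.0 / 3.0, seed=1)
        assert len(sel.false_set) == 5
        assert sel.error_rate == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_false_set_never_overlaps_native(self, planted_map):
        base = rt.select_random(planted_map, n=12, seed=3)
        for lam in (0.1, 0.25, 0.5):
            sel = rt.inject_false_contacts(planted_map, base, lam, seed=7)
            assert not (sel.false_set & planted_map.contacts)
            assert all(j - i >= planted_map.min_sep for i, j in sel.false_set)

    def test_lambda_out_of_domain_rejected(self, planted_map):
        base = rt.select_random(planted_map, n=5, seed=0)
        for lam in (-0.1, 1.0, 1.5):
            with pytest.raises(DomainError):
                rt.inject_false_contacts(planted_map, base, lam, seed=0)

    def test_capacity_error_when_domain_is_saturated(self):
        # L=10, min_sep=4: 21 admissible pairs, 20 native -> 1 free slot
        domain = [(i, j) for i in range(1, 7) for j in range(i + 4, 11)]
        cmap = rt.ContactMap(L=10, contacts=frozenset(domain[:-1]), min_sep=4)
        base = rt.select_random(cmap, n=len(cmap), seed=0)
        with pytest.raises(CapacityError):
            rt.inject_false_contacts(cmap, base, 0.5, seed=0)


class TestHopkinsStatistic:
    def test_uniform_points_score_near_half(self):
        L, min_sep = 120, 4
        values = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pts = []
            while len(pts) < 200:
                x = rng.uniform(1, L, 2)
                if x[1] - x[0] >= min_sep:
                    pts.append(x)
            values.append(
                rt.hopkins_statistic(np.array(pts), L=L, min_sep=min_sep, seed=seed)
            )
        assert np.mean(values) == pytest.approx(0.5, abs=0.05)

    def test_tight_patch_scores_high(self):
        patch = np.array(
            [(50 + a, 150 + b) for a in range(3) for b in range(3)], dtype=float
        )
        assert rt.hopkins_statistic(patch, L=200, min_sep=4, seed=3) > 0.9

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientPointsError):
            rt.hopkins_statistic(np.array([[5.0, 20.0]]), L=50)

    def test_hopkins_scheme_ordering(self, planted_map):
        n = 40
        h = {}
        h["clustered"] = rt.hopkins_statistic(
            rt.select_clustered(planted_map, n=n, seed=0), seed=0
        )
        h["random"] = rt.hopkins_statistic(
            rt.select_random(planted_map, n=n, seed=0), seed=0
        )
        h["gauss"] = rt.hopkins_statistic(
            rt.select_gauss_optimized(planted_map, n=n), seed=0
        )
        assert h["clustered"] > h["random"] > h["gauss"]


class TestSelectionSerialization:
    def test_round_trip_preserves_labels_and_metadata(self, planted_map):
        base = rt.select_random(planted_map, n=10, seed=4)
        sel = rt.inject_false_contacts(planted_map, base, 0.25, seed=5)
        text = rt.write_selection(sel)
        again = rt.read_selection(text, native=planted_map)
        assert again.chosen == sel.chosen
        assert again.true_set == sel.true_set
        assert again.false_set == sel.false_set
        assert again.scheme == sel.scheme
        assert again.error_rate == pytest.approx(sel.error_rate)
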