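"""Correlation screen, network construction, topology, nulls and hubs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizonet.datatypes import ValidationError
from rhizonet.network import (
    build_network,
    correlation_screen,
    hub_shift,
    null_ensemble,
    top_hubs,
    topology,
)
from rhizonet.simulate import generate_community

from conftest import make_table


class TestCorrelationScreen:
    def test_duplicated_taxon_perfectly_correlated(self, rng):
        x = rng.integers(1, 50, size=(10, 1))
        t = make_table(np.hstack([x, x, rng.integers(1, 50, size=(10, 1))]))
        rho, p, _ = correlation_screen(t)
        assert rho.loc["t0", "t1"] == pytest.approx(1.0, abs=1e-12)
        assert p.loc["t0", "t1"] < 1e-8

    def test_independent_taxa_centred_on_zero(self, rng):
        t = make_table(rng.integers(0, 100, size=(100, 20)))
        rho, _, _ = correlation_screen(t)
        off = rho.to_numpy()[np.triu_indices(20, 1)]
        assert abs(off.mean()) < 0.05

    def test_zero_variance_taxa_excluded(self, rng):
        counts = rng.integers(1, 50, size=(8, 4)).astype(float)
        counts[:, 2] = 5.0
        rho, _, dropped = correlation_screen(make_table(counts))
        assert dropped == ["t2"]
        assert "t2" not in rho.index

    def test_fewer_than_four_samples_rejected(self, rng):
        with pytest.raises(ValidationError, match="4 samples"):
            correlation_screen(make_table(rng.integers(0, 9, size=(3, 4))))

    def test_spearman_p_tracks_exact_enumeration_at_n6(self, rng):
        """t-approximation vs full 6! rank-permutation null; the
        approximation is documented accurate to 0.08 absolute at n = 6."""
        t = make_table(rng.integers(0, 100, size=(6, 2)))
        rho, p, _ = correlation_screen(t)
        rx = stats.rankdata(t.counts["t0"])
        ry = stats.rankdata(t.counts["t1"])
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = sum(
            abs(np.corrcoef(rx, np.take(ry, perm))[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(range(6)))
        exact = hits / 720
        assert p.loc["t0", "t1"] == pytest.approx(exact, abs=0.08)


class TestBuildNetwork:
    def _frames(self, rho, p, taxa):
        return (pd.DataFrame(rho, index=taxa, columns=taxa),
                pd.DataFrame(p, index=taxa, columns=taxa))

    def test_all_p_one_gives_empty_network(self):
        taxa = ["a", "b", "c"]
        rho, p = self._frames(np.eye(3), np.ones((3, 3)), taxa)
        net = build_network(rho, p)
        assert net.n_edges == 0 and net.n_nodes == 0  # isolated dropped

    def test_single_significant_pair(self):
        taxa = ["a", "b", "c"]
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = 1e-5
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = -0.9
        net = build_network(*self._frames(rho, p, taxa))
        assert net.n_edges == 1
        assert net.graph["a"]["b"]["sign"] == -1

    def test_raising_alpha_never_removes_edges(self, rng):
        t, _ = generate_community(n_samples=20, n_taxa=15, coupling=1.0, seed=4)
        rho, p, _ = correlation_screen(t)
        strict = build_network(rho, p, edge_alpha=0.01)
        loose = build_network(rho, p, edge_alpha=0.10)
        assert set(map(frozenset, strict.graph.edges())) <= \
            set(map(frozenset, loose.graph.edges()))

    def test_degree_sum_is_twice_edge_count(self, rng):
        t, _ = generate_community(n_samples=15, n_taxa=20, coupling=1.5, seed=9)
        rho, p, _ = correlation_screen(t)
        net = build_network(rho, p, edge_alpha=0.05)
        assert sum(dict(net.graph.degree()).values()) == 2 * net.n_edges

    def test_planted_modules_have_denser_within_edges(self):
        t, truth = generate_community(n_samples=50, n_taxa=30, n_modules=2,
                                      coupling=3.0, seed=6, unstructured_frac=0.0)
        rho, p, _ = correlation_screen(t)
        net = build_network(rho, p, edge_alpha=0.01)
        within = between = 0
        for u, v in net.graph.edges():
            if truth.module_of[u] == truth.module_of[v]:
                within += 1
            else:
                between += 1
        n_half = 15
        within_pairs = 2 * (n_half * (n_half - 1) / 2)
        between_pairs = n_half * n_half
        assert within / within_pairs > between / between_pairs

    def test_misaligned_matrices_rejected(self):
        rho = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        p = pd.DataFrame(np.eye(2), index=["a", "c"], columns=["a", "c"])
        with pytest.raises(ValidationError, match="misaligned"):
            build_network(rho, p)


def _brute_force_betweenness(g):
    """Independent oracle: enumerate all shortest paths per pair."""
    bet = dict.fromkeys(g.nodes(), 0.0)
    for s, t in itertools.combinations(g.nodes(), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for path in paths:
            for interior in path[1:-1]:
                bet[interior] += 1.0 / len(paths)
    return bet


def _brute_force_apl(g):
    dists = []
    for s, t in itertools.combinations(g.nodes(), 2):
        if nx.has_path(g, s, t):
            dists.append(nx.shortest_path_length(g, s, t))
    return float(np.mean(dists)) if dists else float("nan")


class TestTopology:
    def test_star_graph_closed_forms(self):
        g = nx.star_graph(4)  # centre 0, four leaves
        m = topology(g)
        assert m.degree[0] == 4
        assert all(m.degree[i] == 1 for i in range(1, 5))
        assert m.betweenness[0] == 6.0  # all C(4,2) leaf pairs route via centre
        assert m.average_path_length == pytest.approx((4 * 1 + 6 * 2) / 10)

    def test_complete_graph_clustering_and_path_length(self):
        m = topology(nx.complete_graph(4))
        assert m.clustering_coefficient == 1.0
        assert m.average_path_length == 1.0

    def test_empty_graph_metrics_undefined(self):
        m = topology(nx.Graph())
        assert np.isnan(m.average_path_length)
        assert np.isnan(m.modularity)

    def test_random_graphs_match_path_enumeration_oracle(self, rng):
        for _ in range(10):
            g = nx.gnm_random_graph(10, int(rng.integers(8, 20)),
                                    seed=int(rng.integers(0, 10_000)))
            m = topology(g)
            oracle_bet = _brute_force_betweenness(g)
            for v in g.nodes():
                assert m.betweenness[v] == pytest.approx(oracle_bet[v], abs=1e-9)
            apl = _brute_force_apl(g)
            if np.isnan(apl):
                assert np.isnan(m.average_path_length)
            else:
                assert m.average_path_length == pytest.approx(apl, abs=1e-12)
            assert sum(m.degree) == 2 * g.number_of_edges()


class TestNullEnsemble:
    def test_every_null_graph_has_observed_n_and_m(self, monkeypatch):
        seen = []
        real = nx.gnm_random_graph

        def spy(n, m, seed=None):
            g = real(n, m, seed=seed)
            seen.append((g.number_of_nodes(), g.number_of_edges()))
            return g

        monkeypatch.setattr(nx, "gnm_random_graph", spy)
        g = nx.gnm_random_graph(15, 30, seed=1)
        seen.clear()
        null_ensemble(g, n_graphs=99, seed=2, metrics=("clustering_coefficient",))
        assert seen and all(nm == (15, 30) for nm in seen)

    def test_two_disjoint_cliques_flag_extreme_clustering(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        res = null_ensemble(g, n_graphs=199, seed=0,
                            metrics=("clustering_coefficient",))
        assert res.observed["clustering_coefficient"] == 1.0
        assert res.p_values["clustering_coefficient"] == pytest.approx(2 / 200)
        assert res.non_random

    def test_undersized_ensemble_rejected(self):
        with pytest.raises(ValidationError, match="≥ 99"):
            null_ensemble(nx.complete_graph(5), n_graphs=10)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError, match="unknown metrics"):
            null_ensemble(nx.complete_graph(5), n_graphs=99, metrics=("diameter",))


class TestHubs:
    def test_star_centre_is_the_single_hub(self):
        assert top_hubs(nx.star_graph(6), k=1) == [0]

    def test_all_equal_degrees_use_documented_tie_order(self):
        g = nx.cycle_graph(["a", "b", "c", "d", "e"])
        assert top_hubs(g, k=2) == ["a", "b"]  # betweenness ties too → label order

    def test_hub_set_matches_degree_sort_oracle(self, rng):
        g = nx.gnm_random_graph(30, 90, seed=17)
        k = 10
        hubs = top_hubs(g, k=k)
        degrees = sorted((d for _, d in g.degree()), reverse=True)
        hub_degrees = sorted((g.degree(v) for v in hubs), reverse=True)
        assert hub_degrees == degrees[:k]

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValidationError):
            top_hubs(nx.path_graph(3), k=10)


class TestHubShift:
    def test_identical_lists_all_maintained(self):
        hubs = [f"g{i}" for i in range(10)]
        s = hub_shift(hubs, list(hubs))
        assert s.counts() == {"maintained": 10, "lost": 0, "gained": 0, "k": 10}

    def test_disjoint_lists_full_turnover(self):
        s = hub_shift([f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)])
        assert len(s.maintained) == 0 and len(s.lost) == 10 and len(s.gained) == 10

    def test_single_shared_hub_pattern(self):
        # the one-maintained / nine-replaced shape seen in amended rhizoplanes
        untreated = [f"u{i}" for i in range(9)] + ["shared"]
        treated = [f"t{i}" for i in range(9)] + ["shared"]
        s = hub_shift(untreated, treated)
        assert s.maintained == {"shared"}
        assert len(s.lost) == 9 and len(s.gained) == 9

    def test_set_algebra_identities_on_random_lists(self, rng):
        pool = [f"g{i}" for i in range(25)]
        for _ in range(200):
            u = list(rng.choice(pool, size=10, replace=False))
            t = list(rng.choice(pool, size=10, replace=False))
            s = hub_shift(u, t)
            assert len(s.maintained) + len(s.lost) == 10
            assert len(s.maintained) + len(s.gained) == 10
            assert not (s.maintained & s.lost or s.maintained & s.gained)

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            hub_shift(["a", "a", "b"], ["c", "d", "e"])
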