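"""Module detection, module-trait association, Mantel and shift classes."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from rhizonet.datatypes import ValidationError
from rhizonet.modules import (
    AssociationMatrix,
    associate,
    classify_shift,
    detect_modules,
    mantel,
    match_modules,
    module_profile,
    module_profiles,
)
from rhizonet.simulate import generate_community

from conftest import make_table


class TestDetectModules:
    def test_two_disjoint_cliques_give_two_modules(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = detect_modules(g, seed=0)
        assert part.n_modules == 2
        assert {frozenset(part.members(1)), frozenset(part.members(2))} == \
            {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_edge_behaviour_frozen(self):
        # pinned: Louvain puts both endpoints of a lone edge in one module
        part = detect_modules(nx.Graph([("a", "b")]), seed=0)
        assert part.n_modules == 1
        assert part.members(1) == ["a", "b"]

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(30, 60, seed=3)
        assert detect_modules(g, seed=5).module_of == \
            detect_modules(g, seed=5).module_of

    def test_modules_ranked_by_size(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(7))
        part = detect_modules(g, seed=0)
        assert part.sizes[1] == 7 and part.sizes[2] == 3

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            detect_modules(nx.Graph(), seed=0)


class TestModuleProfile:
    def _table_and_partition(self, rng, counts=None):
        counts = counts if counts is not None else rng.integers(1, 60, size=(10, 4))
        t = make_table(counts)
        part = detect_modules(nx.complete_graph(["t0", "t1"]), seed=0)
        return t, part

    def test_one_taxon_module_profile_is_its_zscore(self, rng):
        t = make_table(rng.integers(1, 60, size=(10, 3)))
        g = nx.Graph()
        g.add_edge("t0", "t1")  # one 2-taxon module
        part = detect_modules(g, seed=0)
        # build a 1-member module artificially
        part.module_of = {"t2": 1}
        part.sizes = {1: 1}
        prof = module_profile(t, part, 1)
        rel = t.relative_abundance()["t2"]
        z = (rel - rel.mean()) / rel.std(ddof=1)
        assert np.allclose(prof.to_numpy(), z.to_numpy())

    def test_perfectly_correlated_members_profile_tracks_either(self, rng):
        base = rng.integers(10, 60, size=(12, 1)).astype(float)
        counts = np.hstack([base, base * 2, rng.integers(10, 60, size=(12, 1))])
        t, part = self._table_and_partition(rng, counts)
        prof = module_profile(t, part, 1)
        rel = t.relative_abundance()
        assert abs(np.corrcoef(prof, rel["t0"])[0, 1]) > 0.99

    def test_missing_module_rejected(self, rng):
        t, part = self._table_and_partition(rng)
        with pytest.raises(ValidationError, match="no taxa"):
            module_profile(t, part, 99)


class TestAssociate:
    def _profiles(self, rng, n=12):
        return pd.DataFrame({"M1": rng.normal(size=n), "M2": rng.normal(size=n)},
                            index=[f"u{i}" for i in range(n)])

    def test_exact_copy_trait_is_significant_rho_one(self, rng):
        prof = self._profiles(rng)
        traits = pd.DataFrame({"copy": prof["M1"]}, index=prof.index)
        am = associate(prof, traits, alpha=0.01)
        assert am.rho.loc["M1", "copy"] == pytest.approx(1.0)
        assert am.significant.loc["M1", "copy"]

    def test_monotone_decreasing_transform_gives_minus_one(self, rng):
        prof = self._profiles(rng)
        traits = pd.DataFrame({"neg": -np.exp(prof["M1"])}, index=prof.index)
        am = associate(prof, traits)
        assert am.rho.loc["M1", "neg"] == pytest.approx(-1.0)

    def test_missing_values_drop_pairwise(self, rng):
        prof = self._profiles(rng)
        traits = pd.DataFrame({"t": prof["M1"].to_numpy()}, index=prof.index)
        traits.iloc[0, 0] = np.nan
        am = associate(prof, traits)
        assert am.rho.loc["M1", "t"] == pytest.approx(1.0)

    def test_too_few_units_rejected(self, rng):
        prof = self._profiles(rng, n=3)
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=prof.index)
        with pytest.raises(ValidationError, match="4"):
            associate(prof, traits)


class TestMantel:
    def _dist(self, x):
        return squareform(pdist(np.asarray(x, float)))

    def test_identical_matrices_r_one_minimum_p(self, rng):
        d = self._dist(rng.normal(size=(8, 3)))
        r, p = mantel(d, d.copy(), n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_mismatched_dimensions_rejected(self, rng):
        with pytest.raises(ValidationError):
            mantel(np.zeros((4, 4)), np.zeros((5, 5)), n_perm=99)

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import mantel as sk_mantel
        a = self._dist(rng.normal(size=(7, 3)))
        b = self._dist(rng.normal(size=(7, 3)))
        r, _ = mantel(a, b, n_perm=99, seed=1)
        r_sk = sk_mantel(a, b, permutations=0)[0]
        assert r == pytest.approx(float(r_sk), abs=1e-10)

    def test_sampled_p_agrees_with_exhaustive_enumeration_at_n5(self, rng):
        a = self._dist(rng.normal(size=(5, 2)))
        b = self._dist(rng.normal(size=(5, 2)))
        iu = np.triu_indices(5, 1)
        obs = abs(np.corrcoef(a[iu], b[iu])[0, 1])
        hits = sum(
            abs(np.corrcoef(a[iu], b[np.ix_(perm, perm)][iu])[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(range(5)))
        exact = hits / 120
        _, p = mantel(a, b, n_perm=999, seed=2)
        assert p == pytest.approx(exact, abs=0.05)


def _assoc(p_grid, modules, traits, alpha=0.01):
    p = pd.DataFrame(p_grid, index=modules, columns=traits, dtype=float)
    rho = (0.5 * (p < alpha)).astype(float)
    return AssociationMatrix(rho=rho, p=p, alpha=alpha)


class TestMatchModules:
    def test_relabelled_partition_matched_by_jaccard(self):
        g1 = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(4))
        part_a = detect_modules(g1, seed=0)
        # same structure, permuted node labels: modules swap rank
        g2 = nx.relabel_nodes(g1, {i: (i + 10) % 10 for i in g1.nodes()})
        part_b = detect_modules(g2, seed=0)
        mapping, jaccard = match_modules(part_a, part_b)
        for o, r in mapping.items():
            shared = set(part_b.members(o)) & set(part_a.members(r))
            assert jaccard[o] == pytest.approx(
                len(shared) / len(set(part_b.members(o)) | set(part_a.members(r))))


class TestClassifyShift:
    def test_identical_matrices_all_maintained(self):
        am = _assoc([[0.001, 0.5], [0.002, 0.9]], ["M1", "M2"], ["pH", "TOC"])
        s = classify_shift(am, am)
        assert s.counts() == {"new": 0, "maintained": 2, "missed": 0}

    def test_treated_all_null_means_everything_missed(self):
        u = _assoc([[0.001, 0.001]], ["M1"], ["pH", "TOC"])
        t = _assoc([[0.9, 0.9]], ["M1"], ["pH", "TOC"])
        s = classify_shift(u, t)
        assert len(s.missed) == 2 and not s.new and not s.maintained

    def test_rhizosphere_pattern_22_29_2(self, rng):
        """Constructed grids with 22 shared, 29 treated-only and 2
        untreated-only significant cells classify as (22 maintained,
        29 new, 2 missed)."""
        modules = [f"M{i}" for i in range(1, 5)]
        traits = [f"tr{j}" for j in range(20)]
        cells = [(m, t) for m in modules for t in traits]
        picks = rng.permutation(len(cells))[:53]
        shared, treated_only, untreated_only = (
            picks[:22], picks[22:51], picks[51:53])
        pu = np.ones((4, 20))
        pt = np.ones((4, 20))
        for idx in shared:
            m, t = divmod(idx, 20)
            pu[m, t] = pt[m, t] = 0.001
        for idx in treated_only:
            m, t = divmod(idx, 20)
            pt[m, t] = 0.001
        for idx in untreated_only:
            m, t = divmod(idx, 20)
            pu[m, t] = 0.001
        s = classify_shift(_assoc(pu, modules, traits), _assoc(pt, modules, traits))
        assert s.counts() == {"new": 29, "maintained": 22, "missed": 2}

    def test_set_identities(self, rng):
        modules, traits = ["M1", "M2"], ["a", "b", "c"]
        pu = rng.uniform(size=(2, 3))
        pt = rng.uniform(size=(2, 3))
        u, t = _assoc(pu, modules, traits, 0.5), _assoc(pt, modules, traits, 0.5)
        s = classify_shift(u, t)
        assert s.new | s.maintained == t.significant_pairs()
        assert s.missed | s.maintained == u.significant_pairs()

    def test_differing_trait_sets_rejected(self):
        u = _assoc([[0.5]], ["M1"], ["pH"])
        t = _assoc([[0.5]], ["M1"], ["TOC"])
        with pytest.raises(ValidationError, match="trait sets"):
            classify_shift(u, t)


class TestEndToEndRecovery:
    def test_planted_four_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        from rhizonet.community import filter_rare
        from rhizonet.network import build_network, correlation_screen
        t, truth = generate_community(n_samples=50, n_taxa=60, n_modules=4,
                                      coupling=2.0, seed=21)
        rho, p, _ = correlation_screen(t)
        net = build_network(rho, p, edge_alpha=0.01)
        part = detect_modules(net, seed=0)
        nodes = list(net.graph.nodes())
        ari = adjusted_rand_score([truth.module_of[n] for n in nodes],
                                  [part.module_of[n] for n in nodes])
        assert ari >= 0.8
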