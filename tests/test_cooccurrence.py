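import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coralmicro.cooccurrence import (build_network, guild_recovery_ari,
                                     modular_structure_flag,
                                     nonrandomness_test, spearman_all_pairs,
                                     topology)
from coralmicro.synthetic import generate_table, truth_guild_partition
from coralmicro.tables_io import to_relative_abundance

from conftest import two_host_design


def _frame(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"O{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids,
                        columns=[f"S{j}" for j in range(rows.shape[1])])


def _rank_average_ties(v):
    """Independent average-tie ranking: rank = mean position of equal values."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestSpearmanAllPairs:
    def test_perfect_monotone(self):
        out = spearman_all_pairs(_frame([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]]))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert out.iloc[0]["p"] > 0  # smallest representable, never zero

    def test_perfect_reversal(self):
        out = spearman_all_pairs(_frame([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]]))
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_average_tie_ranks_hand_value(self):
        # ranks (1, 2.5, 2.5, 4) vs (1, 3, 2, 4): Pearson on ranks = 3/sqrt(10)
        out = spearman_all_pairs(_frame([[1, 2, 2, 4, 9], [1, 3, 2, 4, 9]]))
        x = _rank_average_ties([1, 2, 2, 4, 9])
        y = _rank_average_ties([1, 3, 2, 4, 9])
        assert out.iloc[0]["rho"] == pytest.approx(_pearson(x, y))

    def test_matches_rank_formula_with_ties(self, rng):
        values = rng.integers(0, 6, size=(12, 9)).astype(float)
        values[np.ptp(values, axis=1) == 0] += rng.random(9)  # avoid constants
        out = spearman_all_pairs(_frame(values))
        lookup = {(r.otu_a, r.otu_b): r.rho for r in out.itertuples()}
        for i, j in itertools.combinations(range(12), 2):
            expected = _pearson(_rank_average_ties(list(values[i])),
                                _rank_average_ties(list(values[j])))
            assert lookup[(f"O{i}", f"O{j}")] == pytest.approx(expected)

    def test_constant_vector_skipped(self):
        out = spearman_all_pairs(_frame([[1, 1, 1, 1, 1],
                                         [1, 2, 3, 4, 5],
                                         [2, 1, 4, 3, 5]]))
        assert set(zip(out.otu_a, out.otu_b)) == {("O1", "O2")}

    def test_preconditions(self):
        with pytest.raises(ValueError, match="samples"):
            spearman_all_pairs(_frame([[1, 2], [2, 1]]))
        with pytest.raises(ValueError, match="OTUs"):
            spearman_all_pairs(_frame([[1, 2, 3, 4, 5]]))


class TestBuildNetwork:
    @pytest.mark.parametrize("rho,p,present", [
        (0.61, 0.005, True),
        (0.60, 0.001, False),  # "higher than 0.6" is strict
        (0.90, 0.020, False),  # significance threshold is strict
        (0.90, 0.010, False),
        (-0.95, 0.0001, False),  # only positive co-occurrence
    ])
    def test_threshold_rule(self, rho, p, present):
        corr = pd.DataFrame([("A", "B", rho, p, 20)],
                            columns=["otu_a", "otu_b", "rho", "p", "n"])
        net = build_network(corr)
        assert net.has_edge("A", "B") == present

    def test_nodes_are_edge_endpoints_only(self):
        corr = pd.DataFrame([
            ("A", "B", 0.9, 0.001, 20),
            ("C", "D", 0.1, 0.50, 20),
        ], columns=["otu_a", "otu_b", "rho", "p", "n"])
        net = build_network(corr)
        assert set(net.nodes) == {"A", "B"}

    def test_invalid_thresholds(self):
        corr = pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p", "n"])
        with pytest.raises(ValueError):
            build_network(corr, rho_min=1.5)
        with pytest.raises(ValueError):
            build_network(corr, p_max=0.0)


def _brute_shortest_paths(g):
    """Floyd-Warshall on the adjacency matrix, infinity where unreachable."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in g.edges:
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def _brute_clustering(g):
    """Mean local clustering by explicit neighbour-pair triangle counting."""
    vals = []
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if g.has_edge(a, b))
        vals.append(2 * links / (k * (k - 1)))
    return float(np.mean(vals))


class TestTopology:
    def test_triangle(self):
        t = topology(nx.complete_graph(3))
        assert t.avg_connectivity == pytest.approx(2.0)
        assert t.avg_distance == pytest.approx(1.0)
        assert t.diameter == 1
        assert t.avg_clustering == pytest.approx(1.0)

    def test_three_node_path(self):
        t = topology(nx.path_graph(3))
        assert t.avg_distance == pytest.approx((1 + 1 + 2) / 3)
        assert t.diameter == 2
        assert t.avg_clustering == 0.0

    def test_two_disjoint_triangles_modularity(self):
        g = nx.union(nx.complete_graph(3),
                     nx.relabel_nodes(nx.complete_graph(3), {0: 3, 1: 4, 2: 5}))
        t = topology(g, community_seed=0)
        # Q = 2 * (3/6 - (6/12)^2) = 0.5 for the planted 2-community split
        assert t.modularity == pytest.approx(0.5)
        assert t.n_communities == 2
        assert t.is_modular

    def test_avg_connectivity_exact_identity(self, rng):
        for _ in range(10):
            g = nx.gnm_random_graph(rng.integers(5, 25), rng.integers(4, 40),
                                    seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() == 0:
                continue
            t = topology(g)
            assert t.avg_connectivity == 2 * g.number_of_edges() / g.number_of_nodes()

    def test_shortest_paths_and_clustering_against_brute_force(self, rng):
        for _ in range(15):
            g = nx.gnp_random_graph(int(rng.integers(5, 25)), 0.2,
                                    seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 2:
                continue
            t = topology(g)
            d = _brute_shortest_paths(g)
            finite = d[np.isfinite(d) & (d > 0)]
            if finite.size:
                assert t.avg_distance == pytest.approx(finite.mean())
                assert t.diameter == int(finite.max())
            assert t.avg_clustering == pytest.approx(_brute_clustering(g))

    def test_modularity_beats_trivial_partition(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(20, 0.15, seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            t = topology(g, community_seed=1)
            assert t.modularity >= 0.0  # Q of one-community partition is 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology(nx.Graph())


class TestModularFlag:
    @pytest.mark.parametrize("q,expected", [
        (0.73, True), (0.40, False), (0.62, True), (0.401, True), (0.0, False),
    ])
    def test_strict_threshold(self, q, expected):
        assert modular_structure_flag(q) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            modular_structure_flag(float("nan"))


class TestNonrandomness:
    def test_guild_structure_detected(self):
        # 40-sample single-host study with two planted guilds: enough power
        # for the qualifying-edge count to clear every null replicate
        from coralmicro.synthetic import (GroupSpec, GuildSpec,
                                          SyntheticDesign, generate_table,
                                          guild_loading_for_spearman,
                                          otu_name)
        lam = guild_loading_for_spearman(0.8)
        groups = [GroupSpec("Galaxea", loc, 10)
                  for loc in ("CB", "LHT", "SB", "DI")]
        guilds = [GuildSpec([otu_name(i) for i in range(g * 8, (g + 1) * 8)],
                            loading=lam, target_hosts=("Galaxea",))
                  for g in range(2)]
        design = SyntheticDesign(n_otus=60, groups=groups, guilds=guilds,
                                 seed=21)
        table, _, _, _ = generate_table(design)
        res = nonrandomness_test(to_relative_abundance(table).to_frame(),
                                 n_reps=199, seed=0)
        assert res.p_value <= 0.01
        assert res.observed >= res.null_mean

    def test_invariants(self, rng):
        vals = rng.random((10, 12))
        res = nonrandomness_test(pd.DataFrame(
            vals, index=[f"O{i}" for i in range(10)],
            columns=[f"S{j}" for j in range(12)]), n_reps=99, seed=1)
        assert res.observed >= 0
        assert res.null_mean >= 0
        assert res.p_value == pytest.approx((  # (b+1)/(m+1) estimator
            1 + round(res.p_value * 100 - 1)) / 100)

    def test_rep_floor(self):
        with pytest.raises(ValueError):
            nonrandomness_test(pd.DataFrame(np.eye(5)), n_reps=10)


def test_guild_recovery_on_planted_study(small_study):
    table, meta, _, truth = small_study
    rel = to_relative_abundance(table)
    scope = meta.samples_where(host="Galaxea")
    from coralmicro.tables_io import filter_low_abundance
    retained = filter_low_abundance(rel, 0.001, scope)
    frame = rel.select_otus(retained).loc[:, scope]
    net = build_network(spearman_all_pairs(frame))
    t = topology(net, community_seed=0)
    partition = truth_guild_partition(truth)
    galaxea_truth = {o: g for o, g in partition.items() if g == "guild_1"}
    ari = guild_recovery_ari(t.communities, galaxea_truth)
    assert ari == pytest.approx(1.0)  # one guild, fully recovered as one community
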