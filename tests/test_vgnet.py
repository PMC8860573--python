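"""Variant-gene bipartite networks: construction, SCCs, centralities,
degree-model selection, 2-cycles and marker enrichment."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from varlinks import vgnet as vg
from varlinks.annotation import MarkerAnnotation
from varlinks.association import AssociationResult
from varlinks.motifs import MotifImpact, MotifScore


def impact(vid, factor, label, direction, la_ref=10.0, la_alt=5.0):
    ref = MotifScore(la=la_ref, lm=12.0, offset=0, strand="+")
    alt = MotifScore(la=la_alt, lm=12.0, offset=0, strand="+")
    return MotifImpact(vid, f"M_{factor}", factor, ref, alt, label, direction)


def assoc(vid, gene, beta=1.0, p=1e-6):
    return AssociationResult(vid, gene, "additive", beta, 0.1, p)


def random_bipartite(rng, n_var=30, n_gene=20, p_edge=0.05):
    graph = nx.DiGraph()
    variants = [f"v{i}" for i in range(n_var)]
    genes = [f"g{j}" for j in range(n_gene)]
    graph.add_nodes_from(variants, kind="variant")
    graph.add_nodes_from(genes, kind="gene")
    for v in variants:
        for g in genes:
            if rng.random() < p_edge:
                graph.add_edge(v, g, direction_type="variant_to_gene", sign="+")
            if rng.random() < p_edge:
                graph.add_edge(g, v, direction_type="gene_to_variant", sign="-")
    return graph


class TestBuildGraph:
    def test_reciprocal_pair(self):
        graph = vg.build_vg_graph([assoc("v", "TF1")],
                                  [impact("v", "TF1", "deletion", "decrease")])
        assert graph.has_edge("v", "TF1") and graph.has_edge("TF1", "v")
        assert graph.edges["v", "TF1"]["direction_type"] == "variant_to_gene"
        assert graph.edges["TF1", "v"]["sign"] == "-"

    def test_associations_only(self):
        graph = vg.build_vg_graph([assoc("v1", "g1"), assoc("v2", "g1")])
        kinds = {d["direction_type"] for _, _, d in graph.edges(data=True)}
        assert kinds == {"variant_to_gene"}

    def test_bipartiteness_enforced(self):
        for u, v, d in vg.build_vg_graph(
                [assoc("v1", "g1")],
                [impact("v1", "g2", "addition", "increase")]).edges(data=True):
            pass  # no assertion error building it
        with pytest.raises(ValueError, match="both"):
            vg.build_vg_graph([assoc("x", "y")],
                              [impact("y", "x", "addition", "increase")])

    def test_random_fixture_matches_brute_force(self, rng):
        associations = []
        impacts = []
        for _ in range(40):
            associations.append(assoc(f"v{int(rng.integers(10))}",
                                      f"g{int(rng.integers(8))}",
                                      beta=float(rng.normal())))
        for _ in range(40):
            impacts.append(impact(f"v{int(rng.integers(10))}",
                                  f"g{int(rng.integers(8))}",
                                  "deletion", "decrease"))
        graph = vg.build_vg_graph(associations, impacts)
        expected = {(a.variant_id, a.gene_id) for a in associations}
        expected |= {(im.factor, im.variant_id) for im in impacts}
        assert set(graph.edges) == expected

    def test_effect_label_filter(self):
        graph = vg.build_vg_graph([], [impact("v", "F", "match", "none")])
        assert graph.number_of_edges() == 0


def reachability_sccs(graph):
    """Transitive-closure oracle: SCC = mutual-reachability classes."""
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in graph.edges:
        reach[idx[u], idx[v]] = True
    for k in range(n):
        reach |= reach[:, k:k + 1] & reach[k:k + 1, :]
    mutual = reach & reach.T
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        members = frozenset(nodes[j] for j in range(n) if mutual[i, j])
        seen |= {idx[m] for m in members}
        comps.append(members)
    return set(comps)


class TestScc:
    def test_two_cycle_is_one_scc(self):
        graph = vg.build_vg_graph([assoc("v", "TF1")],
                                  [impact("v", "TF1", "deletion", "decrease")])
        comps = vg.strongly_connected_components(graph)
        assert comps[0] == frozenset({"v", "TF1"})

    def test_edgeless_graph_all_singletons(self):
        graph = nx.DiGraph()
        graph.add_nodes_from(range(7))
        comps = vg.strongly_connected_components(graph)
        assert len(comps) == 7 and all(len(c) == 1 for c in comps)

    def test_matches_reachability_oracle(self, rng):
        for n in (20, 80, 200):
            graph = nx.gnp_random_graph(n, 2.0 / n, directed=True,
                                        seed=int(rng.integers(2**31)))
            got = set(vg.strongly_connected_components(graph))
            assert got == reachability_sccs(graph)

    def test_sizes_sum_to_node_count(self, rng):
        graph = random_bipartite(rng)
        comps = vg.strongly_connected_components(graph)
        assert sum(len(c) for c in comps) == graph.number_of_nodes()


def floyd_warshall_centralities(graph):
    """Distance/path-count oracle for betweenness and closeness."""
    nodes = list(graph.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    paths = np.zeros((n, n))
    for i in range(n):
        dist[i, i], paths[i, i] = 0.0, 1.0
    for u, v in graph.edges:
        dist[idx[u], idx[v]], paths[idx[u], idx[v]] = 1.0, 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                alt = dist[i, k] + dist[k, j]
                if alt < dist[i, j]:
                    dist[i, j], paths[i, j] = alt, paths[i, k] * paths[k, j]
                elif alt == dist[i, j] and np.isfinite(alt) and k != i and k != j:
                    paths[i, j] += paths[i, k] * paths[k, j]
    btw = np.zeros(n)
    for w in range(n):
        for s in range(n):
            for t in range(n):
                if s in (w, t) or t == w:
                    continue
                if np.isfinite(dist[s, t]) and paths[s, t] > 0 and \
                        dist[s, w] + dist[w, t] == dist[s, t]:
                    btw[w] += paths[s, w] * paths[w, t] / paths[s, t]
    cls = np.zeros(n)
    for v in range(n):
        reachable = np.isfinite(dist[v]) & (np.arange(n) != v)
        r = reachable.sum()
        total = dist[v, reachable].sum()
        if r > 0 and total > 0:
            cls[v] = (r / total) * (r / (n - 1))
    return ({nodes[i]: btw[i] for i in range(n)},
            {nodes[i]: cls[i] for i in range(n)})


class TestCentralities:
    def test_star_center_has_max_betweenness(self):
        graph = nx.DiGraph()
        for leaf in "abcd":
            graph.add_edge(leaf, "hub")
            graph.add_edge("hub", leaf)
        table = vg.centralities(graph).set_index("node")
        assert table.loc["hub", "betweenness"] == table["betweenness"].max()
        assert table.loc["hub", "betweenness"] > 0

    def test_isolated_node_closeness_zero(self):
        graph = nx.DiGraph()
        graph.add_edge("a", "b")
        graph.add_node("lonely")
        table = vg.centralities(graph).set_index("node")
        assert table.loc["lonely", "closeness"] == 0.0
        assert table.loc["b", "closeness"] == 0.0  # no outgoing reachability

    def test_matches_floyd_warshall_oracle(self, rng):
        for n in (15, 30, 50):
            graph = nx.gnp_random_graph(n, 3.0 / n, directed=True,
                                        seed=int(rng.integers(2**31)))
            table = vg.centralities(graph).set_index("node")
            btw, cls = floyd_warshall_centralities(graph)
            for node in graph.nodes:
                assert table.loc[node, "betweenness"] == pytest.approx(
                    btw[node], abs=1e-9)
                assert table.loc[node, "closeness"] == pytest.approx(
                    cls[node], abs=1e-9)


def lognormal_sample(rng, n, mu=1.0, sigma=0.8, cap=200_000):
    k = np.arange(1, cap + 1)
    pmf = (stats.norm.cdf((np.log(k + 0.5) - mu) / sigma)
           - stats.norm.cdf((np.log(np.maximum(k - 0.5, 1e-12)) - mu) / sigma))
    return rng.choice(k, size=n, p=pmf / pmf.sum())


def powerlaw_sample(rng, n, alpha=2.5, cap=200_000):
    k = np.arange(1, cap + 1)
    pmf = k ** -alpha
    return rng.choice(k, size=n, p=pmf / pmf.sum())


class TestDegreeFit:
    def test_lognormal_sample_preferred(self, rng):
        fit = vg.fit_degree_distribution(lognormal_sample(rng, 5000))
        assert fit.preferred == "lognormal"

    def test_powerlaw_sample_preferred(self, rng):
        fit = vg.fit_degree_distribution(powerlaw_sample(rng, 5000))
        assert fit.preferred == "powerlaw"
        assert 2.2 <= fit.alpha <= 2.8

    def test_constant_degrees_inconclusive(self):
        fit = vg.fit_degree_distribution([3] * 100)
        assert fit.preferred == "inconclusive"

    def test_too_few_points_inconclusive(self):
        fit = vg.fit_degree_distribution([1, 2, 3, 4, 5])
        assert fit.preferred == "inconclusive"


class TestTwoCycles:
    def test_single_reciprocal_pair(self):
        graph = vg.build_vg_graph([assoc("v", "TF1", beta=-1.0)],
                                  [impact("v", "TF1", "deletion", "decrease")])
        (cycle,) = vg.enumerate_2cycles(graph)
        assert (cycle.variant_id, cycle.factor_gene_id) == ("v", "TF1")
        assert cycle.association_sign == "-" and cycle.binding_sign == "-"

    def test_dag_has_none(self):
        graph = vg.build_vg_graph([assoc("v1", "g1"), assoc("v2", "g2")])
        assert vg.enumerate_2cycles(graph) == []

    def test_matches_reciprocal_edge_oracle(self, rng):
        graph = random_bipartite(rng, n_var=300, n_gene=200, p_edge=0.01)
        got = {(c.variant_id, c.factor_gene_id)
               for c in vg.enumerate_2cycles(graph)}
        expected = {
            (u, v) for u, v, d in graph.edges(data=True)
            if d["direction_type"] == "variant_to_gene" and graph.has_edge(v, u)
        }
        assert got == expected

    def test_every_2cycle_inside_one_scc(self, rng):
        graph = random_bipartite(rng)
        comp_of = {}
        for comp in vg.strongly_connected_components(graph):
            for node in comp:
                comp_of[node] = comp
        for c in vg.enumerate_2cycles(graph):
            assert comp_of[c.variant_id] is comp_of[c.factor_gene_id]

    def test_removing_gene_to_variant_edges_kills_cycles(self, rng):
        graph = random_bipartite(rng)
        pruned = graph.copy()
        pruned.remove_edges_from([
            (u, v) for u, v, d in graph.edges(data=True)
            if d["direction_type"] == "gene_to_variant"
        ])
        assert vg.enumerate_2cycles(pruned) == []


def fisher_oracle(table):
    """Two-sided Fisher p as the hypergeometric sum of tables at least as
    extreme (probability at most that of the observed table)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestMarkerEnrichment:
    def _graph_with_cycles(self, n_cycle=5, n_other=40):
        associations = [assoc(f"c{i}", f"TF{i}") for i in range(n_cycle)]
        impacts = [impact(f"c{i}", f"TF{i}", "deletion", "decrease")
                   for i in range(n_cycle)]
        associations += [assoc(f"x{i}", "gY") for i in range(n_other)]
        return vg.build_vg_graph(associations, impacts)

    def test_extreme_table(self):
        graph = self._graph_with_cycles()
        markers = [MarkerAnnotation(f"c{i}", "enhancer", "t") for i in range(5)]
        odds, p, table = vg.twocycle_marker_enrichment(graph, markers)
        assert np.isinf(odds)
        assert p == pytest.approx(fisher_oracle(table))

    def test_fisher_matches_hypergeometric_oracle(self):
        table = np.array([[8, 2], [20, 70]])
        odds, p = stats.fisher_exact(table)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_null_marker_pvalues_roughly_uniform(self, rng):
        graph = self._graph_with_cycles(n_cycle=8, n_other=60)
        variants = [n for n, d in graph.nodes(data=True)
                    if d.get("kind") == "variant"]
        pvals = []
        for _ in range(200):
            chosen = rng.choice(variants, size=20, replace=False)
            markers = [MarkerAnnotation(v, "enhancer", "t") for v in chosen]
            _, p, _ = vg.twocycle_marker_enrichment(graph, markers)
            pvals.append(p)
        # discrete and conservative, but the lowest decile should not be hit
        # far more often than its nominal rate
        assert np.mean(np.array(pvals) <= 0.1) <= 0.2

    def test_degenerate_margin_warns(self):
        graph = self._graph_with_cycles(n_cycle=2, n_other=5)
        with pytest.warns(UserWarning, match="degenerate"):
            _, p, _ = vg.twocycle_marker_enrichment(graph, [])
        assert p == 1.0
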