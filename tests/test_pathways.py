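import random
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthodiff.errors import PathExplosionError, ValidationError
from orthodiff.pathways import (
    affected_paths,
    annotate_missing_genes,
    benjamini_hochberg,
    enrich_pathways,
    hypergeometric_upper_tail,
    node_level_percentage,
    node_statuses,
    to_dot,
)
from orthodiff.types import PathwayGraph, PathwayNode


def exact_upper_tail(k, n, K, N) -> Fraction:
    """Exact tail by summing combinatorial draw counts (independent oracle)."""
    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(hits, total)


class TestHypergeometric:
    def test_zero_k_is_one(self):
        assert hypergeometric_upper_tail(0, 5, 3, 10) == 1.0

    def test_all_success_population(self):
        assert hypergeometric_upper_tail(5, 5, 10, 10) == 1.0

    def test_against_enumeration_example(self):
        got = hypergeometric_upper_tail(3, 5, 6, 20)
        expected = exact_upper_tail(3, 5, 6, 20)
        assert got == pytest.approx(float(expected), rel=1e-13)

    def test_bounds_validation(self):
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(4, 3, 6, 20)  # k > n
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(1, 3, 30, 20)  # K > N
        with pytest.raises(ValidationError):
            hypergeometric_upper_tail(-1, 3, 6, 20)

    def test_agrees_with_scipy(self):
        from scipy.stats import hypergeom

        rng = random.Random(3)
        for _ in range(200):
            N = rng.randint(1, 5000)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k = rng.randint(max(0, n + K - N), min(n, K))
            mine = hypergeometric_upper_tail(k, n, K, N)
            ref = float(hypergeom.sf(k - 1, N, K, n))
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-300)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 40), st.data())
    def test_monotone_nonincreasing_in_k(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        prev = 1.0
        for k in range(min(n, K) + 1):
            p = hypergeometric_upper_tail(k, n, K, N)
            assert p <= prev + 1e-15
            prev = p

    def test_large_population_stable(self):
        p = hypergeometric_upper_tail(500, 1000, 30000, 100000)
        assert 0.0 <= p <= 1.0


class TestBenjaminiHochberg:
    def test_known_adjustment(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])


class TestEnrichPathways:
    def test_disjoint_pathway(self):
        background = {f"g{i}" for i in range(20)}
        membership = {"g0": {"pw"}, "g1": {"pw"}}
        rows = enrich_pathways({"g10", "g11"}, membership, background)
        (row,) = rows
        assert row.k == 0 and row.p_value == 1.0

    def test_extreme_enrichment(self):
        background = {f"g{i}" for i in range(200)}
        membership = {f"g{i}": {"pw"} for i in range(10)}
        missing = {f"g{i}" for i in range(10)}
        (row,) = enrich_pathways(missing, membership, background)
        assert row.k == row.n == 10
        assert row.p_value < 0.01
        assert row.significant()

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            enrich_pathways(set(), {}, set())

    def test_missing_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            enrich_pathways({"ghost"}, {"g1": {"pw"}}, {"g1"})

    def test_rows_sorted_by_p(self):
        background = {f"g{i}" for i in range(100)}
        membership = {}
        for i in range(10):
            membership.setdefault(f"g{i}", set()).add("hot")
        for i in range(50, 60):
            membership.setdefault(f"g{i}", set()).add("cold")
        missing = {f"g{i}" for i in range(8)}
        rows = enrich_pathways(missing, membership, background)
        assert [r.pathway_id for r in rows] == ["hot", "cold"]
        assert rows[0].p_value <= rows[1].p_value

    def test_pair_rows_accepted(self):
        background = {"g1", "g2"}
        rows = enrich_pathways({"g1"}, [("g1", "pw"), ("g2", "pw")], background)
        assert rows[0].n == 2


def _graph(node_genes, edges, phenotype):
    nodes = [
        PathwayNode(node_id=nid, gene_ids=frozenset(genes))
        for nid, genes in node_genes.items()
    ]
    return PathwayGraph(
        pathway_id="pw", nodes=nodes, edges=edges, phenotype_nodes=set(phenotype)
    )


class TestNodeStatuses:
    def test_partial(self):
        g = _graph({"n": {"g1", "g2"}, "P": set()}, [("n", "P")], {"P"})
        (status,) = node_statuses(g, {"g1"})
        assert status.status == "partial"

    def test_all_lost(self):
        g = _graph({"n": {"g1", "g2"}, "P": set()}, [("n", "P")], {"P"})
        (status,) = node_statuses(g, {"g1", "g2"})
        assert status.status == "all_lost"

    def test_empty_missing_all_intact(self):
        g = _graph({"n1": {"g1"}, "n2": {"g2"}, "P": set()},
                   [("n1", "P"), ("n2", "P")], {"P"})
        assert all(s.status == "intact" for s in node_statuses(g, set()))

    def test_status_partition_property(self):
        rng = random.Random(8)
        node_genes = {f"n{i}": {f"n{i}_g{j}" for j in range(2)} for i in range(10)}
        node_genes["P"] = set()
        g = _graph(node_genes, [(f"n{i}", "P") for i in range(10)], {"P"})
        all_genes = sorted(set().union(*node_genes.values()))
        missing = {x for x in all_genes if rng.random() < 0.4}
        statuses = node_statuses(g, missing)
        counts = {"intact": 0, "partial": 0, "all_lost": 0}
        for s in statuses:
            counts[s.status] += 1
        assert sum(counts.values()) == 10

    def test_node_level_percentage(self):
        node_genes = {f"n{i}": {f"g{i}"} for i in range(8)}
        node_genes["P"] = set()
        g = _graph(node_genes, [(f"n{i}", "P") for i in range(8)], {"P"})
        assert node_level_percentage(g, set()) == (0, 8, 0.0)
        assert node_level_percentage(g, {"g0", "g1", "g2"}) == (3, 8, 37.5)

    def test_generator_truth(self, dataset):
        from orthodiff import io as oio

        _, out, ledger = dataset
        missing = set(ledger.class_2)
        for path in sorted(out.glob("pathway_*.json")):
            graph = oio.read_pathway_graph(path)
            lesioned = {
                s.node_id for s in node_statuses(graph, missing) if s.status != "intact"
            }
            assert lesioned == set(ledger.lost_genes_per_node[graph.pathway_id])


def oracle_affected_paths(nodes, edges, phenotype, lesioned):
    """Exhaustive DFS simple-path enumeration, independent of networkx."""
    preds = {n: set() for n in nodes}
    succs = {n: set() for n in nodes}
    for s, d in edges:
        preds[d].add(s)
        succs[s].add(d)
    # nodes that can reach phenotype
    reach = {phenotype}
    stack = [phenotype]
    while stack:
        cur = stack.pop()
        for p in preds[cur]:
            if p not in reach:
                reach.add(p)
                stack.append(p)
    sources = [
        n for n in reach if not (preds[n] & reach) and n != phenotype
    ]
    paths = []

    def dfs(node, trail):
        if node == phenotype:
            paths.append(list(trail))
            return
        for nxt in succs[node] & reach:
            if nxt not in trail:
                trail.append(nxt)
                dfs(nxt, trail)
                trail.pop()

    for src in sorted(sources):
        dfs(src, [src])
    affected = sum(1 for p in paths if any(n in lesioned for n in p))
    return affected, len(paths)


class TestAffectedPaths:
    def test_linear_chain(self):
        g = _graph({"S": {"gs"}, "X": {"gx"}, "P": set()},
                   [("S", "X"), ("X", "P")], {"P"})
        n_affected, n_total, _ = affected_paths(g, "P", {"gx"})
        assert (n_affected, n_total) == (1, 1)

    def test_diamond_branch_isolation(self):
        g = _graph(
            {"S": {"gs"}, "X": {"gx", "gx2"}, "Y": {"gy"}, "P": set()},
            [("S", "X"), ("S", "Y"), ("X", "P"), ("Y", "P")],
            {"P"},
        )
        n_affected, n_total, _ = affected_paths(g, "P", {"gx"})
        assert (n_affected, n_total) == (1, 2)

    def test_unknown_phenotype(self):
        g = _graph({"S": {"g"}, "P": set()}, [("S", "P")], {"P"})
        with pytest.raises(ValidationError):
            affected_paths(g, "ghost", set())

    def test_path_cap(self):
        # complete layered DAG with many paths
        node_genes = {f"n{i}": {f"g{i}"} for i in range(12)}
        node_genes["P"] = set()
        edges = [(f"n{i}", f"n{j}") for i in range(12) for j in range(i + 1, 12)]
        edges += [(f"n{i}", "P") for i in range(12)]
        g = _graph(node_genes, edges, {"P"})
        with pytest.raises(PathExplosionError):
            affected_paths(g, "P", set(), max_paths=10)

    def test_random_dags_match_oracle(self):
        rng = random.Random(21)
        for _ in range(50):
            m = rng.randint(3, 12)
            names = [f"n{i}" for i in range(m)]
            node_genes = {n: {f"{n}_g"} for n in names[:-1]}
            node_genes[names[-1]] = set()
            edges = [
                (names[i], names[j])
                for i in range(m)
                for j in range(i + 1, m)
                if rng.random() < 0.35
            ]
            g = _graph(node_genes, edges, {names[-1]})
            lesion_genes = {f"{n}_g" for n in names[:-1] if rng.random() < 0.3}
            lesioned = {n for n in names[:-1] if f"{n}_g" in lesion_genes}
            got = affected_paths(g, names[-1], lesion_genes)[:2]
            assert got == oracle_affected_paths(names, edges, names[-1], lesioned)

    def test_monotone_in_missing_set(self):
        rng = random.Random(5)
        names = [f"n{i}" for i in range(9)]
        node_genes = {n: {f"{n}_g"} for n in names[:-1]}
        node_genes[names[-1]] = set()
        edges = [
            (names[i], names[j])
            for i in range(9)
            for j in range(i + 1, 9)
            if rng.random() < 0.4
        ]
        g = _graph(node_genes, edges, {names[-1]})
        missing = set()
        prev = 0
        for n in names[:-1]:
            missing.add(f"{n}_g")
            n_affected, n_total, _ = affected_paths(g, names[-1], missing)
            assert n_affected >= prev
            assert n_affected <= n_total
            prev = n_affected


class TestAnnotateMissing:
    def test_reference_percentages(self):
        genes = {f"g{i}" for i in range(29)}
        annotation = {f"g{i}": (False, True) for i in range(19)}
        out = annotate_missing_genes(genes, annotation)
        assert out["n_with_expression_change"] == 19
        assert out["expression_pct"] == 65.5

        genes = {f"g{i}" for i in range(19)}
        annotation = {f"g{i}": (True, False) for i in range(7)}
        out = annotate_missing_genes(genes, annotation)
        assert out["n_with_phenotype"] == 7
        assert out["phenotype_pct"] == 36.8

    def test_empty_annotation(self):
        out = annotate_missing_genes({"g1", "g2"}, {})
        assert out["n_with_phenotype"] == 0
        assert out["phenotype_pct"] == 0.0


class TestDot:
    def test_colors_by_status(self):
        g = _graph({"a": {"g1", "g2"}, "b": {"g3"}, "P": set()},
                   [("a", "P"), ("b", "P")], {"P"})
        dot = to_dot(g, {"g1", "g3"})
        assert "palegreen" in dot  # partial node a
        assert "tomato" in dot  # all_lost node b
        assert "doubleoctagon" in dot  # phenotype sink
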