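"""Pathway enrichment, node lesion status and path-affectedness.

Gene-level enrichment uses the hypergeometric upper tail: the probability of
seeing at least ``k`` missing genes in a size-``n`` pathway drawn from a
background of ``N`` genes of which ``K`` are missing.  Node-level analysis
labels each pathway node intact / partial / all_lost by how many of its genes
are missing, and path-affectedness counts the simple source-to-phenotype
routes that traverse at least one lesioned node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import PathExplosionError, ValidationError
from .formatting import pct1
from .types import PathwayGraph

# ---------------------------------------------------------------------------
# hypergeometric machinery

_LOGFACT = [0.0]


def _logfact(n: int) -> float:
    while len(_LOGFACT) <= n:
        _LOGFACT.append(_LOGFACT[-1] + math.log(len(_LOGFACT)))
    return _LOGFACT[n]


def _logcomb(a: int, b: int) -> float:
    return _logfact(a) - _logfact(b) - _logfact(a - b)


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    Computed from the log-space PMF at ``k`` with a multiplicative recurrence
    over the tail terms, so it is exact to near machine precision for ``N``
    well beyond 1e5.
    """
    for name, value in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not isinstance(value, (int,)) or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if n > N or K > N:
        raise ValidationError(f"need n <= N and K <= N, got n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValidationError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k <= max(0, n + K - N):
        return 1.0
    log_term = _logcomb(K, k) + _logcomb(N - K, n - k) - _logcomb(N, n)
    # streaming log-sum-exp over the tail terms (they can dwarf the first
    # term when k sits far below the distribution's mode)
    log_max = log_term
    scaled_sum = 1.0
    for i in range(k, min(n, K)):
        log_term += math.log(K - i) + math.log(n - i) - math.log(i + 1) - math.log(
            N - K - n + i + 1
        )
        if log_term <= log_max:
            scaled_sum += math.exp(log_term - log_max)
        else:
            scaled_sum = scaled_sum * math.exp(log_max - log_term) + 1.0
            log_max = log_term
    return min(math.exp(log_max + math.log(scaled_sum)), 1.0)


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted q-values, preserving input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    out = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        out[idx] = running
    return out


# ---------------------------------------------------------------------------
# gene-level enrichment


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's hypergeometric test result.

    ``k`` missing genes among the pathway's ``n`` background genes; ``K``
    missing genes in the ``N``-gene background.  ``q_value`` is a
    Benjamini-Hochberg adjunct column (an extension; the significance flag
    uses the raw p-value).
    """

    pathway_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float = float("nan")

    def significant(self, p_max: float = 0.01) -> bool:
        return self.p_value < p_max


def enrich_pathways(
    missing_genes: set[str],
    membership: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
    background: set[str],
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail test of missing-gene excess per pathway.

    ``membership`` maps gene -> pathway ids (or is an iterable of
    ``(gene, pathway)`` rows).  Only background genes count; one row per
    pathway with at least one background gene, sorted by ascending p-value
    then pathway id.
    """
    if not background:
        raise ValidationError("empty background gene set")
    stray = missing_genes - background
    if stray:
        raise ValidationError(
            f"missing genes not in background: {sorted(stray)[:5]}"
        )
    if not isinstance(membership, Mapping):
        pairs = list(membership)
        mapping: dict[str, set[str]] = {}
        for gene, pathway in pairs:
            mapping.setdefault(gene, set()).add(pathway)
        membership = mapping

    pathway_genes: dict[str, set[str]] = {}
    for gene, pathways_of_gene in membership.items():
        if gene not in background:
            continue
        for pw in pathways_of_gene:
            pathway_genes.setdefault(pw, set()).add(gene)

    N = len(background)
    K = len(missing_genes)
    rows = []
    for pw in sorted(pathway_genes):
        genes = pathway_genes[pw]
        n = len(genes)
        k = len(genes & missing_genes)
        rows.append(
            EnrichmentRow(
                pathway_id=pw,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=hypergeometric_upper_tail(k, n, K, N),
            )
        )
    q_values = benjamini_hochberg([r.p_value for r in rows])
    rows = [
        EnrichmentRow(
            pathway_id=r.pathway_id,
            k=r.k,
            n=r.n,
            K=r.K,
            N=r.N,
            p_value=r.p_value,
            q_value=q,
        )
        for r, q in zip(rows, q_values)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rows


# ---------------------------------------------------------------------------
# node-level analysis

INTACT = "intact"
PARTIAL = "partial"
ALL_LOST = "all_lost"


@dataclass(frozen=True)
class NodeStatus:
    node_id: str
    status: str
    n_genes: int
    n_missing: int


def node_statuses(graph: PathwayGraph, missing_genes: set[str]) -> list[NodeStatus]:
    """Label every non-phenotype node intact / partial / all_lost.

    Phenotype sinks are outcome boxes, not gene modules, and are excluded.
    """
    out = []
    for node in sorted(graph.nodes, key=lambda n: n.node_id):
        if node.node_id in graph.phenotype_nodes:
            continue
        n_genes = len(node.gene_ids)
        n_missing = len(node.gene_ids & missing_genes)
        if n_missing == 0:
            status = INTACT
        elif n_missing == n_genes:
            status = ALL_LOST
        else:
            status = PARTIAL
        out.append(
            NodeStatus(
                node_id=node.node_id,
                status=status,
                n_genes=n_genes,
                n_missing=n_missing,
            )
        )
    return out


def node_level_percentage(
    graph: PathwayGraph, missing_genes: set[str]
) -> tuple[int, int, float]:
    """(affected node count, total non-phenotype nodes, percentage to 1 dp)."""
    statuses = node_statuses(graph, missing_genes)
    affected = sum(1 for s in statuses if s.status != INTACT)
    total = len(statuses)
    return affected, total, pct1(affected, total)


def affected_paths(
    graph: PathwayGraph,
    phenotype_node: str,
    missing_genes: set[str],
    max_paths: int = 100_000,
) -> tuple[int, int, list[list[str]]]:
    """Count simple source-to-phenotype paths that traverse a lesioned node.

    The graph is restricted to nodes from which ``phenotype_node`` is
    reachable; sources are the in-degree-0 nodes of that restriction.  A path
    is affected iff it contains at least one partial or all_lost node.
    Enumeration beyond ``max_paths`` raises :class:`PathExplosionError`.
    """
    if phenotype_node not in graph.node_map:
        raise ValidationError(f"unknown phenotype node {phenotype_node!r}")
    g = graph.digraph()
    keep = nx.ancestors(g, phenotype_node) | {phenotype_node}
    h = g.subgraph(keep)
    sources = sorted(
        n for n in h.nodes if h.in_degree(n) == 0 and n != phenotype_node
    )
    lesioned = {
        s.node_id
        for s in node_statuses(graph, missing_genes)
        if s.status != INTACT
    }
    paths: list[list[str]] = []
    n_affected = 0
    for source in sources:
        for path in nx.all_simple_paths(h, source, phenotype_node):
            paths.append(path)
            if len(paths) > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} simple paths to {phenotype_node!r}"
                )
            if any(node in lesioned for node in path):
                n_affected += 1
    return n_affected, len(paths), paths


def annotate_missing_genes(
    missing_genes: set[str],
    annotation: Mapping[str, tuple[bool, bool]],
) -> dict:
    """Join missing genes against a user-supplied annotation table.

    The table maps gene -> (phenotype_flag, expression_flag); returns counts
    and one-decimal percentages over ``missing_genes``.
    """
    n = len(missing_genes)
    n_pheno = sum(
        1 for g in missing_genes if annotation.get(g, (False, False))[0]
    )
    n_expr = sum(
        1 for g in missing_genes if annotation.get(g, (False, False))[1]
    )
    return {
        "n_genes": n,
        "n_with_phenotype": n_pheno,
        "phenotype_pct": pct1(n_pheno, n),
        "n_with_expression_change": n_expr,
        "expression_pct": pct1(n_expr, n),
    }


_DOT_COLORS = {INTACT: "white", PARTIAL: "palegreen", ALL_LOST: "tomato"}


def to_dot(graph: PathwayGraph, missing_genes: set[str]) -> str:
    """GraphViz DOT rendering with the white/green/red lesion colouring."""
    color = {s.node_id: _DOT_COLORS[s.status] for s in node_statuses(graph, missing_genes)}
    lines = [f'digraph "{graph.pathway_id}" {{']
    for node in sorted(graph.nodes, key=lambda n: n.node_id):
        if node.node_id in graph.phenotype_nodes:
            lines.append(
                f'  "{node.node_id}" [shape=doubleoctagon, label="{node.label or node.node_id}"];'
            )
        else:
            lines.append(
                f'  "{node.node_id}" [style=filled, fillcolor={color[node.node_id]}, '
                f'label="{node.label or node.node_id}"];'
            )
    for src, dst in sorted(graph.edges):
        lines.append(f'  "{src}" -> "{dst}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
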