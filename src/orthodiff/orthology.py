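"""Isoform selection, reciprocal-best-hit orthology and gene classification.

Orthology is computed at gene level after isoform collapsing: each gene is
represented by a single protein (smallest protein-existence rank, ties broken
by longest sequence, then lexicographically smallest protein id), and hits
between non-representative isoforms are ignored.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping

from .errors import ValidationError
from .formatting import pct1
from .types import AlignmentHit, ClassPartition, OrthologPair, ProteinRecord

_PE_ABSENT = float("inf")


def select_representative(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Pick one representative protein per gene.

    Order of precedence: minimal ``pe_rank`` (absent ranks last), then maximal
    sequence length, then lexicographically smallest ``protein_id``.
    """
    by_gene: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        by_gene[rec.gene_id].append(rec)
    out: dict[str, ProteinRecord] = {}
    for gene, group in by_gene.items():
        if not group:
            raise ValidationError(f"gene {gene!r}: empty isoform group")
        out[gene] = min(
            group,
            key=lambda r: (
                r.pe_rank if r.pe_rank is not None else _PE_ABSENT,
                -len(r.sequence),
                r.protein_id,
            ),
        )
    return out


def best_hits(
    hits: Iterable[AlignmentHit], cutoff: float = 1e-6
) -> dict[str, str]:
    """Best subject per query among hits with ``e_value <= cutoff``.

    Best = highest bit score; ties broken by lowest e-value, then by
    lexicographically smallest subject id.  Queries with no surviving hit are
    absent from the map.
    """
    return {q: hit.subject_id for q, hit in best_hit_rows(hits, cutoff).items()}


def best_hit_rows(
    hits: Iterable[AlignmentHit], cutoff: float = 1e-6
) -> dict[str, AlignmentHit]:
    """As :func:`best_hits` but retaining the winning row per query."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.e_value > cutoff:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: AlignmentHit) -> tuple:
    return (-hit.bit_score, hit.e_value, hit.subject_id)


def reciprocal_best_hits(
    forward: Mapping[str, str], reverse: Mapping[str, str]
) -> list[OrthologPair]:
    """Pairs ``(a, b)`` with ``forward[a] == b`` and ``reverse[b] == a``."""
    pairs = [
        OrthologPair(gene_a=a, gene_b=b)
        for a, b in forward.items()
        if reverse.get(b) == a
    ]
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def rbh_from_tables(
    forward_hits: Iterable[AlignmentHit],
    reverse_hits: Iterable[AlignmentHit],
    cutoff: float = 1e-6,
    gene_of_a: Mapping[str, str] | None = None,
    gene_of_b: Mapping[str, str] | None = None,
) -> list[OrthologPair]:
    """Reciprocal best hits straight from two tabular files.

    When ``gene_of_a``/``gene_of_b`` map protein ids to gene ids, rows whose
    query/subject is not a mapped representative are dropped and the emitted
    pairs carry gene ids; otherwise ids are used verbatim.
    """

    def translate(
        rows: Iterable[AlignmentHit],
        qmap: Mapping[str, str] | None,
        smap: Mapping[str, str] | None,
    ) -> list[AlignmentHit]:
        if qmap is None and smap is None:
            return list(rows)
        out = []
        for h in rows:
            q = qmap.get(h.query_id) if qmap is not None else h.query_id
            s = smap.get(h.subject_id) if smap is not None else h.subject_id
            if q is None or s is None:
                continue
            if q != h.query_id or s != h.subject_id:
                h = AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    pct_identity=h.pct_identity,
                    aln_length=h.aln_length,
                    mismatches=h.mismatches,
                    gap_opens=h.gap_opens,
                    q_start=h.q_start,
                    q_end=h.q_end,
                    s_start=h.s_start,
                    s_end=h.s_end,
                    e_value=h.e_value,
                    bit_score=h.bit_score,
                )
            out.append(h)
        return out

    fwd = best_hit_rows(translate(forward_hits, gene_of_a, gene_of_b), cutoff)
    rev = best_hit_rows(translate(reverse_hits, gene_of_b, gene_of_a), cutoff)
    pairs = []
    for a, fhit in fwd.items():
        b = fhit.subject_id
        rhit = rev.get(b)
        if rhit is not None and rhit.subject_id == a:
            pairs.append(
                OrthologPair(gene_a=a, gene_b=b, forward_hit=fhit, reverse_hit=rhit)
            )
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def classify_genes(
    genes_a: set[str],
    genes_b: set[str],
    pairs: Iterable[OrthologPair],
) -> ClassPartition:
    """Three-way partition: shared pairs, A-only genes, B-only genes."""
    class_1: set[tuple[str, str]] = set()
    for pair in pairs:
        if pair.gene_a not in genes_a:
            raise ValidationError(f"pair references unknown species-A gene {pair.gene_a!r}")
        if pair.gene_b not in genes_b:
            raise ValidationError(f"pair references unknown species-B gene {pair.gene_b!r}")
        class_1.add((pair.gene_a, pair.gene_b))
    paired_a = {a for a, _ in class_1}
    paired_b = {b for _, b in class_1}
    if len(paired_a) != len(class_1) or len(paired_b) != len(class_1):
        raise ValidationError("a gene participates in more than one ortholog pair")
    return ClassPartition(
        class_1=class_1,
        class_2=genes_a - paired_a,
        class_3=genes_b - paired_b,
    )


def partition_summary(partition: ClassPartition) -> dict:
    """Class sizes plus shared-gene percentages of each species' total."""
    n_shared = len(partition.class_1)
    n_a = n_shared + len(partition.class_2)
    n_b = n_shared + len(partition.class_3)
    return {
        "n_genes_a": n_a,
        "n_genes_b": n_b,
        "n_class_1": n_shared,
        "n_class_2": len(partition.class_2),
        "n_class_3": len(partition.class_3),
        "shared_pct_of_a": pct1(n_shared, n_a),
        "shared_pct_of_b": pct1(n_shared, n_b),
    }
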