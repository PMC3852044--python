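"""Protein-family assignment and expansion/contraction scoring.

Counting conventions
--------------------
* Each protein keeps at most one family (smallest e-value wins).
* Families are counted by gene, after isoform collapsing.
* ``class_1_count`` is the number of shared ortholog pairs in which at least
  one of the two genes carries the family; ``class_2_count``/``class_3_count``
  count lineage-specific genes per species.
* The signed change ``delta = class_3_count - class_2_count`` is the per-family
  expansion (positive) or contraction (negative) of species B relative to A.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .types import ClassPartition, FamilyAssignment, FamilyDynamicsRow


def assign_families(
    raw_hits: Mapping[str, Sequence[tuple[str, float, float]]],
    cutoff: float = 1e-5,
) -> list[FamilyAssignment]:
    """Keep the single best family per protein.

    ``raw_hits`` maps protein id to candidate ``(family_id, e_value,
    bit_score)`` tuples.  Candidates with ``e_value > cutoff`` are dropped
    (the bound is inclusive); among survivors the smallest e-value wins, ties
    broken by highest bit score, then lexicographic family id.  Proteins left
    with no candidate produce no assignment.
    """
    out: list[FamilyAssignment] = []
    for protein_id in sorted(raw_hits):
        survivors = []
        for family_id, e_val, bits in raw_hits[protein_id]:
            if e_val < 0:
                raise ValidationError(
                    f"protein {protein_id!r}: negative e-value for {family_id!r}"
                )
            if e_val <= cutoff:
                survivors.append((e_val, -bits, family_id))
        if not survivors:
            continue
        e_val, neg_bits, family_id = min(survivors)
        out.append(
            FamilyAssignment(
                protein_id=protein_id,
                family_id=family_id,
                e_value=e_val,
                bit_score=-neg_bits,
            )
        )
    return out


def count_by_class(
    assignments: Iterable[FamilyAssignment],
    partition: ClassPartition,
    gene_of: Mapping[str, str],
) -> list[FamilyDynamicsRow]:
    """Per-family gene counts split by orthology class.

    Assignments may cover proteins of both species; every assigned protein
    must map (via ``gene_of``) to a gene present in the partition.  Rows come
    back sorted by family id.
    """
    pair_of_gene: dict[str, tuple[str, str]] = {}
    for pair in partition.class_1:
        pair_of_gene[pair[0]] = pair
        pair_of_gene[pair[1]] = pair

    fam_pairs: dict[str, set[tuple[str, str]]] = defaultdict(set)
    fam_c2: dict[str, set[str]] = defaultdict(set)
    fam_c3: dict[str, set[str]] = defaultdict(set)
    for asg in assignments:
        gene = gene_of.get(asg.protein_id)
        if gene is None:
            raise ValidationError(
                f"assignment for {asg.protein_id!r}: protein has no gene mapping"
            )
        if gene in pair_of_gene:
            fam_pairs[asg.family_id].add(pair_of_gene[gene])
        elif gene in partition.class_2:
            fam_c2[asg.family_id].add(gene)
        elif gene in partition.class_3:
            fam_c3[asg.family_id].add(gene)
        else:
            raise ValidationError(
                f"assignment for {asg.protein_id!r}: gene {gene!r} is not in "
                "the partition"
            )

    families = sorted(set(fam_pairs) | set(fam_c2) | set(fam_c3))
    return [
        FamilyDynamicsRow(
            family_id=fam,
            class_1_count=len(fam_pairs.get(fam, ())),
            class_2_count=len(fam_c2.get(fam, ())),
            class_3_count=len(fam_c3.get(fam, ())),
        )
        for fam in families
    ]


def rank_dynamics(
    rows: Iterable[FamilyDynamicsRow], direction: str, top_k: int | None = None
) -> list[FamilyDynamicsRow]:
    """Rows ordered by expansion (delta desc) or contraction (delta asc).

    Ties are broken by family id; ``top_k`` truncates the list.
    """
    if direction not in ("expanded", "contracted"):
        raise ValidationError(f"direction must be expanded|contracted, got {direction!r}")
    sign = -1 if direction == "expanded" else 1
    ordered = sorted(rows, key=lambda r: (sign * r.delta, r.family_id))
    return ordered[:top_k] if top_k is not None else ordered


def family_overlap(
    families_a: set[str], families_b: set[str]
) -> tuple[int, int, int]:
    """(|A|, |B|, |A intersect B|) of the two species' family repertoires."""
    return len(families_a), len(families_b), len(families_a & families_b)
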