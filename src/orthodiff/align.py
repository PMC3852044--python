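"""Desk-scale local protein alignment with affine gaps.

A thin wrapper around Biopython's :class:`~Bio.Align.PairwiseAligner`
configured BLAST-style: BLOSUM62 scores with a length-``L`` gap costing
``11 + L`` (open 11, extend 1).  The summary row carries a pseudo e-value
from fixed Karlin–Altschul constants (lambda = 0.267, K = 0.041, the
canonical gapped-BLOSUM62 values) so e-value cutoffs are exercisable without
an external search engine; it is an ordering device, not a database-size
calibrated statistic.
"""

from __future__ import annotations

import math

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .types import AMINO_ALPHABET, AlignedPair, AlignmentHit

_LAMBDA = 0.267
_K = 0.041

# gap of length L costs 11 + L  =>  biopython open (first column) = 12
_OPEN = -12.0
_EXTEND = -1.0


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = _OPEN
    aligner.extend_gap_score = _EXTEND
    return aligner


_ALIGNER = _make_aligner()


def _validate_sequence(seq: str, role: str) -> None:
    if not seq:
        raise ValidationError(f"{role} sequence is empty")
    bad = set(seq) - AMINO_ALPHABET
    if bad:
        raise ValidationError(f"{role} sequence has illegal character(s) {sorted(bad)}")


def bit_score(raw_score: float) -> float:
    """Raw alignment score -> bit score under the fixed constants."""
    return (_LAMBDA * raw_score - math.log(_K)) / math.log(2)


def e_value(raw_score: float, m: int, n: int) -> float:
    """Pseudo e-value for a raw score over an ``m x n`` search space."""
    return m * n * 2.0 ** (-bit_score(raw_score))


def local_align(
    seq_a: str,
    seq_b: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> tuple[AlignedPair, AlignmentHit]:
    """Optimal local alignment of two protein sequences.

    Returns the explicit gapped alignment plus a 12-column-style summary row
    (identity %, length, mismatches, gap opens, 1-based coordinates,
    pseudo e-value, bit score).
    """
    _validate_sequence(seq_a, "query")
    _validate_sequence(seq_b, "subject")
    alignments = _ALIGNER.align(seq_a, seq_b)
    aln = alignments[0]
    query_aln = str(aln[0])
    subject_aln = str(aln[1])
    q_offset = int(aln.coordinates[0][0]) + 1
    s_offset = int(aln.coordinates[1][0]) + 1
    pair = AlignedPair(
        query_id=query_id,
        subject_id=subject_id,
        query_aln=query_aln,
        subject_aln=subject_aln,
        q_offset=q_offset,
        s_offset=s_offset,
    )
    hit = summarize_alignment(pair, float(aln.score), len(seq_a), len(seq_b))
    return pair, hit


def summarize_alignment(
    pair: AlignedPair, raw_score: float, m: int, n: int
) -> AlignmentHit:
    """Derive the tabular summary row from an explicit alignment."""
    identities = 0
    mismatches = 0
    gap_opens = 0
    q_res = 0
    s_res = 0
    prev_gap_side = None  # None | "q" | "s"
    for qa, sa in zip(pair.query_aln, pair.subject_aln):
        if qa == "-":
            if prev_gap_side != "q":
                gap_opens += 1
            prev_gap_side = "q"
            s_res += 1
            continue
        if sa == "-":
            if prev_gap_side != "s":
                gap_opens += 1
            prev_gap_side = "s"
            q_res += 1
            continue
        prev_gap_side = None
        q_res += 1
        s_res += 1
        if qa == sa:
            identities += 1
        else:
            mismatches += 1
    length = len(pair.query_aln)
    return AlignmentHit(
        query_id=pair.query_id,
        subject_id=pair.subject_id,
        pct_identity=100.0 * identities / length if length else 0.0,
        aln_length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=pair.q_offset,
        q_end=pair.q_offset + q_res - 1,
        s_start=pair.s_offset,
        s_end=pair.s_offset + s_res - 1,
        e_value=e_value(raw_score, m, n),
        bit_score=bit_score(raw_score),
    )


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Optimal local alignment score only (used by tests and verification)."""
    _validate_sequence(seq_a, "query")
    _validate_sequence(seq_b, "subject")
    return float(_ALIGNER.score(seq_a, seq_b))
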