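"""Large insertion/deletion screening over ortholog pair alignments.

An alignment qualifies when its longest single gap run is strictly longer
than the configured threshold (default 25 columns) and its mismatch
percentage, over the full alignment length, is strictly below the configured
ceiling (default 10%).  A flag switches the gap criterion to the summed-gap
reading for sensitivity analysis.  Polarity is relative to species B (the
subject): a gap run on B's side is a deletion in B, a run on A's side an
insertion in B.  Event coordinates live on the ungapped sequence that
retains the segment, so they compose directly with domain annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import align as _align
from .errors import ValidationError
from .formatting import pct1
from .types import (
    NUCLEOTIDE_ALPHABET,
    AlignedPair,
    DomainAnnotation,
    IndelEvent,
    ThresholdConfig,
)


@dataclass(frozen=True)
class GapRun:
    """A maximal block of gap columns on one side of an alignment.

    ``side`` is "query" or "subject" (which row holds the dashes);
    ``column_start`` is the 1-based alignment column where the run begins.
    """

    side: str
    column_start: int
    length: int


@dataclass(frozen=True)
class GapProfile:
    pair: AlignedPair
    runs: tuple[GapRun, ...]
    total_gap_columns: int
    mismatch_count: int
    identity_count: int

    @property
    def aln_length(self) -> int:
        return len(self.pair)

    @property
    def mismatch_pct(self) -> float:
        return 100.0 * self.mismatch_count / self.aln_length

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identity_count / self.aln_length

    @property
    def max_run_length(self) -> int:
        return max((r.length for r in self.runs), default=0)


def gap_profile(pair: AlignedPair) -> GapProfile:
    """Gap runs, mismatch and identity accounting for one explicit alignment."""
    runs: list[GapRun] = []
    mismatches = 0
    identities = 0
    run_side: str | None = None
    run_start = 0
    run_len = 0

    def close_run() -> None:
        nonlocal run_side, run_len
        if run_side is not None:
            runs.append(GapRun(side=run_side, column_start=run_start, length=run_len))
        run_side = None
        run_len = 0

    for col, (qa, sa) in enumerate(zip(pair.query_aln, pair.subject_aln), start=1):
        if qa == "-" and sa == "-":
            raise ValidationError(
                f"pair {pair.query_id}/{pair.subject_id}: column {col} gapped on both sides"
            )
        side = "query" if qa == "-" else ("subject" if sa == "-" else None)
        if side != run_side:
            close_run()
            if side is not None:
                run_side, run_start, run_len = side, col, 0
        if side is not None:
            run_len += 1
        else:
            if qa == sa:
                identities += 1
            else:
                mismatches += 1
    close_run()
    total_gaps = sum(r.length for r in runs)
    return GapProfile(
        pair=pair,
        runs=tuple(runs),
        total_gap_columns=total_gaps,
        mismatch_count=mismatches,
        identity_count=identities,
    )


def _run_coordinates(profile: GapProfile, run: GapRun) -> tuple[int, int]:
    """1-based inclusive coordinates of a run's segment on its carrier sequence.

    The carrier is the ungapped sequence on the side *opposite* the dashes.
    """
    pair = profile.pair
    if run.side == "subject":
        carrier_aln, offset = pair.query_aln, pair.q_offset
    else:
        carrier_aln, offset = pair.subject_aln, pair.s_offset
    preceding = carrier_aln[: run.column_start - 1]
    start = offset + len(preceding) - preceding.count("-")
    return start, start + run.length - 1


def select_candidates(
    profiles: Iterable[GapProfile],
    config: ThresholdConfig | None = None,
    gap_mode: str = "max_run",
) -> list[IndelEvent]:
    """Apply the large-indel thresholds and emit one event per qualifying run.

    A pair qualifies when its gap criterion exceeds ``config.indel_gap_min``
    (strict) and its mismatch percentage is strictly below
    ``config.indel_mismatch_pct_max``.  With ``gap_mode="max_run"`` (default)
    the criterion is the longest single run and every run longer than the
    threshold becomes an event; ``gap_mode="total"`` gates on summed gap
    columns instead (events are still per-run, all runs reported).
    """
    if gap_mode not in ("max_run", "total"):
        raise ValidationError(f"gap_mode must be max_run|total, got {gap_mode!r}")
    config = config or ThresholdConfig()
    events: list[IndelEvent] = []
    for profile in profiles:
        if profile.mismatch_pct >= config.indel_mismatch_pct_max:
            continue
        if gap_mode == "max_run":
            if profile.max_run_length <= config.indel_gap_min:
                continue
            qualifying = [r for r in profile.runs if r.length > config.indel_gap_min]
        else:
            if profile.total_gap_columns <= config.indel_gap_min:
                continue
            qualifying = list(profile.runs)
        for run in qualifying:
            start, end = _run_coordinates(profile, run)
            events.append(
                IndelEvent(
                    gene_a=profile.pair.query_id,
                    gene_b=profile.pair.subject_id,
                    polarity="deletion_in_b" if run.side == "subject" else "insertion_in_b",
                    start=start,
                    end=end,
                    length=run.length,
                    mismatch_pct=profile.mismatch_pct,
                )
            )
    events.sort(key=lambda e: (e.gene_a, e.gene_b, e.start))
    return events


def domain_overlap(
    event: IndelEvent, domains: Sequence[DomainAnnotation]
) -> list[str]:
    """Domain ids whose interval intersects the event's by >= 1 residue.

    The domains must belong to the protein carrying the segment.
    """
    return sorted(
        {
            d.domain_id
            for d in domains
            if d.start <= event.end and event.start <= d.end
        }
    )


def attach_domains(
    events: Iterable[IndelEvent],
    domains_by_protein: dict[str, Sequence[DomainAnnotation]],
    carrier_protein_of: dict[str, str] | None = None,
) -> list[IndelEvent]:
    """Fill each event's ``overlapping_domains`` from per-protein annotations.

    ``carrier_protein_of`` maps the carrier gene id to its representative
    protein id (identity if omitted).
    """
    out = []
    for event in events:
        carrier = event.carrier
        protein = (
            carrier_protein_of.get(carrier, carrier)
            if carrier_protein_of is not None
            else carrier
        )
        hits = domain_overlap(event, domains_by_protein.get(protein, ()))
        out.append(
            IndelEvent(
                gene_a=event.gene_a,
                gene_b=event.gene_b,
                polarity=event.polarity,
                start=event.start,
                end=event.end,
                length=event.length,
                mismatch_pct=event.mismatch_pct,
                overlapping_domains=tuple(hits),
            )
        )
    return out


def gap_class_summary(profiles: Iterable[GapProfile], small_gap_max: int = 5) -> dict:
    """Pair counts by gap burden, with one-decimal percentages.

    ``gap_free`` pairs have no gap columns at all; ``small_gap`` pairs have at
    most ``small_gap_max`` total gap columns (gap-free pairs included).
    """
    profiles = list(profiles)
    total = len(profiles)
    gap_free = sum(1 for p in profiles if p.total_gap_columns == 0)
    small = sum(1 for p in profiles if p.total_gap_columns <= small_gap_max)
    return {
        "n_pairs": total,
        "n_gap_free": gap_free,
        "gap_free_pct": pct1(gap_free, total),
        "n_small_gap": small,
        "small_gap_pct": pct1(small, total),
    }


# ---------------------------------------------------------------------------
# genome verification

_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class SegmentVerdict:
    present: bool
    frame: int | None = None
    identity_pct: float = 0.0
    coverage_pct: float = 0.0
    nt_start: int | None = None  # 1-based on the forward strand
    nt_end: int | None = None


def six_frame_translations(genome_seq: str) -> dict[int, str]:
    """The six conceptual translations of a nucleotide sequence.

    Stop codons are rendered as ``X`` so downstream alignment stays within the
    protein alphabet (a stop simply scores as a mismatch).
    """
    genome_seq = genome_seq.upper()
    bad = set(genome_seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValidationError(f"genome sequence has illegal character(s) {sorted(bad)}")
    fwd = Seq(genome_seq)
    rev = fwd.reverse_complement()
    out: dict[int, str] = {}
    for frame in _FRAMES:
        strand_seq = fwd if frame > 0 else rev
        offset = abs(frame) - 1
        sub = strand_seq[offset : offset + 3 * ((len(strand_seq) - offset) // 3)]
        out[frame] = str(sub.translate()).replace("*", "X")
    return out


def verify_segment_absence(
    segment: str,
    genome_seq: str,
    min_identity: float = 90.0,
    min_coverage: float = 80.0,
) -> SegmentVerdict:
    """Check whether a protein segment is encoded anywhere in a genome.

    Aligns the segment against all six frame translations; ``present`` iff
    the best local alignment covers at least ``min_coverage`` percent of the
    segment at ``min_identity`` percent identity.
    """
    if len(segment) < 10:
        raise ValidationError("segment must be at least 10 residues long")
    translations = six_frame_translations(genome_seq)
    genome_len = len(genome_seq)
    best = SegmentVerdict(present=False)
    best_key = (-1.0, -1.0)
    for frame, protein in translations.items():
        if not protein:
            continue
        pair, hit = _align.local_align(segment, protein, "segment", f"frame{frame}")
        aligned_residues = hit.q_end - hit.q_start + 1
        coverage = 100.0 * aligned_residues / len(segment)
        identity = hit.pct_identity
        if (coverage, identity) > best_key:
            best_key = (coverage, identity)
            nt_start, nt_end = _frame_to_nt(frame, hit.s_start, hit.s_end, genome_len)
            best = SegmentVerdict(
                present=identity >= min_identity and coverage >= min_coverage,
                frame=frame,
                identity_pct=identity,
                coverage_pct=coverage,
                nt_start=nt_start,
                nt_end=nt_end,
            )
    return best


def _frame_to_nt(
    frame: int, p_start: int, p_end: int, genome_len: int
) -> tuple[int, int]:
    """Protein coordinates in a frame translation -> forward-strand nt coords."""
    offset = abs(frame) - 1
    lo = offset + 3 * (p_start - 1) + 1
    hi = offset + 3 * p_end
    if frame > 0:
        return lo, hi
    return genome_len - hi + 1, genome_len - lo + 1
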