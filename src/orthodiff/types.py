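"""Core domain types shared by every pipeline stage.

All coordinates in this package are 1-based and inclusive (the tabular
pairwise-alignment convention); sequences are uppercase amino-acid strings
over the 20 standard residues plus ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ValidationError

#: The 20 standard amino acids plus the ambiguity code X.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Nucleotide alphabet accepted by the genome-verification step.
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein entry of a proteome FASTA file.

    ``gene_id`` defaults to ``protein_id`` when the proteome has no isoform
    structure; ``pe_rank`` (protein-existence rank, smaller = stronger
    evidence) may be absent.
    """

    protein_id: str
    gene_id: str
    sequence: str
    species: str = ""
    pe_rank: int | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )
        if self.pe_rank is not None and self.pe_rank < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: pe_rank must be >= 1, got {self.pe_rank}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular pairwise-alignment output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: start > end coordinate"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )
        if self.mismatches > self.aln_length:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: mismatches exceed length"
            )


@dataclass(frozen=True)
class AlignedPair:
    """An explicit gapped pairwise alignment of two sequences.

    ``q_offset``/``s_offset`` are the 1-based start coordinates of the aligned
    region on the respective ungapped sequences.
    """

    query_id: str
    subject_id: str
    query_aln: str
    subject_aln: str
    q_offset: int = 1
    s_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.subject_aln):
            raise ValidationError(
                f"aligned pair {self.query_id}/{self.subject_id}: unequal row lengths"
            )
        for i, (qa, sa) in enumerate(zip(self.query_aln, self.subject_aln)):
            if qa == "-" and sa == "-":
                raise ValidationError(
                    f"aligned pair {self.query_id}/{self.subject_id}: "
                    f"column {i + 1} gapped on both sides"
                )

    def __len__(self) -> int:
        return len(self.query_aln)

    def swapped(self) -> "AlignedPair":
        """The same alignment with query and subject roles exchanged."""
        return AlignedPair(
            query_id=self.subject_id,
            subject_id=self.query_id,
            query_aln=self.subject_aln,
            subject_aln=self.query_aln,
            q_offset=self.s_offset,
            s_offset=self.q_offset,
        )


@dataclass(frozen=True)
class ThresholdConfig:
    """Every cutoff the pipeline applies, with published defaults.

    ``ortholog_evalue_max`` and ``family_evalue_max`` are inclusive bounds;
    ``indel_gap_min`` and ``indel_mismatch_pct_max`` are exclusive (a run must
    be strictly longer than ``indel_gap_min`` columns and the mismatch
    percentage strictly below ``indel_mismatch_pct_max``); the enrichment flag
    fires strictly below ``enrichment_p_max``.
    """

    ortholog_evalue_max: float = 1e-6
    family_evalue_max: float = 1e-5
    indel_gap_min: int = 25
    indel_mismatch_pct_max: float = 10.0
    enrichment_p_max: float = 0.01

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"threshold {f.name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown threshold key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            kwargs[key] = int(value) if key == "indel_gap_min" else float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit gene pair between species A and B."""

    gene_a: str
    gene_b: str
    forward_hit: AlignmentHit | None = None
    reverse_hit: AlignmentHit | None = None


@dataclass
class ClassPartition:
    """The three-way gene classification downstream stages consume.

    class_1: shared ortholog pairs; class_2: species-A-only genes;
    class_3: species-B-only genes.
    """

    class_1: set[tuple[str, str]] = field(default_factory=set)
    class_2: set[str] = field(default_factory=set)
    class_3: set[str] = field(default_factory=set)

    @property
    def class_1_a(self) -> set[str]:
        return {a for a, _ in self.class_1}

    @property
    def class_1_b(self) -> set[str]:
        return {b for _, b in self.class_1}

    @property
    def genes_a(self) -> set[str]:
        return self.class_1_a | self.class_2

    @property
    def genes_b(self) -> set[str]:
        return self.class_1_b | self.class_3


@dataclass(frozen=True)
class PathwayNode:
    """A pathway-map module holding one or several functionally similar genes."""

    node_id: str
    label: str = ""
    gene_ids: frozenset[str] = frozenset()


@dataclass
class PathwayGraph:
    """A curated pathway map: gene-holding nodes, directed edges, phenotype sinks.

    Gene sets may be empty only for phenotype nodes (pure outcome boxes).
    """

    pathway_id: str
    nodes: list[PathwayNode]
    edges: list[tuple[str, str]]
    phenotype_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"pathway {self.pathway_id}: duplicate node id(s) {dup}"
            )
        known = set(ids)
        for src, dst in self.edges:
            for end in (src, dst):
                if end not in known:
                    raise ValidationError(
                        f"pathway {self.pathway_id}: edge ({src}, {dst}) "
                        f"references unknown node {end!r}"
                    )
        missing = self.phenotype_nodes - known
        if missing:
            raise ValidationError(
                f"pathway {self.pathway_id}: phenotype node(s) {sorted(missing)} "
                "not declared among nodes"
            )
        for node in self.nodes:
            if not node.gene_ids and node.node_id not in self.phenotype_nodes:
                raise ValidationError(
                    f"pathway {self.pathway_id}: non-phenotype node "
                    f"{node.node_id!r} has an empty gene set"
                )

    @property
    def node_map(self) -> dict[str, PathwayNode]:
        return {n.node_id: n for n in self.nodes}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes:
            out |= node.gene_ids
        return out

    def digraph(self):
        """The graph as a :class:`networkx.DiGraph` (nodes carry gene sets)."""
        import networkx as nx

        g = nx.DiGraph(pathway_id=self.pathway_id)
        for node in self.nodes:
            g.add_node(node.node_id, label=node.label, gene_ids=set(node.gene_ids))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class FamilyAssignment:
    """The single best family hit retained for one protein."""

    protein_id: str
    family_id: str
    e_value: float
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"family assignment {self.protein_id}: negative e-value"
            )


@dataclass(frozen=True)
class FamilyDynamicsRow:
    """Per-family gene counts by orthology class; delta = class_3 - class_2."""

    family_id: str
    class_1_count: int
    class_2_count: int
    class_3_count: int

    @property
    def delta(self) -> int:
        return self.class_3_count - self.class_2_count


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain interval on one protein (1-based inclusive residues)."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain {self.domain_id} on {self.protein_id}: bad interval "
                f"[{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class IndelEvent:
    """A detected insertion/deletion run between an ortholog pair.

    Polarity is relative to species B: ``deletion_in_b`` means the segment is
    present in A and absent in B (the gap run sits on B's side of the
    alignment); ``insertion_in_b`` the reverse.  ``start``/``end`` are 1-based
    inclusive coordinates on the ungapped sequence that retains the segment.
    """

    gene_a: str
    gene_b: str
    polarity: str  # "insertion_in_b" | "deletion_in_b"
    start: int
    end: int
    length: int
    mismatch_pct: float
    overlapping_domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.polarity not in ("insertion_in_b", "deletion_in_b"):
            raise ValidationError(f"bad polarity {self.polarity!r}")
        if self.length != self.end - self.start + 1 or self.length < 1:
            raise ValidationError(
                f"indel {self.gene_a}/{self.gene_b}: length {self.length} "
                f"inconsistent with [{self.start}, {self.end}]"
            )
        if not (0 <= self.mismatch_pct <= 100):
            raise ValidationError("mismatch_pct out of [0, 100]")

    @property
    def carrier(self) -> str:
        """Gene id of the species that retains the segment."""
        return self.gene_a if self.polarity == "deletion_in_b" else self.gene_b
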