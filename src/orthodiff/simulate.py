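"""Paired-proteome simulator with a planted ground-truth ledger.

Emits two related proteomes (shared orthologs as mutated copies, plus
lineage-specific genes), family/domain/pathway/annotation tables, simulated
forward/reverse alignment tables, and ``truth.json`` recording everything
that was planted, so every downstream stage can be scored against a known
answer without any external database.

Determinism: one global integer seed drives a named substream per output
(CRC32 of the stream name mixed into the bit generator), so identical
configs give byte-identical datasets and adding a new output never perturbs
existing ones.  Sequences use a uniform amino-acid composition; simulated
e-values are a documented monotone function of identity and length (ordering
is what matters, not Karlin-Altschul calibration).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .errors import ValidationError
from .orthology import select_representative
from .types import (
    AlignmentHit,
    DomainAnnotation,
    PathwayGraph,
    PathwayNode,
    ProteinRecord,
)

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults give a small, fast dataset."""

    n_shared_genes: int = 100
    n_a_only: int = 30
    n_b_only: int = 20
    mean_protein_length: int = 300
    substitution_rate: float = 0.05
    n_families: int = 8
    family_shared: int = 3
    family_a_extra: int = 2
    family_b_extra: int = 2
    family_expansions: tuple[tuple[int, int], ...] | None = None
    n_indel_pairs: int = 10
    indel_length_min: int = 28
    indel_length_max: int = 40
    fraction_indels_in_domains: float = 0.5
    n_pathways: int = 4
    genes_per_pathway: int = 15
    nodes_per_graph: int = 10
    n_phenotype_nodes: int = 1
    isoform_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_shared_genes",
            "n_a_only",
            "n_b_only",
            "n_families",
            "n_indel_pairs",
            "n_pathways",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("substitution_rate", "fraction_indels_in_domains", "isoform_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_indel_pairs > self.n_shared_genes:
            raise ValidationError("more indel pairs requested than shared genes")
        if not (25 < self.indel_length_min <= self.indel_length_max):
            raise ValidationError(
                "indel lengths must satisfy 25 < indel_length_min <= indel_length_max"
            )
        if self.n_pathways > 0:
            if self.nodes_per_graph < 3:
                raise ValidationError("nodes_per_graph must be >= 3")
            if self.genes_per_pathway < 1:
                raise ValidationError("genes_per_pathway must be >= 1")
        expansions = self.expansions()
        if self.n_families:
            need_shared = sum(1 for _ in expansions) * self.family_shared
            need_a = sum(a for a, _ in expansions)
            need_b = sum(b for _, b in expansions)
            if need_shared > self.n_shared_genes:
                raise ValidationError("family spec needs more shared genes than simulated")
            if need_a > self.n_a_only or need_b > self.n_b_only:
                raise ValidationError("family spec needs more lineage-specific genes than simulated")

    def expansions(self) -> list[tuple[int, int]]:
        if self.family_expansions is not None:
            if len(self.family_expansions) != self.n_families:
                raise ValidationError("family_expansions length must equal n_families")
            return [tuple(e) for e in self.family_expansions]
        return [(self.family_a_extra, self.family_b_extra)] * self.n_families


@dataclass(frozen=True)
class PlantedIndel:
    """Ground truth for one planted contiguous indel."""

    gene_a: str
    gene_b: str
    polarity: str  # insertion_in_b | deletion_in_b
    start: int  # 1-based inclusive, on the segment-retaining sequence
    end: int
    length: int
    in_domain: bool


@dataclass
class TruthLedger:
    """Everything the generator planted, keyed the way analyses report it."""

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    class_2: list[str] = field(default_factory=list)  # A-only genes
    class_3: list[str] = field(default_factory=list)  # B-only genes
    family_of_protein_a: dict[str, str] = field(default_factory=dict)
    family_of_protein_b: dict[str, str] = field(default_factory=dict)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    lost_genes_per_node: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    representatives_a: dict[str, str] = field(default_factory=dict)
    representatives_b: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "ortholog_pairs": sorted(self.ortholog_pairs),
            "class_2": sorted(self.class_2),
            "class_3": sorted(self.class_3),
            "family_of_protein_a": self.family_of_protein_a,
            "family_of_protein_b": self.family_of_protein_b,
            "planted_indels": [asdict(e) for e in self.planted_indels],
            "lost_genes_per_node": self.lost_genes_per_node,
            "representatives_a": self.representatives_a,
            "representatives_b": self.representatives_b,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        payload = json.loads(text)
        return cls(
            ortholog_pairs=[tuple(p) for p in payload["ortholog_pairs"]],
            class_2=payload["class_2"],
            class_3=payload["class_3"],
            family_of_protein_a=payload["family_of_protein_a"],
            family_of_protein_b=payload["family_of_protein_b"],
            planted_indels=[PlantedIndel(**e) for e in payload["planted_indels"]],
            lost_genes_per_node=payload["lost_genes_per_node"],
            representatives_a=payload["representatives_a"],
            representatives_b=payload["representatives_b"],
        )


# ---------------------------------------------------------------------------
# sequence helpers


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = _AMINO[_AMINO != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def _sequence_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    floor = max(80, config.indel_length_max + 70)
    length = int(rng.normal(config.mean_protein_length, 0.1 * config.mean_protein_length))
    return max(floor, length)


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: SimulationConfig, out_dir: str | Path) -> TruthLedger:
    """Write a self-contained synthetic dataset and return its truth ledger."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger = TruthLedger()

    # --- genes and representative sequences
    shared_ids = [
        (f"gA_s{i:04d}", f"gB_s{i:04d}") for i in range(config.n_shared_genes)
    ]
    a_only = [f"gA_u{i:04d}" for i in range(config.n_a_only)]
    b_only = [f"gB_u{i:04d}" for i in range(config.n_b_only)]
    ledger.ortholog_pairs = list(shared_ids)
    ledger.class_2 = list(a_only)
    ledger.class_3 = list(b_only)

    seq_rng = _rng(config.seed, "sequences")
    indel_rng = _rng(config.seed, "indels")
    indel_indices = set(
        indel_rng.choice(config.n_shared_genes, size=config.n_indel_pairs, replace=False)
        .tolist()
        if config.n_indel_pairs
        else []
    )

    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}
    for i, (ga, gb) in enumerate(shared_ids):
        length = _sequence_length(seq_rng, config)
        seq_a = _random_sequence(seq_rng, length)
        seq_b = _mutate(seq_rng, seq_a, config.substitution_rate)
        if i in indel_indices:
            seq_b, event = _plant_indel(indel_rng, ga, gb, seq_a, seq_b, config)
            ledger.planted_indels.append(event)
        seqs_a[ga] = seq_a
        seqs_b[gb] = seq_b
    for gene in a_only:
        seqs_a[gene] = _random_sequence(seq_rng, _sequence_length(seq_rng, config))
    for gene in b_only:
        seqs_b[gene] = _random_sequence(seq_rng, _sequence_length(seq_rng, config))

    # --- isoforms and FASTA emission
    records_a = _emit_isoforms(_rng(config.seed, "isoforms_a"), seqs_a, config, "A")
    records_b = _emit_isoforms(_rng(config.seed, "isoforms_b"), seqs_b, config, "B")
    _io.write_fasta(out / "proteome_a.fasta", records_a)
    _io.write_fasta(out / "proteome_b.fasta", records_b)
    reps_a = select_representative(records_a)
    reps_b = select_representative(records_b)
    ledger.representatives_a = {g: r.protein_id for g, r in sorted(reps_a.items())}
    ledger.representatives_b = {g: r.protein_id for g, r in sorted(reps_b.items())}

    # --- families
    fam_rng = _rng(config.seed, "families")
    rows_a, rows_b = _assign_family_truth(config, ledger, fam_rng)
    _io.write_family_table(out / "families_a.tsv", rows_a)
    _io.write_family_table(out / "families_b.tsv", rows_b)

    # --- domains
    dom_rng = _rng(config.seed, "domains")
    domains_a, domains_b = _plant_domains(dom_rng, config, ledger, seqs_a, seqs_b)
    _io.write_domain_table(out / "domains_a.tsv", domains_a)
    _io.write_domain_table(out / "domains_b.tsv", domains_b)

    # --- pathways
    pw_rng = _rng(config.seed, "pathways")
    membership, graphs = _build_pathways(pw_rng, config, shared_ids, a_only, ledger)
    _io.write_membership_table(out / "membership.tsv", membership)
    for graph in graphs:
        _io.write_pathway_graph(out / f"pathway_{graph.pathway_id}.json", graph)

    # --- annotation of A-only (missing-in-B) genes
    ann_rng = _rng(config.seed, "annotation")
    annotation = {
        gene: (bool(ann_rng.random() < 0.3), bool(ann_rng.random() < 0.5))
        for gene in sorted(a_only)
    }
    _io.write_annotation_table(out / "annotation.tsv", annotation)

    # --- simulated alignment tables (noise-free)
    sim = simulate_alignment_table(records_a, records_b, ledger)
    _io.write_tabular_alignment(out / "alignments_fwd.tsv", sim.forward)
    _io.write_tabular_alignment(out / "alignments_rev.tsv", sim.reverse)

    (out / "truth.json").write_text(ledger.to_json(), encoding="utf-8")
    return ledger


def _plant_indel(
    rng: np.random.Generator,
    gene_a: str,
    gene_b: str,
    seq_a: str,
    seq_b: str,
    config: SimulationConfig,
) -> tuple[str, PlantedIndel]:
    """Apply one contiguous indel to seq_b; coordinates are on the carrier."""
    length = int(rng.integers(config.indel_length_min, config.indel_length_max + 1))
    margin = 30
    deletion = bool(rng.integers(0, 2))
    if deletion:
        pos = int(rng.integers(margin, len(seq_a) - length - margin))
        new_b = seq_b[:pos] + seq_b[pos + length :]
        event = PlantedIndel(
            gene_a=gene_a,
            gene_b=gene_b,
            polarity="deletion_in_b",
            start=pos + 1,
            end=pos + length,
            length=length,
            in_domain=False,
        )
    else:
        pos = int(rng.integers(margin, len(seq_b) - margin))
        segment = _random_sequence(rng, length)
        new_b = seq_b[:pos] + segment + seq_b[pos:]
        event = PlantedIndel(
            gene_a=gene_a,
            gene_b=gene_b,
            polarity="insertion_in_b",
            start=pos + 1,
            end=pos + length,
            length=length,
            in_domain=False,
        )
    return new_b, event


def _emit_isoforms(
    rng: np.random.Generator,
    seqs: dict[str, str],
    config: SimulationConfig,
    species: str,
) -> list[ProteinRecord]:
    records = []
    for gene in sorted(seqs):
        seq = seqs[gene]
        records.append(
            ProteinRecord(
                protein_id=f"{gene}_p1",
                gene_id=gene,
                sequence=seq,
                species=species,
                pe_rank=1,
            )
        )
        if rng.random() < config.isoform_fraction:
            n_extra = int(rng.integers(1, 3))
            for j in range(n_extra):
                if rng.random() < 0.5:
                    cut = max(30, int(len(seq) * rng.uniform(0.4, 0.8)))
                    iso_seq = seq[:cut]
                else:
                    iso_seq = seq + _random_sequence(rng, int(rng.integers(10, 51)))
                records.append(
                    ProteinRecord(
                        protein_id=f"{gene}_p{j + 2}",
                        gene_id=gene,
                        sequence=iso_seq,
                        species=species,
                        pe_rank=int(rng.integers(2, 4)),
                    )
                )
    return records


def _assign_family_truth(
    config: SimulationConfig,
    ledger: TruthLedger,
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Slice disjoint gene pools into families; emit per-species tables."""
    shared_pool = list(ledger.ortholog_pairs)
    a_pool = list(ledger.class_2)
    b_pool = list(ledger.class_3)
    rows_a, rows_b = [], []
    si = ai = bi = 0
    for f, (a_extra, b_extra) in enumerate(config.expansions()):
        fam = f"F{f:03d}"

        def add(protein: str, side: str) -> None:
            e_val = float(10.0 ** -rng.uniform(6, 30))
            bits = float(rng.uniform(50, 300))
            if side == "a":
                rows_a.append((protein, fam, e_val, bits))
                ledger.family_of_protein_a[protein] = fam
            else:
                rows_b.append((protein, fam, e_val, bits))
                ledger.family_of_protein_b[protein] = fam

        for ga, gb in shared_pool[si : si + config.family_shared]:
            add(ledger.representatives_a[ga], "a")
            add(ledger.representatives_b[gb], "b")
        si += config.family_shared
        for gene in a_pool[ai : ai + a_extra]:
            add(ledger.representatives_a[gene], "a")
        ai += a_extra
        for gene in b_pool[bi : bi + b_extra]:
            add(ledger.representatives_b[gene], "b")
        bi += b_extra
    return rows_a, rows_b


def _plant_domains(
    rng: np.random.Generator,
    config: SimulationConfig,
    ledger: TruthLedger,
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
) -> tuple[list[DomainAnnotation], list[DomainAnnotation]]:
    domains_a: list[DomainAnnotation] = []
    domains_b: list[DomainAnnotation] = []
    carriers: set[str] = set()
    updated: list[PlantedIndel] = []
    for idx, event in enumerate(ledger.planted_indels):
        in_domain = bool(rng.random() < config.fraction_indels_in_domains)
        if event.polarity == "deletion_in_b":
            carrier_gene, seq, sink = event.gene_a, seqs_a[event.gene_a], domains_a
            protein = ledger.representatives_a[carrier_gene]
        else:
            carrier_gene, seq, sink = event.gene_b, seqs_b[event.gene_b], domains_b
            protein = ledger.representatives_b[carrier_gene]
        carriers.add(protein)
        if in_domain:
            start = max(1, event.start - int(rng.integers(0, 10)))
            end = min(len(seq), event.end + int(rng.integers(0, 10)))
            sink.append(
                DomainAnnotation(
                    protein_id=protein, domain_id=f"D{idx:03d}", start=start, end=end
                )
            )
        updated.append(
            PlantedIndel(
                gene_a=event.gene_a,
                gene_b=event.gene_b,
                polarity=event.polarity,
                start=event.start,
                end=event.end,
                length=event.length,
                in_domain=in_domain,
            )
        )
    ledger.planted_indels = updated

    # background domains on non-carrier proteins
    for gene in sorted(seqs_a)[::7]:
        protein = ledger.representatives_a[gene]
        if protein in carriers:
            continue
        length = len(seqs_a[gene])
        start = int(rng.integers(1, max(2, length // 2)))
        end = min(length, start + int(rng.integers(20, 60)))
        domains_a.append(
            DomainAnnotation(
                protein_id=protein, domain_id=f"DBG_{gene}", start=start, end=end
            )
        )
    return domains_a, domains_b


def _build_pathways(
    rng: np.random.Generator,
    config: SimulationConfig,
    shared_ids: list[tuple[str, str]],
    a_only: list[str],
    ledger: TruthLedger,
) -> tuple[list[tuple[str, str]], list[PathwayGraph]]:
    membership: list[tuple[str, str]] = []
    graphs: list[PathwayGraph] = []
    class1_a = [a for a, _ in shared_ids]
    missing = set(a_only)
    for p in range(config.n_pathways):
        pid = f"pw{p:02d}"
        n_missing_genes = max(1, config.genes_per_pathway * 3 // 10) if a_only else 0
        n_present = config.genes_per_pathway - n_missing_genes
        chosen_missing = (
            sorted(
                rng.choice(a_only, size=min(n_missing_genes, len(a_only)), replace=False)
                .tolist()
            )
            if n_missing_genes
            else []
        )
        chosen_present = sorted(
            rng.choice(class1_a, size=min(n_present, len(class1_a)), replace=False)
            .tolist()
        )
        genes = chosen_missing + chosen_present
        membership.extend((g, pid) for g in genes)

        n_nodes = config.nodes_per_graph
        n_pheno = min(config.n_phenotype_nodes, max(1, n_nodes - 2))
        gene_nodes = n_nodes - n_pheno
        node_ids = [f"{pid}_n{j:02d}" for j in range(n_nodes)]
        pheno_ids = set(node_ids[gene_nodes:])

        # node 0 gets only missing genes (a guaranteed all_lost lesion when
        # the pathway has missing genes); the rest round-robin
        buckets: list[list[str]] = [[] for _ in range(gene_nodes)]
        for g in chosen_missing[: max(1, len(chosen_missing) // 2)]:
            buckets[0].append(g)
        rest = chosen_missing[max(1, len(chosen_missing) // 2) :] + chosen_present
        for i, g in enumerate(rest):
            if gene_nodes > 1:
                buckets[1 + (i % (gene_nodes - 1))].append(g)
            else:
                buckets[0].append(g)
        # backfill any empty gene node so the graph validates
        pool = list(chosen_present) or list(genes)
        for b, bucket in enumerate(buckets):
            if not bucket:
                bucket.append(pool[b % len(pool)])

        nodes = [
            PathwayNode(
                node_id=node_ids[j],
                label=f"module {j}",
                gene_ids=frozenset(buckets[j]),
            )
            for j in range(gene_nodes)
        ] + [
            PathwayNode(node_id=nid, label="phenotype", gene_ids=frozenset())
            for nid in sorted(pheno_ids)
        ]

        edges: set[tuple[str, str]] = set()
        for j in range(1, gene_nodes):
            parent = int(rng.integers(0, j))
            edges.add((node_ids[parent], node_ids[j]))
        for j in range(gene_nodes):
            for k in range(j + 1, gene_nodes):
                if rng.random() < 0.15:
                    edges.add((node_ids[j], node_ids[k]))
        for nid in sorted(pheno_ids):
            feeder = int(rng.integers(max(1, gene_nodes // 2), gene_nodes))
            edges.add((node_ids[feeder], nid))
            edges.add((node_ids[gene_nodes - 1], nid))

        graph = PathwayGraph(
            pathway_id=pid,
            nodes=nodes,
            edges=sorted(edges),
            phenotype_nodes=pheno_ids,
        )
        graphs.append(graph)
        ledger.lost_genes_per_node[pid] = {
            node.node_id: sorted(node.gene_ids & missing)
            for node in nodes
            if node.gene_ids & missing
        }
    return membership, graphs


# ---------------------------------------------------------------------------
# simulated alignment tables


@dataclass(frozen=True)
class NoiseSpec:
    """Optional imperfections for simulated alignment tables."""

    n_spurious: int = 0
    spurious_evalue: float = 1e-3
    asymmetric_fraction: float = 0.0
    seed: int = 0


@dataclass
class SimulatedAlignments:
    forward: list[AlignmentHit]
    reverse: list[AlignmentHit]
    broken_pairs: list[tuple[str, str]] = field(default_factory=list)


def _pair_identity(seq_a: str, seq_b: str) -> float:
    n = min(len(seq_a), len(seq_b))
    matches = sum(1 for x, y in zip(seq_a[:n], seq_b[:n]) if x == y)
    return 100.0 * matches / n


def _true_hit(qid: str, sid: str, seq_q: str, seq_s: str) -> AlignmentHit:
    identity = _pair_identity(seq_q, seq_s)
    n = min(len(seq_q), len(seq_s))
    bits = identity * n / 25.0
    e_val = max(10.0 ** (-min(identity * n / 500.0, 180.0)), 1e-180)
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        pct_identity=identity,
        aln_length=max(len(seq_q), len(seq_s)),
        mismatches=int(round(n * (1 - identity / 100.0))),
        gap_opens=0 if len(seq_q) == len(seq_s) else 1,
        q_start=1,
        q_end=len(seq_q),
        s_start=1,
        s_end=len(seq_s),
        e_value=e_val,
        bit_score=bits,
    )


def simulate_alignment_table(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    ledger: TruthLedger,
    noise: NoiseSpec | None = None,
) -> SimulatedAlignments:
    """Forward/reverse hit tables in which true pairs are mutual best hits.

    With ``noise`` enabled, spurious cross-hits (screenable by the e-value
    cutoff) and asymmetric-best-hit violations (which remove the affected
    pairs from any RBH result) are added; broken pairs are reported back.
    """
    reps_a = {r.protein_id: r for r in proteome_a if r.protein_id in set(ledger.representatives_a.values())}
    reps_b = {r.protein_id: r for r in proteome_b if r.protein_id in set(ledger.representatives_b.values())}
    forward: list[AlignmentHit] = []
    reverse: list[AlignmentHit] = []
    pair_hits: list[tuple[tuple[str, str], AlignmentHit, AlignmentHit]] = []
    for ga, gb in sorted(ledger.ortholog_pairs):
        pa = ledger.representatives_a[ga]
        pb = ledger.representatives_b[gb]
        seq_a = reps_a[pa].sequence
        seq_b = reps_b[pb].sequence
        fwd = _true_hit(pa, pb, seq_a, seq_b)
        rev = _true_hit(pb, pa, seq_b, seq_a)
        pair_hits.append(((ga, gb), fwd, rev))
        forward.append(fwd)
        reverse.append(rev)

    broken: list[tuple[str, str]] = []
    if noise is not None and pair_hits:
        rng = _rng(noise.seed, "alignment_noise")
        rep_ids_a = sorted(reps_a)
        rep_ids_b = sorted(reps_b)
        for _ in range(noise.n_spurious):
            qa = rep_ids_a[int(rng.integers(0, len(rep_ids_a)))]
            sb = rep_ids_b[int(rng.integers(0, len(rep_ids_b)))]
            forward.append(
                AlignmentHit(
                    query_id=qa,
                    subject_id=sb,
                    pct_identity=30.0,
                    aln_length=60,
                    mismatches=40,
                    gap_opens=2,
                    q_start=1,
                    q_end=60,
                    s_start=1,
                    s_end=60,
                    e_value=noise.spurious_evalue,
                    bit_score=28.0,
                )
            )
        if noise.asymmetric_fraction > 0 and len(pair_hits) > 1:
            n_break = int(round(noise.asymmetric_fraction * len(pair_hits)))
            victims = rng.choice(len(pair_hits), size=n_break, replace=False)
            for vi in sorted(victims.tolist()):
                (ga, gb), fwd, _ = pair_hits[vi]
                other = pair_hits[(vi + 1) % len(pair_hits)]
                decoy_subject = other[1].subject_id
                forward.append(
                    AlignmentHit(
                        query_id=fwd.query_id,
                        subject_id=decoy_subject,
                        pct_identity=fwd.pct_identity,
                        aln_length=fwd.aln_length,
                        mismatches=fwd.mismatches,
                        gap_opens=fwd.gap_opens,
                        q_start=fwd.q_start,
                        q_end=fwd.q_end,
                        s_start=fwd.s_start,
                        s_end=fwd.s_end,
                        e_value=fwd.e_value / 10.0,
                        bit_score=fwd.bit_score + 5.0,
                    )
                )
                broken.append((ga, gb))
    return SimulatedAlignments(forward=forward, reverse=reverse, broken_pairs=broken)
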