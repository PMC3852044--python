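"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* FASTA headers follow the dialect ``>protein_id gene=GENE pe=N``; both
  key=value tokens are optional and ``gene_id`` defaults to the protein id.
* All tables are UTF-8, tab-separated, with a single header line beginning
  ``#``.  Alignment tables are the standard 12-column tabular format
  (query, subject, identity, length, mismatches, gap opens, qstart, qend,
  sstart, send, evalue, bitscore) and carry no header.
* Pathway graphs use a small JSON dialect::

      {"pathway_id": "...",
       "nodes": [{"node_id": "...", "label": "...", "gene_ids": [...]}, ...],
       "edges": [["src", "dst"], ...],
       "phenotype_nodes": ["..."]}

* Every writer sorts rows by a documented key so outputs are byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError
from .types import (
    AlignmentHit,
    DomainAnnotation,
    PathwayGraph,
    PathwayNode,
    ProteinRecord,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Parse a proteome FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and a single trailing ``*`` (stop) is stripped.
    Raises :class:`ParseError` naming the offending line on malformed headers
    and :class:`ValidationError` on empty sequences.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: tuple[int, str] | None = None  # (line number, header text)
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if header is None:
            return
        lineno, text = header
        protein_id, gene_id, pe_rank = _parse_fasta_header(text, path, lineno)
        sequence = "".join(chunks).upper()
        if sequence.endswith("*"):
            sequence = sequence[:-1]
        if not sequence:
            raise ValidationError(
                f"{path}, line {lineno}: record {protein_id!r} has an empty sequence"
            )
        if protein_id in seen:
            raise ValidationError(
                f"{path}, line {lineno}: duplicate protein id {protein_id!r}"
            )
        seen.add(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                gene_id=gene_id,
                sequence=sequence,
                species=species,
                pe_rank=pe_rank,
            )
        )

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = (lineno, line[1:].strip())
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}, line {lineno}: sequence data before first header"
                    )
                chunks.append(line.strip())
    flush()
    return records


def _parse_fasta_header(
    text: str, path: Path, lineno: int
) -> tuple[str, str, int | None]:
    if not text:
        raise ParseError(f"{path}, line {lineno}: empty FASTA header")
    tokens = text.split()
    protein_id = tokens[0]
    gene_id = protein_id
    pe_rank: int | None = None
    for token in tokens[1:]:
        if "=" not in token:
            raise ParseError(
                f"{path}, line {lineno}: malformed header token {token!r} "
                "(expected key=value)"
            )
        key, _, value = token.partition("=")
        if key == "gene":
            gene_id = value
        elif key == "pe":
            try:
                pe_rank = int(value)
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: pe token must be an integer, "
                    f"got {value!r}"
                ) from None
        else:
            raise ParseError(
                f"{path}, line {lineno}: unknown header token key {key!r}"
            )
    return protein_id, gene_id, pe_rank


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    """Write records in the package FASTA dialect, 60 columns per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.protein_id}"
            if rec.gene_id != rec.protein_id:
                header += f" gene={rec.gene_id}"
            if rec.pe_rank is not None:
                header += f" pe={rec.pe_rank}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignment

_ALN_COLUMNS = 12


def read_tabular_alignment(path: str | Path) -> list[AlignmentHit]:
    """Parse standard 12-column tabular alignment output, rows in file order."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with path.open(encoding="utf-8") as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _ALN_COLUMNS:
                raise ParseError(
                    f"{path}, row {rowno}: expected {_ALN_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}, row {rowno}: non-numeric field ({exc})") from None
    return hits


def write_tabular_alignment(path: str | Path, hits: Iterable[AlignmentHit]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# generic TSV tables (single '#' header line)


def _read_tsv(path: Path, n_cols: int) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with path.open(encoding="utf-8") as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}, row {rowno}: expected {n_cols} columns, got {len(parts)}"
                )
            rows.append((rowno, parts))
    return rows


def read_family_table(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Rows of (protein_id, family_id, e_value, bit_score)."""
    path = Path(path)
    out = []
    for rowno, parts in _read_tsv(path, 4):
        try:
            out.append((parts[0], parts[1], float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ParseError(f"{path}, row {rowno}: non-numeric field ({exc})") from None
    return out


def write_family_table(path: str | Path, rows: Iterable[tuple[str, str, float, float]]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#protein_id\tfamily_id\te_value\tbit_score\n")
        for pid, fid, ev, bits in sorted(rows):
            fh.write(f"{pid}\t{fid}\t{ev:.3g}\t{bits:.1f}\n")


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    path = Path(path)
    out = []
    for rowno, parts in _read_tsv(path, 4):
        try:
            out.append(
                DomainAnnotation(
                    protein_id=parts[0],
                    domain_id=parts[1],
                    start=int(parts[2]),
                    end=int(parts[3]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, row {rowno}: non-numeric field ({exc})") from None
    return out


def write_domain_table(path: str | Path, domains: Iterable[DomainAnnotation]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#protein_id\tdomain_id\tstart\tend\n")
        for d in sorted(domains, key=lambda d: (d.protein_id, d.start, d.domain_id)):
            fh.write(f"{d.protein_id}\t{d.domain_id}\t{d.start}\t{d.end}\n")


def read_membership_table(path: str | Path) -> list[tuple[str, str]]:
    """Rows of (gene_id, pathway_id)."""
    path = Path(path)
    return [(p[0], p[1]) for _, p in _read_tsv(path, 2)]


def write_membership_table(path: str | Path, rows: Iterable[tuple[str, str]]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#gene_id\tpathway_id\n")
        for gene, pathway in sorted(rows):
            fh.write(f"{gene}\t{pathway}\n")


def read_annotation_table(path: str | Path) -> dict[str, tuple[bool, bool]]:
    """gene_id -> (phenotype_flag, expression_flag)."""
    path = Path(path)
    out: dict[str, tuple[bool, bool]] = {}
    for rowno, parts in _read_tsv(path, 3):
        for flag in parts[1:]:
            if flag not in ("0", "1"):
                raise ParseError(
                    f"{path}, row {rowno}: flags must be 0/1, got {flag!r}"
                )
        out[parts[0]] = (parts[1] == "1", parts[2] == "1")
    return out


def write_annotation_table(
    path: str | Path, rows: dict[str, tuple[bool, bool]]
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#gene_id\tphenotype_flag\texpression_flag\n")
        for gene in sorted(rows):
            pheno, expr = rows[gene]
            fh.write(f"{gene}\t{int(pheno)}\t{int(expr)}\n")


# ---------------------------------------------------------------------------
# class partition table


def write_class_partition(path: str | Path, partition) -> None:
    """Persist a three-way partition as ``#class gene_a gene_b`` rows.

    Class-2 rows leave gene_b as ``-``; class-3 rows leave gene_a as ``-``.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#class\tgene_a\tgene_b\n")
        for a, b in sorted(partition.class_1):
            fh.write(f"1\t{a}\t{b}\n")
        for gene in sorted(partition.class_2):
            fh.write(f"2\t{gene}\t-\n")
        for gene in sorted(partition.class_3):
            fh.write(f"3\t-\t{gene}\n")


def read_class_partition(path: str | Path):
    from .types import ClassPartition

    path = Path(path)
    partition = ClassPartition()
    for rowno, parts in _read_tsv(path, 3):
        label, gene_a, gene_b = parts
        if label == "1":
            partition.class_1.add((gene_a, gene_b))
        elif label == "2":
            partition.class_2.add(gene_a)
        elif label == "3":
            partition.class_3.add(gene_b)
        else:
            raise ParseError(f"{path}, row {rowno}: unknown class label {label!r}")
    return partition


# ---------------------------------------------------------------------------
# pathway graph JSON


def read_pathway_graph(path: str | Path) -> PathwayGraph:
    """Load one pathway graph from the documented JSON dialect."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from None
    for key in ("pathway_id", "nodes", "edges"):
        if key not in payload:
            raise ParseError(f"{path}: missing required key {key!r}")
    nodes = []
    for entry in payload["nodes"]:
        if "node_id" not in entry:
            raise ParseError(f"{path}: node entry without node_id: {entry!r}")
        nodes.append(
            PathwayNode(
                node_id=entry["node_id"],
                label=entry.get("label", ""),
                gene_ids=frozenset(entry.get("gene_ids", [])),
            )
        )
    edges = [(src, dst) for src, dst in payload["edges"]]
    return PathwayGraph(
        pathway_id=payload["pathway_id"],
        nodes=nodes,
        edges=edges,
        phenotype_nodes=set(payload.get("phenotype_nodes", [])),
    )


def write_pathway_graph(path: str | Path, graph: PathwayGraph) -> None:
    payload = {
        "pathway_id": graph.pathway_id,
        "nodes": [
            {
                "node_id": n.node_id,
                "label": n.label,
                "gene_ids": sorted(n.gene_ids),
            }
            for n in sorted(graph.nodes, key=lambda n: n.node_id)
        ],
        "edges": sorted([list(e) for e in graph.edges]),
        "phenotype_nodes": sorted(graph.phenotype_nodes),
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# key=value config files (threshold overrides for the CLI)


def read_config_overrides(path: str | Path) -> dict[str, str]:
    """Parse a ``key = value`` file (``#`` comments allowed) into a dict."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}, line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
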