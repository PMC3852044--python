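# orthodiff

Two-proteome gain/loss comparison toolkit: reciprocal-best-hit (RBH)
orthology with isoform collapsing, protein-family expansion/contraction
scoring, hypergeometric pathway enrichment at gene and node level,
path-affectedness analysis over pathway graphs, and a large-indel screen
over ortholog alignments. A built-in synthetic-data generator plants a
known ground truth (orthologs, family structure, >25-aa indels, lesioned
pathway nodes) so the whole pipeline is testable end to end without any
external database.

## Pipeline stages

1. **Orthology** (`orthodiff.orthology`) — one representative protein per
   gene (smallest protein-existence rank, then longest sequence), best hits
   at an inclusive e-value cutoff (default `1e-6`), RBH pairing, and the
   three-way partition: class 1 = shared ortholog pairs, class 2 = species-A
   only, class 3 = species-B only.
2. **Family dynamics** (`orthodiff.families`) — one best family per protein
   (smallest e-value, inclusive cutoff `1e-5`), per-family gene counts by
   class, and the signed change `delta = class_3 − class_2` ranking
   expansions and contractions.
3. **Pathway analysis** (`orthodiff.pathways`) — hypergeometric upper-tail
   enrichment of missing (class-2) genes per pathway (flagged at raw
   `p < 0.01`, with a Benjamini–Hochberg column as an extension), node
   statuses (intact / partial / all_lost), and counts of simple
   source-to-phenotype paths that traverse a lesioned node.
4. **Indel scan** (`orthodiff.indels`) — gap-run profiling of explicit
   pairwise alignments; an event requires a single gap run strictly longer
   than 25 columns and mismatch percentage strictly below 10% (a
   `--gap-mode total` flag switches to the summed-gap reading); domain
   overlap reporting and optional six-frame verification of deleted
   segments against a genome sequence.
5. **Alignment engine** (`orthodiff.align`) — local affine-gap alignment
   (BLOSUM62, gap cost `11 + L`) via Biopython, with a pseudo e-value from
   fixed Karlin–Altschul constants so cutoffs are exercisable offline;
   externally produced 12-column tabular alignment files are equally
   supported and are the expected route for real data.
6. **Simulator** (`orthodiff.simulate`) — seeded, byte-deterministic
   datasets plus `truth.json`.

## CLI

```sh
orthodiff --seed 7 simulate --out data/
orthodiff run-all --data-dir data/ --out results/

# or stage by stage
orthodiff orthology --fasta-a a.fasta --fasta-b b.fasta \
    --fwd fwd.tsv --rev rev.tsv --out results/
orthodiff families --families-a fa.tsv --families-b fb.tsv \
    --fasta-a a.fasta --fasta-b b.fasta --classes results/classes.tsv --out results/
orthodiff enrich --membership membership.tsv --classes results/classes.tsv \
    --graph pathway_pw00.json --out results/
orthodiff paths --graph pathway_pw00.json --classes results/classes.tsv --dot --out results/
orthodiff indels --fasta-a a.fasta --fasta-b b.fasta \
    --classes results/classes.tsv --domains-a da.tsv --out results/
```

Thresholds can be overridden with `--config FILE` (lines of
`key = value`, e.g. `ortholog_evalue_max = 1e-10`).

### File formats

- **FASTA** headers: `>protein_id gene=GENE pe=N` (both tokens optional;
  `gene` defaults to the protein id).
- **Alignments**: standard 12-column tab-separated format (query, subject,
  identity, length, mismatches, gap opens, qstart, qend, sstart, send,
  evalue, bitscore). All coordinates 1-based inclusive.
- **Tables** (family, domain, membership, annotation, classes): UTF-8 TSV
  with one `#` header line.
- **Pathway graphs**: a small JSON dialect with `pathway_id`, `nodes`
  (`node_id`, `label`, `gene_ids`), `edges`, and `phenotype_nodes`.

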