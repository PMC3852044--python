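from pathlib import Path

import pytest

from orthodiff.simulate import SimulationConfig, generate_dataset
from orthodiff.types import ClassPartition, FamilyAssignment, ThresholdConfig


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """A small generated dataset shared by read-only tests."""
    out = tmp_path_factory.mktemp("dataset")
    config = SimulationConfig(
        n_shared_genes=60,
        n_a_only=20,
        n_b_only=15,
        n_indel_pairs=6,
        n_families=5,
        seed=11,
    )
    ledger = generate_dataset(config, out)
    return config, out, ledger


def build_family_fixture(specs):
    """Materialise a (partition, assignments, gene_of) triple for given counts.

    ``specs`` maps family_id -> (class_1_count, class_2_count, class_3_count).
    Every gene gets its own protein; class-1 pairs carry the family on the
    species-A side.
    """
    partition = ClassPartition()
    assignments = []
    gene_of = {}

    def protein(gene):
        pid = f"{gene}_p"
        gene_of[pid] = gene
        return pid

    for fam, (c1, c2, c3) in specs.items():
        for i in range(c1):
            ga, gb = f"{fam}.s{i}.a", f"{fam}.s{i}.b"
            partition.class_1.add((ga, gb))
            assignments.append(
                FamilyAssignment(protein_id=protein(ga), family_id=fam, e_value=1e-9)
            )
            protein(gb)  # mapped but unassigned
        for i in range(c2):
            gene = f"{fam}.x{i}"
            partition.class_2.add(gene)
            assignments.append(
                FamilyAssignment(protein_id=protein(gene), family_id=fam, e_value=1e-9)
            )
        for i in range(c3):
            gene = f"{fam}.y{i}"
            partition.class_3.add(gene)
            assignments.append(
                FamilyAssignment(protein_id=protein(gene), family_id=fam, e_value=1e-9)
            )
    return partition, assignments, gene_of


# Regression fixture: family class-count rows with independently known
# expansion ("+") / contraction ("-") magnitudes.
REFERENCE_FAMILY_COUNTS = [
    # (family_id, class_1, class_2, class_3, magnitude, direction)
    ("PF00001", 221, 108, 205, 97, "+"),
    ("PF01454", 11, 18, 45, 27, "+"),
    ("PF00433", 26, 1, 27, 26, "+"),
    ("PF02093", 1, 1, 27, 26, "+"),
    ("PF00012", 13, 0, 23, 23, "+"),
    ("PF01849", 4, 2, 20, 18, "+"),
    ("PF00276", 1, 1, 16, 15, "+"),
    ("PF01282", 2, 2, 16, 14, "+"),
    ("PF05712", 2, 2, 13, 11, "+"),
    ("PF00261", 5, 0, 10, 10, "+"),
    ("PF00153", 46, 8, 17, 9, "+"),
    ("PF00118", 12, 2, 10, 8, "+"),
    ("PF00183", 4, 0, 8, 8, "+"),
    ("PF01015", 1, 1, 9, 8, "+"),
    ("PF01873", 2, 0, 8, 8, "+"),
    ("PF13853", 293, 852, 691, 161, "-"),
    ("PF03402", 2, 99, 3, 96, "-"),
    ("PF00003", 14, 72, 17, 55, "-"),
    ("PF00028", 50, 38, 4, 34, "-"),
    ("PF05296", 4, 32, 2, 30, "-"),
    ("PF08391", 1, 21, 0, 21, "-"),
    ("PF02994", 0, 20, 0, 20, "-"),
    ("PF01157", 1, 32, 13, 19, "-"),
    ("PF13885", 3, 12, 1, 11, "-"),
    ("PF13841", 7, 11, 0, 11, "-"),
    ("PF01198", 1, 16, 6, 10, "-"),
    ("PF01779", 1, 10, 1, 9, "-"),
    ("PF12774", 1, 9, 0, 9, "-"),
    ("PF00879", 0, 9, 1, 8, "-"),
    ("PF00618", 0, 8, 0, 8, "-"),
]
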