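"""Shared fixtures: tiny hand-built triad datasets and ped/map writers."""

import numpy as np
import pytest
from hypothesis import settings

from xtriad.pedio import MarkerMap, TriadDataset, TriadRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def single_snp_map():
    return MarkerMap(
        marker_ids=["rs1"],
        chromosomes=["X"],
        positions_bp=np.array([1000]),
        alleles=[("1", "2")],
    )


def make_triad(fid, mother, father, sex, child):
    """Build a TriadRecord from per-marker allele codes (-1 missing)."""
    mother = np.asarray(mother, dtype=np.int8).reshape(-1, 2)
    father = np.asarray(father, dtype=np.int8).reshape(-1)
    if sex == "male":
        child = np.asarray(child, dtype=np.int8).reshape(-1)
    else:
        child = np.asarray(child, dtype=np.int8).reshape(-1, 2)
    return TriadRecord(
        family_id=fid,
        mother_genotypes=mother,
        father_genotypes=father,
        child_sex=sex,
        child_genotypes=child,
    )


def _repeat_triads(cells, prefix):
    """cells: list of (mother, father, sex, child, count)."""
    triads = []
    i = 0
    for mother, father, sex, child, count in cells:
        for _ in range(count):
            i += 1
            triads.append(make_triad(f"{prefix}{i}", mother, father, sex, child))
    return triads


@pytest.fixture
def males_consistent_dataset(single_snp_map):
    """Complete-data boys' triads exactly at the model's expectations.

    Variant frequency 1/3 and boys' relative risk 2: the ascertained maternal
    cells (hom-variant, het transmit variant, het transmit ref, hom-ref) have
    probabilities 1/6, 1/3, 1/6, 1/3; fathers are an independent margin at
    frequency 1/3.  At N = 180 every empirical margin equals the model value,
    so the joint MLE is (1/3, 2) and the fitted RR equals the transmitted/
    untransmitted ratio from heterozygous mothers (120/60 = 2).
    """
    cells = []
    for mother, child, n in ([[1, 1], 1, 30], [[0, 1], 1, 60],
                             [[0, 1], 0, 30], [[0, 0], 0, 60]):
        cells.append((mother, [1], "male", [child], n // 3))
        cells.append((mother, [0], "male", [child], n - n // 3))
    return TriadDataset(single_snp_map, _repeat_triads(cells, "M"))


@pytest.fixture
def females_consistent_dataset(single_snp_map):
    """Girls' analogue of the consistent fixture (q = 1/3, r = 2).

    For girls the paternal margin is risk-weighted, p_f r_f / S, which at
    these values is exactly 1/2 variant.  Child genotype is {transmitted,
    paternal} unordered.
    """
    cells = []
    for mother, t, n in ([[1, 1], 1, 10], [[0, 1], 1, 20],
                         [[0, 1], 0, 10], [[0, 0], 0, 20]):
        cells.append((mother, [1], "female", [sorted([t, 1])], n // 2))
        cells.append((mother, [0], "female", [sorted([t, 0])], n - n // 2))
    return TriadDataset(single_snp_map, _repeat_triads(cells, "G"))


@pytest.fixture
def balanced_null_dataset(single_snp_map):
    """Boys' triads exactly at the null (q = 1/2, r = 1), 15/15... 16 per cell.

    All four ascertained maternal cells are equiprobable under the null at
    q = 1/2 and fathers are 50/50, so the MLE is r = 1 with LRT exactly 0;
    heterozygous mothers transmit the variant 16 times and the reference 16.
    """
    cells = []
    for mother, child in ([[1, 1], 1], [[0, 1], 1], [[0, 1], 0], [[0, 0], 0]):
        cells.append((mother, [1], "male", [child], 8))
        cells.append((mother, [0], "male", [child], 8))
    return TriadDataset(single_snp_map, _repeat_triads(cells, "N"))


def write_toy_ped_map(tmp_path, ped_rows, map_rows):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    mp.write_text("\n".join(map_rows) + "\n")
    return str(ped), str(mp)


TOY_MAP_ROWS = ["X rs1 0 1000", "23 rs2 0 2000"]

# one complete trio (girl child), two markers
TOY_PED_ROWS = [
    "fam1 dad 0 0 1 1  A A  G G",
    "fam1 mom 0 0 2 1  A C  G T",
    "fam1 kid dad mom 2 2  A C  G G",
]
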