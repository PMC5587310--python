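"""PLINK-style text ped/map input, triad assembly, QC filters and result output.

Genotypes are stored as allele *codes*: indices 0/1 into each marker's sorted
allele-label pair, with -1 for a missing call.  Mothers and girls carry an
unordered pair per marker (shape ``(L, 2)``), fathers and boys a single
hemizygous allele (shape ``(L,)``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoDataError, PedigreeError
from .xmodel import FEMALE, MALE

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"
#: chromosome labels accepted as the X chromosome
X_LABELS = {"X", "23", "x", "chrX", "chr23"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered marker metadata from a .map file."""

    marker_ids: list[str]
    chromosomes: list[str]
    positions_bp: np.ndarray          # (L,) int64, 1-based physical coordinates
    alleles: list[tuple[str, str]]    # per marker, sorted pair of labels

    def __post_init__(self):
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise PedigreeError("marker ids must be unique")
        if np.any(self.positions_bp <= 0):
            raise PedigreeError("positions must be positive 1-based coordinates")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return MarkerMap(
            marker_ids=[self.marker_ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            positions_bp=self.positions_bp[idx],
            alleles=[self.alleles[i] for i in idx],
        )


@dataclass
class TriadRecord:
    """One family: mother, father and affected child at all mapped markers."""

    family_id: str
    mother_genotypes: np.ndarray   # (L, 2) int8, codes, -1 missing
    father_genotypes: np.ndarray   # (L,)  int8
    child_sex: str                 # "male" | "female"
    child_genotypes: np.ndarray    # girls (L, 2); boys (L,)

    def __post_init__(self):
        self.mother_genotypes = np.asarray(self.mother_genotypes, dtype=np.int8)
        self.father_genotypes = np.asarray(self.father_genotypes, dtype=np.int8)
        self.child_genotypes = np.asarray(self.child_genotypes, dtype=np.int8)
        if self.child_sex not in (MALE, FEMALE):
            raise PedigreeError(f"invalid child sex {self.child_sex!r}")

    def member_missing_fractions(self) -> dict[str, float]:
        """Per-member fraction of markers with a missing call."""
        m_miss = np.any(self.mother_genotypes < 0, axis=1)
        f_miss = self.father_genotypes < 0
        if self.child_sex == MALE:
            c_miss = self.child_genotypes < 0
        else:
            c_miss = np.any(self.child_genotypes < 0, axis=1)
        n = len(f_miss)
        return {
            "mother": float(m_miss.mean()) if n else 0.0,
            "father": float(f_miss.mean()) if n else 0.0,
            "child": float(c_miss.mean()) if n else 0.0,
        }

    def subset_markers(self, keep: np.ndarray) -> "TriadRecord":
        return TriadRecord(
            family_id=self.family_id,
            mother_genotypes=self.mother_genotypes[keep],
            father_genotypes=self.father_genotypes[keep],
            child_sex=self.child_sex,
            child_genotypes=self.child_genotypes[keep],
        )


@dataclass
class TriadDataset:
    """A marker map plus the assembled case-parent triads."""

    map: MarkerMap
    triads: list[TriadRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [t.family_id for t in self.triads]
        if len(set(ids)) != len(ids):
            raise PedigreeError("family ids must be unique")

    @property
    def n_triads(self) -> int:
        return len(self.triads)


@dataclass
class QCReport:
    """Counts recorded by :func:`qc_filter`."""

    n_individuals_removed: int
    n_triads_removed_individuals: int
    n_snps_removed_missingness: int
    n_snps_removed_maf: int
    n_triads_retained: int
    ind_missing_max: float
    snp_missing_max: float
    maf_min: float


# ---------------------------------------------------------------------------
# ped/map reading
# ---------------------------------------------------------------------------

def _read_map(map_path) -> tuple[list[str], list[str], np.ndarray]:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedigreeError(
                    f"{map_path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, mid, _cm, bp = parts
            rows.append((chrom, mid, int(bp)))
    if not rows:
        raise PedigreeError(f"{map_path}: no markers")
    chroms = [r[0] for r in rows]
    ids = [r[1] for r in rows]
    pos = np.array([r[2] for r in rows], dtype=np.int64)
    return ids, chroms, pos


def _code_female(a1: str, a2: str, pair: tuple[str, str]) -> tuple[int, int]:
    if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
        return -1, -1
    return pair.index(a1), pair.index(a2)


def _code_male(a1: str, a2: str, pair: tuple[str, str]) -> tuple[int, int]:
    """Collapse a male's pair to one hemizygous allele.

    Returns (code, n_warnings): distinct non-missing alleles are impossible on
    the X, so the call is set missing and counted rather than aborting.
    """
    if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
        return -1, 0
    if a1 != a2:
        return -1, 1
    return pair.index(a1), 0


def read_ped_map(ped_path, map_path) -> TriadDataset:
    """Read PLINK-style text files and assemble complete case-parent triads.

    Individuals that do not form a complete mother-father-child trio are
    dropped (counted in the provenance log).  A child is any individual whose
    paternal and maternal id columns both resolve within its family; extra
    children beyond the first are logged and skipped.  Male X genotypes given
    as a homozygous pair are collapsed to one allele; a male carrying two
    distinct alleles has the call set missing with a counted warning.
    """
    marker_ids, chroms, positions = _read_map(map_path)
    n_markers = len(marker_ids)
    ncols = 6 + 2 * n_markers

    individuals: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != ncols:
                raise PedigreeError(
                    f"{ped_path}: line {lineno}: expected {ncols} columns "
                    f"(6 + 2 per marker), got {len(parts)}"
                )
            fid, iid, pat, mat, sex, _pheno = parts[:6]
            if sex not in ("1", "2"):
                raise PedigreeError(
                    f"{ped_path}: line {lineno}: impossible sex code {sex!r}"
                )
            key = (fid, iid)
            individuals[key] = {
                "pat": pat,
                "mat": mat,
                "sex": MALE if sex == "1" else FEMALE,
                "alleles": parts[6:],
                "line": lineno,
            }
            order.append(key)

    # allele labels per marker, discovered from the data and kept sorted so
    # that code order equals lexicographic label order
    observed: list[set[str]] = [set() for _ in range(n_markers)]
    for rec in individuals.values():
        al = rec["alleles"]
        for j in range(n_markers):
            for a in (al[2 * j], al[2 * j + 1]):
                if a != MISSING_ALLELE:
                    observed[j].add(a)
    alleles: list[tuple[str, str]] = []
    for j, obs in enumerate(observed):
        if len(obs) > 2:
            raise PedigreeError(
                f"marker {marker_ids[j]!r}: more than two alleles observed: {sorted(obs)}"
            )
        if any(len(a) != 1 for a in obs):
            raise PedigreeError(
                f"marker {marker_ids[j]!r}: allele labels must be single characters"
            )
        labs = sorted(obs)
        while len(labs) < 2:          # monomorphic or fully missing marker
            labs.append("." if "." not in labs else "?")
        alleles.append((labs[0], labs[1]))

    marker_map = MarkerMap(marker_ids, chroms, positions, alleles)

    def decode(key, sex):
        al = individuals[key]["alleles"]
        warnings = 0
        if sex == MALE:
            g = np.empty(n_markers, dtype=np.int8)
            for j in range(n_markers):
                g[j], w = _code_male(al[2 * j], al[2 * j + 1], alleles[j])
                warnings += w
        else:
            g = np.empty((n_markers, 2), dtype=np.int8)
            for j in range(n_markers):
                g[j] = _code_female(al[2 * j], al[2 * j + 1], alleles[j])
        return g, warnings

    # assemble triads family by family, preserving file order of children
    triads: list[TriadRecord] = []
    used: set[tuple[str, str]] = set()
    seen_families: set[str] = set()
    n_extra_children = 0
    n_male_het = 0
    for fid, iid in order:
        rec = individuals[(fid, iid)]
        pat_key, mat_key = (fid, rec["pat"]), (fid, rec["mat"])
        if pat_key not in individuals or mat_key not in individuals:
            continue  # not a child of a complete trio
        father, mother = individuals[pat_key], individuals[mat_key]
        if father["sex"] != MALE or mother["sex"] != FEMALE:
            raise PedigreeError(
                f"family {fid!r}: parental sex codes inconsistent with roles"
            )
        if fid in seen_families:
            n_extra_children += 1
            logger.warning("family %r: extra child %r skipped", fid, iid)
            continue
        seen_families.add(fid)
        mg, _ = decode(mat_key, FEMALE)
        fg, w_f = decode(pat_key, MALE)
        cg, w_c = decode((fid, iid), rec["sex"])
        n_male_het += w_f + w_c
        triads.append(
            TriadRecord(
                family_id=fid,
                mother_genotypes=mg,
                father_genotypes=fg,
                child_sex=rec["sex"],
                child_genotypes=cg,
            )
        )
        used.update({(fid, iid), pat_key, mat_key})

    n_dropped = len(individuals) - len(used)
    provenance = [
        f"read {len(individuals)} individuals from {ped_path}; "
        f"assembled {len(triads)} triads; dropped {n_dropped} individuals "
        f"not in a complete trio; skipped {n_extra_children} extra children; "
        f"{n_male_het} male heterozygote calls set missing",
    ]
    ds = TriadDataset(map=marker_map, triads=triads, provenance=provenance)
    ds.n_male_het_warnings = n_male_het
    ds.n_individuals_dropped = n_dropped
    return ds


# ---------------------------------------------------------------------------
# ped/map writing (round-trip of simulated or filtered datasets)
# ---------------------------------------------------------------------------

def write_ped_map(data: TriadDataset, ped_path, map_path) -> None:
    """Write a dataset back to PLINK-style text files.

    Males are written as homozygous pairs; missing calls as ``0 0``; child
    rows reference the parental individual ids (``<fid>_f``, ``<fid>_m``).
    """
    m = data.map
    with open(map_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chromosomes[j]}\t{m.marker_ids[j]}\t0\t{m.positions_bp[j]}\n")

    def fmt_pair(codes, j) -> str:
        a, b = codes
        if a < 0 or b < 0:
            return "0 0"
        pair = m.alleles[j]
        return f"{pair[a]} {pair[b]}"

    def fmt_hemi(code, j) -> str:
        if code < 0:
            return "0 0"
        lab = m.alleles[j][code]
        return f"{lab} {lab}"

    with open(ped_path, "w") as fh:
        for t in data.triads:
            fid = t.family_id
            fa, mo, ch = f"{fid}_f", f"{fid}_m", f"{fid}_c"
            fa_g = " ".join(fmt_hemi(t.father_genotypes[j], j) for j in range(m.n_markers))
            mo_g = " ".join(fmt_pair(t.mother_genotypes[j], j) for j in range(m.n_markers))
            if t.child_sex == MALE:
                ch_g = " ".join(fmt_hemi(t.child_genotypes[j], j) for j in range(m.n_markers))
                ch_sex = "1"
            else:
                ch_g = " ".join(fmt_pair(t.child_genotypes[j], j) for j in range(m.n_markers))
                ch_sex = "2"
            fh.write(f"{fid} {fa} 0 0 1 1 {fa_g}\n")
            fh.write(f"{fid} {mo} 0 0 2 1 {mo_g}\n")
            fh.write(f"{fid} {ch} {fa} {mo} {ch_sex} 2 {ch_g}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def allele_frequencies(data: TriadDataset) -> np.ndarray:
    """Frequency of allele code 1 per marker over all observed X alleles.

    Mothers contribute two alleles, fathers one, boys one and girls two, so
    the count matches the X-chromosome copy number of each member.
    """
    n = data.map.n_markers
    count1 = np.zeros(n)
    total = np.zeros(n)
    for t in data.triads:
        for g in (t.mother_genotypes[:, 0], t.mother_genotypes[:, 1]):
            obs = g >= 0
            count1[obs] += g[obs]
            total[obs] += 1
        obs = t.father_genotypes >= 0
        count1[obs] += t.father_genotypes[obs]
        total[obs] += 1
        if t.child_sex == MALE:
            obs = t.child_genotypes >= 0
            count1[obs] += t.child_genotypes[obs]
            total[obs] += 1
        else:
            for k in (0, 1):
                g = t.child_genotypes[:, k]
                obs = g >= 0
                count1[obs] += g[obs]
                total[obs] += 1
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, count1 / total, np.nan)


def minor_allele_frequencies(data: TriadDataset) -> np.ndarray:
    f = allele_frequencies(data)
    return np.fmin(f, 1.0 - f)


def _snp_missing_fraction(data: TriadDataset) -> np.ndarray:
    """Per-marker fraction of missing calls (one call per individual)."""
    n = data.map.n_markers
    miss = np.zeros(n)
    total = 3 * max(data.n_triads, 1)
    for t in data.triads:
        miss += np.any(t.mother_genotypes < 0, axis=1)
        miss += t.father_genotypes < 0
        if t.child_sex == MALE:
            miss += t.child_genotypes < 0
        else:
            miss += np.any(t.child_genotypes < 0, axis=1)
    return miss / total


def qc_filter(
    data: TriadDataset,
    ind_missing_max: float = 0.10,
    snp_missing_max: float = 0.01,
    maf_min: float = 0.01,
) -> tuple[TriadDataset, QCReport]:
    """Apply the standard QC cascade: individuals, SNP missingness, then MAF.

    Individuals with a missing-call fraction above ``ind_missing_max`` are
    removed first (losing any member removes the whole triad), then SNPs with
    missing fraction above ``snp_missing_max``, then SNPs with minor allele
    frequency below ``maf_min`` computed over all retained X alleles.
    """
    for thr in (ind_missing_max, snp_missing_max, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")

    n_ind_removed = 0
    kept_triads: list[TriadRecord] = []
    for t in data.triads:
        fracs = t.member_missing_fractions()
        bad = [m for m, fr in fracs.items() if fr > ind_missing_max]
        if bad:
            n_ind_removed += len(bad)
        else:
            kept_triads.append(t)
    n_triads_removed = data.n_triads - len(kept_triads)

    stage1 = TriadDataset(map=data.map, triads=kept_triads,
                          provenance=list(data.provenance))
    if stage1.n_triads == 0:
        raise NoDataError("no triads remain after the individual-missingness filter")

    miss = _snp_missing_fraction(stage1)
    keep_miss = miss <= snp_missing_max
    n_snps_miss = int((~keep_miss).sum())

    stage2 = TriadDataset(
        map=stage1.map.subset(keep_miss),
        triads=[t.subset_markers(keep_miss) for t in stage1.triads],
        provenance=stage1.provenance,
    )
    if stage2.map.n_markers == 0:
        raise NoDataError("no SNPs remain after the missingness filter")

    maf = minor_allele_frequencies(stage2)
    keep_maf = np.nan_to_num(maf, nan=0.0) >= maf_min
    n_snps_maf = int((~keep_maf).sum())

    out = TriadDataset(
        map=stage2.map.subset(keep_maf),
        triads=[t.subset_markers(keep_maf) for t in stage2.triads],
        provenance=stage2.provenance
        + [
            f"qc_filter: removed {n_triads_removed} triads "
            f"({n_ind_removed} individuals > {ind_missing_max:.0%} missing), "
            f"{n_snps_miss} SNPs > {snp_missing_max:.0%} missing, "
            f"{n_snps_maf} SNPs with MAF < {maf_min}"
        ],
    )
    if out.map.n_markers == 0:
        raise NoDataError("no SNPs remain after the MAF filter")

    report = QCReport(
        n_individuals_removed=n_ind_removed,
        n_triads_removed_individuals=n_triads_removed,
        n_snps_removed_missingness=n_snps_miss,
        n_snps_removed_maf=n_snps_maf,
        n_triads_retained=out.n_triads,
        ind_missing_max=ind_missing_max,
        snp_missing_max=snp_missing_max,
        maf_min=maf_min,
    )
    return out, report


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

_LIST_COLUMNS = (
    "snp_ids", "positions_bp", "haplotypes", "frequencies",
    "rr_single_dose", "rr_single_ci_low", "rr_single_ci_high",
    "rr_double_dose", "rr_boys", "pruned_haplotypes",
)


def write_results(table, path, format: str = "tsv") -> None:
    """Write a :class:`~xtriad.scan.ScanTable` as TSV or JSON.

    TSV is tab-delimited with a header and ``#``-prefixed metadata lines;
    per-haplotype vectors are comma-joined within a cell.  JSON keeps the
    vectors as arrays and round-trips all numeric fields exactly.
    """
    df = table.table
    if df.empty:
        raise ValueError("refusing to write an empty scan table")
    if format == "tsv":
        out = df.copy()
        for col in _LIST_COLUMNS:
            if col in out.columns:
                out[col] = out[col].map(
                    lambda v: ",".join(
                        f"{x:.8g}" if isinstance(x, float) else str(x) for x in v
                    )
                )
        with open(path, "w") as fh:
            for key, val in table.metadata.items():
                fh.write(f"# {key}: {val}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    elif format == "json":
        payload = {
            "metadata": table.metadata,
            "windows": json.loads(df.to_json(orient="records", double_precision=15)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")
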