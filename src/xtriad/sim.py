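"""Case-parent triad simulator and statistical power estimation.

Triads are drawn *directly* from the ascertained (case-conditional) triad
distribution of the penetrance model: for each sex the probability of a
phased configuration (maternal transmitted, maternal untransmitted, paternal)
is proportional to ``p_t * p_u * p_f`` times the penetrance factor, already
normalized per sex.  For case-only triads this exact sampler is equivalent to
prospective population simulation followed by ascertainment of affected
children, without the rejection loop.

Power is the fraction of simulated replicates whose window-level
likelihood-ratio test rejects at the chosen significance level.  For the
sex-stratified parameterizations the simulated sample size is halved and only
the analyzed sex is generated, mirroring how sex-stratified designs split a
fixed genotyping budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateParameterError, NoDataError
from .fitcore import fit_window
from .pedio import MarkerMap, TriadDataset, TriadRecord
from .xmodel import (
    FEMALE,
    MALE,
    HaplotypeTable,
    PenetranceSpec,
    Window,
    enumerate_haplotypes,
)

#: allele labels used for simulated markers ("2" is the variant allele, so a
#: single-SNP spec with frequencies (1 - maf, maf) has variant frequency maf)
_SIM_ALLELES = ("1", "2")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulation scenario.

    ``haplotype_frequencies`` has length ``2**L`` for a window of L SNPs in
    the lexicographic haplotype order of :func:`~xtriad.xmodel.enumerate_haplotypes`;
    for a single SNP it is ``(1 - maf, maf)``.  ``true_rr_single_dose`` is the
    girls' single-dose relative risk per haplotype (reference entry 1); boys'
    risks follow from the model coupling.
    """

    haplotype_frequencies: tuple
    true_rr_single_dose: tuple
    model: PenetranceSpec = PenetranceSpec()
    n_triads: int = 600
    sex_ratio_cases: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.haplotype_frequencies, float)
        r = np.asarray(self.true_rr_single_dose, float)
        if abs(p.sum() - 1.0) > 1e-10 or np.any(p < 0):
            raise ValueError("haplotype frequencies must be a simplex vector")
        if len(p) != len(r):
            raise ValueError("frequencies and relative risks must align")
        n_loci = math.log2(len(p))
        if n_loci != int(n_loci) or not 1 <= n_loci <= 4:
            raise ValueError("need 2**L haplotypes for a window of 1..4 SNPs")
        if self.n_triads < 1:
            raise ValueError("n_triads must be >= 1")
        for rate in (self.sex_ratio_cases, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return int(math.log2(len(self.haplotype_frequencies)))


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate for one scenario."""

    power: float
    mc_se: float
    n_replicates: int
    n_failed: int
    alpha: float
    spec: SimSpec

    def __post_init__(self):
        expected = math.sqrt(self.power * (1.0 - self.power) / self.n_replicates)
        if abs(self.mc_se - expected) > 1e-12:
            raise ValueError("mc_se inconsistent with power and n_replicates")


def _sim_marker_map(n_loci: int) -> MarkerMap:
    return MarkerMap(
        marker_ids=[f"sim{j + 1}" for j in range(n_loci)],
        chromosomes=["X"] * n_loci,
        positions_bp=np.arange(1, n_loci + 1) * 100_000,
        alleles=[_SIM_ALLELES] * n_loci,
    )


def _case_config_distribution(spec: SimSpec, sex: str):
    """Normalized distribution over phased (t, u, f) cells for one sex."""
    p = np.asarray(spec.haplotype_frequencies, float)
    r = np.asarray(spec.true_rr_single_dose, float)
    h = len(p)
    t, u, f = np.unravel_index(np.arange(h ** 3), (h, h, h))
    base = p[t] * p[u] * p[f]
    if sex == MALE:
        rm = spec.model.male_rr(r)
        weights = base * rm[t]
    else:
        weights = base * r[t] * r[f]
    total = weights.sum()
    if total <= 0:
        raise DegenerateParameterError(
            "case-triad distribution has zero mass; a relative risk demands "
            "support on a zero-frequency haplotype"
        )
    return np.column_stack([t, u, f]), weights / total


def simulate_triads(spec: SimSpec, rng=None, sexes=None) -> TriadDataset:
    """Draw ``n_triads`` case-parent triads from the penetrance model.

    Child sexes are Bernoulli(``sex_ratio_cases``) unless given explicitly;
    each triad's phased configuration is then drawn from the exact
    case-conditional cell distribution for its sex, unphased (mothers and
    girls reported as unordered pairs) and masked at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    marker_map = _sim_marker_map(spec.n_loci)
    window = Window(0, spec.n_loci, tuple(marker_map.marker_ids))
    codes = enumerate_haplotypes(window, marker_map).allele_codes

    if sexes is None:
        sexes = np.where(
            rng.random(spec.n_triads) < spec.sex_ratio_cases, MALE, FEMALE
        )
    else:
        sexes = np.asarray(sexes)
        if len(sexes) != spec.n_triads:
            raise ValueError("sexes must have length n_triads")

    cfg_by_sex = {}
    for sex in (MALE, FEMALE):
        n_sex = int(np.sum(sexes == sex))
        if n_sex == 0:
            continue
        cells, probs = _case_config_distribution(spec, sex)
        draws = rng.choice(len(probs), size=n_sex, p=probs)
        cfg_by_sex[sex] = iter(cells[draws])

    triads = []
    for i, sex in enumerate(sexes):
        t, u, f = next(cfg_by_sex[sex])
        mother = np.sort(np.column_stack([codes[t], codes[u]]), axis=1).astype(np.int8)
        father = codes[f].astype(np.int8).copy()
        if sex == MALE:
            child = codes[t].astype(np.int8).copy()
        else:
            child = np.sort(np.column_stack([codes[t], codes[f]]), axis=1).astype(np.int8)
        if spec.missing_rate > 0:
            mother[rng.random(spec.n_loci) < spec.missing_rate] = -1
            father[rng.random(spec.n_loci) < spec.missing_rate] = -1
            cmask = rng.random(spec.n_loci) < spec.missing_rate
            child[cmask] = -1
        triads.append(
            TriadRecord(
                family_id=f"F{i + 1:06d}",
                mother_genotypes=mother,
                father_genotypes=father,
                child_sex=str(sex),
                child_genotypes=child,
            )
        )
    return TriadDataset(
        map=marker_map,
        triads=triads,
        provenance=[f"simulated: {spec}"],
    )


def simulate_independent_snps(
    mafs, rr_variant, model: PenetranceSpec, n_triads: int, seed: int,
    missing_rate: float = 0.0, sex_ratio_cases: float = 0.5,
) -> TriadDataset:
    """A multi-SNP dataset of mutually independent markers (no LD).

    ``mafs`` and ``rr_variant`` give per-SNP variant frequencies and variant
    single-dose relative risks.  Child sex is drawn once per family and shared
    across SNPs.  Intended for null chromosome scans and planted-effect tests.
    """
    mafs = np.atleast_1d(np.asarray(mafs, float))
    rrs = np.broadcast_to(np.asarray(rr_variant, float), mafs.shape)
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n_triads) < sex_ratio_cases, MALE, FEMALE)

    per_snp = []
    for maf, rr in zip(mafs, rrs):
        snp_spec = SimSpec(
            haplotype_frequencies=(1.0 - maf, maf),
            true_rr_single_dose=(1.0, rr),
            model=model,
            n_triads=n_triads,
            missing_rate=missing_rate,
        )
        per_snp.append(simulate_triads(snp_spec, rng=rng, sexes=sexes))

    n_snps = len(per_snp)
    marker_map = MarkerMap(
        marker_ids=[f"snp{j + 1}" for j in range(n_snps)],
        chromosomes=["X"] * n_snps,
        positions_bp=np.arange(1, n_snps + 1) * 100_000,
        alleles=[_SIM_ALLELES] * n_snps,
    )
    triads = []
    for i in range(n_triads):
        parts = [ds.triads[i] for ds in per_snp]
        sex = parts[0].child_sex
        triads.append(
            TriadRecord(
                family_id=f"F{i + 1:06d}",
                mother_genotypes=np.vstack([p.mother_genotypes for p in parts]),
                father_genotypes=np.concatenate([p.father_genotypes for p in parts]),
                child_sex=sex,
                child_genotypes=(
                    np.concatenate([p.child_genotypes for p in parts])
                    if sex == MALE
                    else np.vstack([p.child_genotypes for p in parts])
                ),
            )
        )
    return TriadDataset(map=marker_map, triads=triads,
                        provenance=[f"simulated {n_snps} independent SNPs"])


def _stratified_sim_spec(spec: SimSpec) -> SimSpec:
    """Halve the sample and fix the sex for sex-stratified analyses."""
    if spec.model.model == "males_only":
        return replace(spec, n_triads=max(spec.n_triads // 2, 1),
                       sex_ratio_cases=1.0)
    if spec.model.model == "females_only":
        return replace(spec, n_triads=max(spec.n_triads // 2, 1),
                       sex_ratio_cases=0.0)
    return spec


def estimate_power(
    spec: SimSpec,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    min_freq: float = 0.01,
) -> PowerResult:
    """Monte-Carlo power of the window-level LRT under ``spec``.

    Each replicate simulates a dataset, fits the matching model and records
    whether the overall LRT p-value falls below ``alpha``.  Replicates whose
    fit fails or does not converge are excluded (and counted).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sim_spec = _stratified_sim_spec(spec)
    marker_map = _sim_marker_map(sim_spec.n_loci)
    window = Window(0, sim_spec.n_loci, tuple(marker_map.marker_ids))
    streams = np.random.SeedSequence(spec.seed).spawn(n_replicates)

    n_reject = 0
    n_failed = 0
    n_used = 0
    for ss in streams:
        data = simulate_triads(sim_spec, rng=np.random.default_rng(ss))
        try:
            fit = fit_window(data, window, spec.model, min_freq=min_freq,
                             compute_ci=False)
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        n_used += 1
        if fit.p_value < alpha:
            n_reject += 1
    if n_used == 0:
        raise NoDataError("all replicates failed to fit")
    power = n_reject / n_used
    return PowerResult(
        power=power,
        mc_se=math.sqrt(power * (1.0 - power) / n_used),
        n_replicates=n_used,
        n_failed=n_failed,
        alpha=alpha,
        spec=spec,
    )


def power_grid(
    rr_values,
    maf_values,
    n_values,
    model_list,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Power over the Cartesian grid of scenarios, one row per cell.

    Cell seeds are derived deterministically from the master seed, so the
    grid is reproducible and insensitive to evaluation order.
    """
    rr_values = list(rr_values)
    maf_values = list(maf_values)
    n_values = list(n_values)
    model_list = [
        m if isinstance(m, PenetranceSpec) else PenetranceSpec(m)
        for m in model_list
    ]
    if not (rr_values and maf_values and n_values and model_list):
        raise ValueError("all grid dimensions must be non-empty")

    rows = []
    cell = 0
    for model in model_list:
        for rr in rr_values:
            for maf in maf_values:
                for n in n_values:
                    cell_seed = int(
                        np.random.SeedSequence([seed, cell]).generate_state(1)[0]
                        % (2 ** 31)
                    )
                    cell += 1
                    spec = SimSpec(
                        haplotype_frequencies=(1.0 - maf, maf),
                        true_rr_single_dose=(1.0, rr),
                        model=model,
                        n_triads=n,
                        seed=cell_seed,
                    )
                    row = {"model": model.model, "rr": rr, "maf": maf, "n": n,
                           "alpha": alpha, "seed": cell_seed}
                    try:
                        res = estimate_power(spec, n_replicates=n_replicates,
                                             alpha=alpha)
                        row.update(power=res.power, mc_se=res.mc_se,
                                   n_replicates=res.n_replicates,
                                   n_failed=res.n_failed, failure="")
                    except Exception as exc:  # propagate as missing with reason
                        row.update(power=np.nan, mc_se=np.nan,
                                   n_replicates=0, n_failed=n_replicates,
                                   failure=str(exc))
                    rows.append(row)
    return pd.DataFrame(rows)
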