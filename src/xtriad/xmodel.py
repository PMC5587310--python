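"""X-linked penetrance model for case-parent triads.

A triad consists of an affected child and its two parents, genotyped at a
window of 1-4 contiguous biallelic X-chromosome SNPs.  Mothers are diploid,
fathers hemizygous; boys inherit their single X from the mother, girls one X
from each parent.  A fully phased explanation of a family (a
:class:`TriadConfig`) names the maternal transmitted and untransmitted
haplotypes and the paternal haplotype.

Conditional on the child being affected and of known sex, and assuming random
mating with haplotype frequencies ``p`` shared between eggs and sperm, the
probability of a configuration is

* girls:  ``p_t * p_u * p_f * r_t * r_f / C_f``  with  ``C_f = (sum_h p_h r_h)**2``
* boys:   ``p_t * p_u * p_f * r_t^(m) / C_m``     with  ``C_m = sum_h p_h r_h^(m)``

where ``r_h`` is the relative risk of a single dose of haplotype ``h`` in
girls (reference haplotype fixed at 1) and the boys' relative risk
``r_h^(m)`` is coupled to ``r_h`` by the X-inactivation assumption:
``r_h^(m) = r_h**2`` with X-inactivation (a hemizygous boy is like a
double-dose girl) and ``r_h^(m) = r_h`` without (like a single-dose girl).
The dose-response in girls is multiplicative: the double-dose relative risk
is the square of the single-dose one.  Sex-specific baseline prevalences
cancel in these conditional probabilities, so case-only triads carry no
information about them and they are not parameters of the model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateParameterError, TooAmbiguousError

MALE = "male"
FEMALE = "female"

#: the four supported model parameterizations
MODELS = ("no_xinactivation", "xinactivation", "males_only", "females_only")

#: default cap on the number of phased explanations per family
DEFAULT_CONFIG_CAP = 65_536


def double_dose_rr(single_dose_rr):
    """Double-dose relative risk implied by the multiplicative dose-response.

    Two copies of a haplotype multiply the risk twice, so the double-dose
    relative risk is the square of the single-dose one.
    """
    return np.square(single_dose_rr)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A run of 1-4 contiguous markers analyzed as one haplotype unit."""

    start_index: int
    length: int
    marker_ids: tuple[str, ...]

    def __post_init__(self):
        if not 1 <= self.length <= 4:
            raise ValueError(f"window length must be in 1..4, got {self.length}")
        if len(self.marker_ids) != self.length:
            raise ValueError("marker_ids length must equal window length")
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length


@dataclass
class HaplotypeTable:
    """Candidate haplotypes of a window with their population frequencies.

    ``haplotypes`` are allele strings (one character per locus),
    ``allele_codes`` the same haplotypes as 0/1 indices into each marker's
    sorted allele pair.  ``reference_index`` is set once a reference
    haplotype has been chosen (the most frequent under the null fit).
    """

    haplotypes: list[str]
    allele_codes: np.ndarray  # (H, L) int8
    frequencies: np.ndarray   # (H,) float, simplex
    reference_index: int | None = None

    def __post_init__(self):
        self.allele_codes = np.asarray(self.allele_codes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != len(set(self.haplotypes)):
            raise ValueError("haplotypes must be distinct")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-10:
            raise ValueError("frequencies must sum to 1")
        if self.reference_index is not None and not (
            0 <= self.reference_index < len(self.haplotypes)
        ):
            raise ValueError("reference_index out of range")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class PenetranceSpec:
    """Which parameterization of the X-linked penetrance model is fitted.

    The dose-response in girls is always multiplicative; ``model`` selects
    the boy/girl coupling or restricts to one sex.
    """

    model: str = "no_xinactivation"
    dose_response: str = "multiplicative"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.dose_response != "multiplicative":
            raise ValueError("only the multiplicative dose-response is supported")

    def includes_sex(self, sex: str) -> bool:
        if self.model == "males_only":
            return sex == MALE
        if self.model == "females_only":
            return sex == FEMALE
        return True

    def male_rr(self, single_dose_rr):
        """Boys' relative risks implied by the X-inactivation coupling."""
        r = np.asarray(single_dose_rr, dtype=None)
        if self.model == "xinactivation":
            return r * r
        if self.model == "females_only":
            raise ValueError("females_only model has no male relative risks")
        # no_xinactivation couples boys to a single dose; males_only
        # estimates the boys' risks directly.
        return r


@dataclass
class RiskParams:
    """Single-dose relative risks per haplotype, reference fixed at 1."""

    single_dose_rr: np.ndarray
    reference_index: int

    def __post_init__(self):
        self.single_dose_rr = np.asarray(self.single_dose_rr, dtype=float)
        r = self.single_dose_rr
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("relative risks must be finite and positive")
        if r[self.reference_index] != 1.0:
            raise ValueError("reference relative risk must be exactly 1")


@dataclass(frozen=True)
class TriadConfig:
    """One fully phased explanation of a family within a window."""

    maternal_transmitted: int
    maternal_untransmitted: int
    paternal: int
    child_sex: str


# ---------------------------------------------------------------------------
# haplotype and configuration enumeration
# ---------------------------------------------------------------------------

def enumerate_haplotypes(window: Window, marker_map) -> HaplotypeTable:
    """All ``2**length`` haplotypes of a window, uniform initial frequencies.

    Ordering is lexicographic by allele label per locus (the allele pairs in
    the map are kept sorted, so code order equals label order).
    """
    pairs = [marker_map.alleles[j] for j in range(window.start_index, window.stop_index)]
    haps = ["".join(combo) for combo in itertools.product(*pairs)]
    codes = np.array(
        list(itertools.product(*[range(2)] * window.length)), dtype=np.int8
    )
    h = len(haps)
    return HaplotypeTable(
        haplotypes=haps,
        allele_codes=codes,
        frequencies=np.full(h, 1.0 / h),
    )


def enumerate_configs(
    triad,
    window: Window,
    haps: HaplotypeTable,
    cap: int = DEFAULT_CONFIG_CAP,
) -> list[TriadConfig]:
    """All phased explanations of one family consistent with its genotypes.

    Missing calls impose no constraint; an empty list signals a Mendelian
    inconsistency for this window.  Genotypes are matched per locus: the
    mother's unordered pair must equal {transmitted, untransmitted}, the
    father's hemizygous allele the paternal haplotype, a boy's allele the
    maternal transmitted haplotype and a girl's unordered pair
    {maternal transmitted, paternal}.
    """
    lo, hi = window.start_index, window.stop_index
    a = haps.allele_codes  # (H, L) of 0/1
    h = haps.n_haplotypes

    mg = triad.mother_genotypes[lo:hi]  # (L, 2)
    fg = triad.father_genotypes[lo:hi]  # (L,)

    # mother: for biallelic 0/1 codes an unordered pair is determined by its sum
    ok_mother = np.ones((h, h), dtype=bool)
    for j in range(window.length):
        if mg[j, 0] >= 0 and mg[j, 1] >= 0:
            s = int(mg[j, 0] + mg[j, 1])
            ok_mother &= (a[:, j][:, None] + a[:, j][None, :]) == s

    ok_father = np.ones(h, dtype=bool)
    obs_f = fg >= 0
    if obs_f.any():
        ok_father = np.all(a[:, obs_f] == fg[obs_f], axis=1)

    if triad.child_sex == MALE:
        cg = triad.child_genotypes[lo:hi]  # (L,)
        obs_c = cg >= 0
        ok_t = np.ones(h, dtype=bool)
        if obs_c.any():
            ok_t = np.all(a[:, obs_c] == cg[obs_c], axis=1)
        mask = ok_mother[:, :, None] & ok_t[:, None, None] & ok_father[None, None, :]
    else:
        cg = triad.child_genotypes[lo:hi]  # (L, 2)
        ok_tf = np.ones((h, h), dtype=bool)
        for j in range(window.length):
            if cg[j, 0] >= 0 and cg[j, 1] >= 0:
                s = int(cg[j, 0] + cg[j, 1])
                ok_tf &= (a[:, j][:, None] + a[:, j][None, :]) == s
        mask = ok_mother[:, :, None] & ok_tf[:, None, :] & ok_father[None, None, :]

    n_cfg = int(mask.sum())
    if n_cfg > cap:
        raise TooAmbiguousError(
            f"family {triad.family_id!r}: {n_cfg} phased explanations exceed cap {cap}"
        )
    idx = np.argwhere(mask)
    return [
        TriadConfig(int(t), int(u), int(f), triad.child_sex) for t, u, f in idx
    ]


# ---------------------------------------------------------------------------
# cell probabilities and log-likelihood
# ---------------------------------------------------------------------------

def _normalizers(p: np.ndarray, r: np.ndarray, spec: PenetranceSpec):
    """(C_male, C_female) normalizing constants; None where sex is excluded."""
    c_m = c_f = None
    if spec.model != "females_only":
        rm = spec.male_rr(r)
        c_m = float(np.dot(p, rm))
    if spec.model != "males_only":
        c_f = float(np.dot(p, r)) ** 2
    return c_m, c_f


def cell_probability(
    config: TriadConfig,
    haps: HaplotypeTable,
    params: RiskParams,
    spec: PenetranceSpec,
) -> float:
    """Probability of one phased triad configuration given the child's sex.

    Configurations of a given sex sum to one over all H**3 cells.
    """
    if not spec.includes_sex(config.child_sex):
        raise ValueError(
            f"model {spec.model!r} excludes {config.child_sex} children"
        )
    p = haps.frequencies
    r = params.single_dose_rr
    t, u, f = config.maternal_transmitted, config.maternal_untransmitted, config.paternal
    base = p[t] * p[u] * p[f]
    c_m, c_f = _normalizers(p, r, spec)
    if config.child_sex == MALE:
        if c_m is None or c_m <= 0:
            raise DegenerateParameterError("male normalizer is zero")
        return float(base * spec.male_rr(r)[t] / c_m)
    if c_f is None or c_f <= 0:
        raise DegenerateParameterError("female normalizer is zero")
    return float(base * r[t] * r[f] / c_f)


def loglik(
    families: Sequence[tuple],
    haps: HaplotypeTable,
    params: RiskParams,
    spec: PenetranceSpec,
) -> float:
    """Observed-data log-likelihood.

    ``families`` is a sequence of ``(TriadRecord, configs)`` pairs; each
    family contributes the log of the sum of its configurations' cell
    probabilities (missing genotypes are thereby summed out).
    """
    total = 0.0
    for record, configs in families:
        if not configs:
            raise ValueError(
                f"family {record.family_id!r} has no compatible configuration; "
                "exclude Mendelian-inconsistent families upstream"
            )
        if not spec.includes_sex(record.child_sex):
            raise ValueError(
                f"family {record.family_id!r} does not match the sex restriction "
                f"of model {spec.model!r}"
            )
        fam = sum(cell_probability(c, haps, params, spec) for c in configs)
        total += math.log(fam)
    if not math.isfinite(total):
        raise DegenerateParameterError("log-likelihood is not finite")
    return total
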