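"""Maximum-likelihood fitting of the X-linked triad model for one window.

The null model (all relative risks equal to 1) is a pure haplotype-frequency
problem and is maximized by EM with a closed-form M-step.  The full model is
maximized by quasi-Newton optimization of the observed-data log-likelihood in
transformed coordinates (softmax for the frequency simplex, log for the
relative risks, reference fixed at 0), started from the null fit.  Gradients
use complex-step differentiation, which is exact to machine precision;
standard errors come from the inverse of a central-difference observed
information matrix, giving Wald confidence intervals on the log-risk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateParameterError,
    NoDataError,
    WindowUninformativeError,
)
from .xmodel import (
    FEMALE,
    MALE,
    HaplotypeTable,
    PenetranceSpec,
    RiskParams,
    TriadConfig,
    enumerate_configs,
    enumerate_haplotypes,
)

_Z95 = float(stats.norm.ppf(0.975))
_LOG_RR_CAP = 15.0          # |log r| bound; hit => separation flag
_EM_TOL = 1e-8
_EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# packed family representation
# ---------------------------------------------------------------------------

class _Packed:
    """Families grouped by identical (sex, configuration-set) pattern.

    Identical patterns contribute identical likelihood terms, so each unique
    pattern is evaluated once and weighted by its multiplicity.  Configuration
    rows of all groups are stacked into one ``(M, 3)`` array so the whole
    likelihood is a handful of vectorized operations.
    """

    def __init__(self, families):
        groups: dict[tuple, int] = {}
        for record, configs in families:
            if not configs:
                raise ValueError(
                    f"family {record.family_id!r} has no compatible configuration"
                )
            key = (
                record.child_sex,
                tuple(
                    sorted(
                        (c.maternal_transmitted, c.maternal_untransmitted, c.paternal)
                        for c in configs
                    )
                ),
            )
            groups[key] = groups.get(key, 0) + 1

        cfg_rows, starts, counts, male_groups = [], [], [], []
        pos = 0
        for (sex, triples), count in groups.items():
            starts.append(pos)
            counts.append(count)
            male_groups.append(sex == MALE)
            cfg_rows.extend(triples)
            pos += len(triples)

        self.cfg = np.asarray(cfg_rows, dtype=np.int64)            # (M, 3)
        self.starts = np.asarray(starts, dtype=np.int64)           # (G,)
        self.counts = np.asarray(counts, dtype=float)              # (G,)
        self.group_sizes = np.diff(np.append(self.starts, len(self.cfg)))
        self.group_index = np.repeat(
            np.arange(len(self.starts)), self.group_sizes
        )
        self.cfg_is_male = np.asarray(male_groups)[self.group_index]
        self.n_families = int(self.counts.sum())
        self.has_male = bool(np.any(male_groups))
        self.has_female = not all(male_groups)


def _packed_loglik(packed: _Packed, p, r, spec: PenetranceSpec):
    """Observed-data log-likelihood; complex-safe for complex-step gradients."""
    t, u, f = packed.cfg[:, 0], packed.cfg[:, 1], packed.cfg[:, 2]
    base = p[t] * p[u] * p[f]
    fac = np.ones(len(base), dtype=np.result_type(p, r))
    if packed.has_male:
        rm = spec.male_rr(r)
        c_m = (p * rm).sum()
        mm = packed.cfg_is_male
        fac[mm] = rm[t[mm]] / c_m
    if packed.has_female:
        s = (p * r).sum()
        ff = ~packed.cfg_is_male
        fac[ff] = r[t[ff]] * r[f[ff]] / (s * s)
    fam = np.add.reduceat(base * fac, packed.starts)
    return (packed.counts * np.log(fam)).sum()


# ---------------------------------------------------------------------------
# null fit (EM over haplotype frequencies)
# ---------------------------------------------------------------------------

def _em_null(packed: _Packed, n_haps: int, start=None,
             tol: float = _EM_TOL, max_iter: int = _EM_MAX_ITER):
    """EM for haplotype frequencies with all relative risks fixed at 1.

    E-step weights each family's configurations by the current frequency
    products; the M-step is the weighted count of haplotypes appearing in the
    transmitted/untransmitted/paternal slots (three draws per family).
    Returns (frequencies, loglik trace, converged).
    """
    p = np.full(n_haps, 1.0 / n_haps) if start is None else np.asarray(start, float)
    t, u, f = packed.cfg[:, 0], packed.cfg[:, 1], packed.cfg[:, 2]
    trace = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        w = p[t] * p[u] * p[f]
        fam = np.add.reduceat(w, packed.starts)
        if np.any(fam <= 0):
            raise DegenerateParameterError("a family has zero total probability")
        ll = float((packed.counts * np.log(fam)).sum())
        trace.append(ll)
        wn = w / fam[packed.group_index] * packed.counts[packed.group_index]
        counts = np.bincount(
            packed.cfg.ravel(), weights=np.repeat(wn, 3), minlength=n_haps
        )
        p_new = counts / (3.0 * packed.n_families)
        if ll - prev < tol and np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        prev = ll
        p = p_new
    return p, trace, converged


def _choose_reference(haplotypes: list[str], frequencies: np.ndarray) -> int:
    """Most frequent haplotype; ties broken by lexicographically smallest."""
    fmax = frequencies.max()
    near = np.flatnonzero(frequencies >= fmax - 1e-12)
    return int(min(near, key=lambda i: haplotypes[i]))


def fit_null(families, haps: HaplotypeTable,
             tol: float = _EM_TOL, max_iter: int = _EM_MAX_ITER,
             return_trace: bool = False):
    """Maximize the likelihood with all relative risks equal to 1.

    Returns ``(HaplotypeTable with fitted frequencies and reference set,
    loglik_null)``; with ``return_trace=True`` the per-iteration likelihood
    trace and a convergence flag are appended.
    """
    if not families:
        raise NoDataError("no families to fit")
    packed = _Packed(families)
    p, trace, converged = _em_null(packed, haps.n_haplotypes,
                                   start=haps.frequencies, tol=tol,
                                   max_iter=max_iter)
    fitted = HaplotypeTable(
        haplotypes=list(haps.haplotypes),
        allele_codes=haps.allele_codes.copy(),
        frequencies=p / p.sum(),
        reference_index=_choose_reference(haps.haplotypes, p),
    )
    if return_trace:
        return fitted, trace[-1], trace, converged
    return fitted, trace[-1]


# ---------------------------------------------------------------------------
# rare-haplotype pruning
# ---------------------------------------------------------------------------

def prune_rare(haps: HaplotypeTable, min_freq: float = 0.01, families=None):
    """Drop haplotypes with fitted frequency below ``min_freq``.

    Frequencies are renormalized, configurations referencing a pruned
    haplotype deleted, and families left with no configuration excluded.
    Returns ``(pruned HaplotypeTable, retained families, pruned labels)``.
    """
    families = families if families is not None else []
    keep = np.flatnonzero(haps.frequencies >= min_freq)
    if len(keep) < 2:
        raise WindowUninformativeError(
            f"pruning at {min_freq} would leave {len(keep)} haplotype(s)"
        )
    if len(keep) == haps.n_haplotypes:
        return haps, list(families), []

    pruned_labels = [haps.haplotypes[i] for i in range(haps.n_haplotypes)
                     if i not in set(keep.tolist())]
    remap = {int(old): new for new, old in enumerate(keep)}
    freqs = haps.frequencies[keep]
    new_haps = HaplotypeTable(
        haplotypes=[haps.haplotypes[i] for i in keep],
        allele_codes=haps.allele_codes[keep],
        frequencies=freqs / freqs.sum(),
    )
    new_haps.reference_index = _choose_reference(
        new_haps.haplotypes, new_haps.frequencies
    )

    kept_families = []
    for record, configs in families:
        new_cfgs = [
            TriadConfig(
                remap[c.maternal_transmitted],
                remap[c.maternal_untransmitted],
                remap[c.paternal],
                c.child_sex,
            )
            for c in configs
            if c.maternal_transmitted in remap
            and c.maternal_untransmitted in remap
            and c.paternal in remap
        ]
        if new_cfgs:
            kept_families.append((record, new_cfgs))
    return new_haps, kept_families, pruned_labels


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

@dataclass
class WindowFit:
    """Fitted window: frequencies, relative risks with Wald CIs, and the LRT."""

    haplotype_table: HaplotypeTable
    rr_single_dose: np.ndarray
    rr_single_ci: np.ndarray          # (H, 2) 95% CI on the single-dose RR
    rr_double_dose: np.ndarray
    rr_double_ci: np.ndarray
    rr_boys: np.ndarray | None        # None for females_only
    loglik_full: float
    loglik_null: float
    lrt_statistic: float
    df: int
    p_value: float
    n_families_used: int
    model: str
    pruned_haplotypes: list = field(default_factory=list)
    n_mendelian_inconsistent: int = 0
    n_families_excluded_pruning: int = 0
    converged: bool = True
    boundary_haplotypes: list = field(default_factory=list)
    ci_unbounded: bool = False

    @property
    def reference_index(self) -> int:
        return self.haplotype_table.reference_index


def _unpack_params(x, n_haps: int, ref: int, free: np.ndarray):
    """x = (softmax logits, log relative risks) for the non-reference entries."""
    k = len(free)
    logits = np.zeros(n_haps, dtype=x.dtype)
    logits[free] = x[:k]
    e = np.exp(logits)
    p = e / e.sum()
    r = np.ones(n_haps, dtype=x.dtype)
    r[free] = np.exp(x[k:])
    return p, r


def fit_full(
    families,
    haps: HaplotypeTable,
    spec: PenetranceSpec,
    compute_ci: bool = True,
    reference: int | str | None = None,
    max_iter: int = 500,
) -> WindowFit:
    """Jointly maximize the likelihood over frequencies and relative risks.

    ``haps`` should already be pruned.  For ``males_only``/``females_only``
    families of the other sex are excluded first.  The overall LRT compares
    all relative risks free against all equal to 1, with
    ``df = n_haplotypes - 1``.
    """
    fams = [fc for fc in families if spec.includes_sex(fc[0].child_sex)]
    if not fams:
        raise NoDataError(f"no families match the sex restriction of {spec.model!r}")
    h = haps.n_haplotypes
    if h < 2:
        raise WindowUninformativeError("fewer than two haplotypes")

    packed = _Packed(fams)
    p0, trace, em_converged = _em_null(packed, h, start=haps.frequencies)
    ll_null = trace[-1]

    if reference is None:
        ref = _choose_reference(haps.haplotypes, p0)
    elif isinstance(reference, str):
        ref = haps.haplotypes.index(reference)
    else:
        ref = int(reference)
    free = np.array([i for i in range(h) if i != ref], dtype=np.int64)
    k = len(free)

    p0_safe = np.clip(p0, 1e-12, None)
    x0 = np.concatenate([np.log(p0_safe[free] / p0_safe[ref]), np.zeros(k)])

    def negll(x):
        p, r = _unpack_params(x, h, ref, free)
        return -_packed_loglik(packed, p, r, spec)

    cstep = 1e-20

    def grad(x):
        g = np.empty(len(x))
        for i in range(len(x)):
            xi = x.astype(complex)
            xi[i] += 1j * cstep
            g[i] = negll(xi).imag / cstep
        return g

    def fun_and_grad(x):
        return float(negll(x).real), grad(x)

    bounds = [(-30.0, 30.0)] * k + [(-_LOG_RR_CAP, _LOG_RR_CAP)] * k
    res = optimize.minimize(
        fun_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    x_hat = res.x
    ll_full = -float(negll(x_hat).real)
    converged = bool(res.success) or float(np.max(np.abs(grad(x_hat)))) < 1e-5

    # the null is nested, so the optimum can never be worse than the start
    if ll_full < ll_null:
        x_hat = x0
        ll_full = ll_null
        converged = converged and (ll_null - ll_full) < 1e-9

    p_hat, r_hat = _unpack_params(x_hat, h, ref, free)
    beta = x_hat[k:]
    boundary = [
        haps.haplotypes[free[i]]
        for i in range(k)
        if abs(beta[i]) >= _LOG_RR_CAP - 1e-6
    ]

    se_beta = np.full(k, np.nan)
    ci_unbounded = False
    if compute_ci:
        hess = _hessian(negll, x_hat)
        try:
            cov = np.linalg.pinv(hess)
            var = np.diag(cov)[k:]
            good = np.isfinite(var) & (var > 0)
            se_beta[good] = np.sqrt(var[good])
            ci_unbounded = bool(np.any(~good))
        except np.linalg.LinAlgError:
            ci_unbounded = True

    def _exp(v):  # overflow-proof: huge Wald bounds become inf
        return math.exp(v) if v < 700.0 else math.inf

    ci_single = np.ones((h, 2))
    ci_double = np.ones((h, 2))
    for i, hidx in enumerate(free):
        if math.isfinite(se_beta[i]):
            lo, hi = beta[i] - _Z95 * se_beta[i], beta[i] + _Z95 * se_beta[i]
            ci_single[hidx] = (_exp(lo), _exp(hi))
            ci_double[hidx] = (_exp(2 * lo), _exp(2 * hi))
        else:
            ci_single[hidx] = (0.0, np.inf)
            ci_double[hidx] = (0.0, np.inf)

    lrt = 2.0 * (ll_full - ll_null)
    if lrt < -1e-8:
        raise AssertionError("LRT statistic negative beyond tolerance")
    lrt = max(lrt, 0.0)
    df = h - 1
    pval = lrt_pvalue(ll_full, ll_null, df)

    fitted_table = HaplotypeTable(
        haplotypes=list(haps.haplotypes),
        allele_codes=haps.allele_codes.copy(),
        frequencies=np.real(p_hat) / np.real(p_hat).sum(),
        reference_index=ref,
    )
    r_real = np.real(r_hat)
    rr_boys = None if spec.model == "females_only" else spec.male_rr(r_real)
    return WindowFit(
        haplotype_table=fitted_table,
        rr_single_dose=r_real,
        rr_single_ci=ci_single,
        rr_double_dose=r_real ** 2,
        rr_double_ci=ci_double,
        rr_boys=rr_boys,
        loglik_full=ll_full,
        loglik_null=ll_null,
        lrt_statistic=lrt,
        df=df,
        p_value=pval,
        n_families_used=packed.n_families,
        model=spec.model,
        converged=converged and em_converged,
        boundary_haplotypes=boundary,
        ci_unbounded=ci_unbounded,
    )


def _hessian(fun, x, step: float = 1e-5):
    """Central-difference Hessian of a complex-safe scalar function.

    Differentiates the complex-step gradient, so each entry is accurate to
    roughly ``step**2``.
    """
    d = len(x)
    cstep = 1e-20

    def grad_at(y):
        g = np.empty(d)
        for i in range(d):
            yi = y.astype(complex)
            yi[i] += 1j * cstep
            g[i] = fun(yi).imag / cstep
        return g

    hess = np.empty((d, d))
    for i in range(d):
        h_i = step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h_i
        xm[i] -= h_i
        hess[i] = (grad_at(xp) - grad_at(xm)) / (2 * h_i)
    return 0.5 * (hess + hess.T)


def lrt_pvalue(loglik_full: float, loglik_null: float, df: int) -> float:
    """Chi-square upper-tail p-value of the likelihood-ratio statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (loglik_full - loglik_null)
    if stat < -1e-8:
        raise AssertionError(
            f"full log-likelihood below null beyond tolerance (stat={stat})"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# one-window pipeline
# ---------------------------------------------------------------------------

def fit_window(
    dataset,
    window,
    spec: PenetranceSpec,
    min_freq: float = 0.01,
    cap: int = 65_536,
    compute_ci: bool = True,
    reference: int | str | None = None,
) -> WindowFit:
    """Full pipeline for one window: enumerate, fit null, prune, fit full.

    Mendelian-inconsistent families (no compatible configuration) are dropped
    for this window and counted, as are families excluded by pruning.
    """
    haps = enumerate_haplotypes(window, dataset.map)
    families = []
    n_inconsistent = 0
    for triad in dataset.triads:
        if not spec.includes_sex(triad.child_sex):
            continue
        cfgs = enumerate_configs(triad, window, haps, cap=cap)
        if cfgs:
            families.append((triad, cfgs))
        else:
            n_inconsistent += 1
    if not families:
        raise NoDataError("no compatible families in this window")

    null_table, _ = fit_null(families, haps)
    pruned_table, kept_families, pruned_labels = prune_rare(
        null_table, min_freq, families
    )
    n_pruned_out = len(families) - len(kept_families)
    if not kept_families:
        raise WindowUninformativeError("pruning excluded every family")

    fit = fit_full(
        kept_families, pruned_table, spec,
        compute_ci=compute_ci, reference=reference,
    )
    fit.pruned_haplotypes = pruned_labels
    fit.n_mendelian_inconsistent = n_inconsistent
    fit.n_families_excluded_pruning = n_pruned_out
    return fit
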