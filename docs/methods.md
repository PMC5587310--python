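# Methods

## Model

`xtriad` analyzes case-parent triads at windows of 1–4 contiguous X-linked
SNPs.  A window with L markers has 2^L candidate haplotypes, enumerated in
lexicographic allele order.  The sampling unit is a *phased configuration*
(t, u, f): the maternal transmitted haplotype t, maternal untransmitted u,
and paternal haplotype f.  Boys carry t; girls carry {t, f}.

Assuming random mating, equal haplotype frequencies p in eggs and sperm, and
Hardy–Weinberg proportions in the source population, the probability of a
configuration conditional on an affected child of known sex is

    girls:  p_t p_u p_f · r_t r_f / C_f,   C_f = (Σ_h p_h r_h)²
    boys:   p_t p_u p_f · r_t^(m) / C_m,   C_m = Σ_h p_h r_h^(m)

where r_h is the girls' single-dose relative risk (reference haplotype fixed
at 1) and the dose-response is multiplicative, RR_double = RR_single².  The
boys' coupling is a modeling choice:

* `xinactivation`: r^(m) = r² — with one X silenced per cell, a hemizygous
  boy's risk matches a double-dose girl's;
* `no_xinactivation`: r^(m) = r — a boy's single copy acts like a single
  dose in girls;
* `males_only` / `females_only`: one sex analyzed alone, with r estimated
  directly for that sex.

Conditioning on affection status and sex makes the sex-specific baseline
prevalences cancel, so case-only triads identify frequencies and relative
risks but not baselines; combined-sex models share p and r across the two
sex strata.  The father's haplotype enters the likelihood in boys' triads
too — it carries frequency information even though boys do not inherit it.

Missing genotypes (including entirely untyped members) are handled by
summing each family's likelihood over all configurations compatible with its
observed calls; a family with no compatible configuration is Mendelian-
inconsistent *for that window* and is excluded there, not globally.  A
configurable cap (default 65,536) guards against pathological ambiguity.

## Estimation

1. **Null fit** (all r = 1): EM over haplotype frequencies.  The E-step
   weights each family's configurations by the current frequency products;
   the M-step counts haplotypes in the three slots (t, u, f) with those
   weights — three draws per family.  The likelihood is non-decreasing per
   iteration; iteration stops when the gain drops below 1e-8 (cap 1000).
2. **Pruning**: haplotypes with fitted null frequency below `min_freq`
   (default 0.01, mirroring the MAF floor) are removed, frequencies
   renormalized, and families explicable only through pruned haplotypes
   excluded and counted.  A window retaining fewer than two haplotypes is
   uninformative.  The reference haplotype is the most frequent after the
   null fit, ties broken lexicographically; it can be overridden (useful for
   comparing fits under allele relabelling, which inverts the RR of the
   complementary haplotype).
3. **Full fit**: joint quasi-Newton (L-BFGS-B) maximization over softmax-
   transformed frequencies and log relative risks (reference pinned at 0),
   started at the null solution.  There is no closed-form M-step once r
   enters the normalizers, which is why the full model is not fitted by EM.
   Gradients use complex-step differentiation (exact to machine precision);
   bounds |log r| ≤ 15 cap separated estimates, recorded via a boundary
   flag.  Convergence: L-BFGS-B success or gradient sup-norm < 1e-5, with
   ftol 1e-14 / gtol 1e-9.
4. **Inference**: the observed information is a central-difference Hessian
   of the negative log-likelihood at the optimum (step 1e-5, scaled);
   standard errors on the log-r scale give 95% Wald CIs, exponentiated
   (doubled on the log scale for double-dose CIs).  A singular information
   matrix yields CIs flagged unbounded rather than a failure.  Each window
   carries one overall LRT — all r free versus all r = 1 — on
   df = (retained haplotypes − 1), with a chi-square upper-tail p-value;
   per-haplotype inference is Wald.  The scan ranks windows by the overall
   LRT p-value (one point per window).

## Scan and FDR

`run_scan` slides a fixed-length window (step 1) across the QC'd map,
fitting every position; failed windows keep missing p-values and are
excluded from the multiplicity count.  Within one scan (one model × one
window length) p-values become q-values by the Benjamini–Hochberg step-up
rule q_(i) = min_{j≥i} p_(j)·m/j; significance is declared at q ≤ 0.1
(FDR 10% among declared findings).  Storey-type π0 rescaling (λ = 0.5) is
available as an option but BH is the default, since FDR control among
rejected hypotheses is the stated goal and π0 estimation adds tuning.  Under
a full null with independent windows BH attains E[FDP] = α exactly, so
empirical checks of FDR control must allow Monte-Carlo slack around α.

## QC

The cascade is: individuals with more than 10% missing calls removed first
(removing any member removes the triad), then SNPs with more than 1%
missing calls, then SNPs with minor allele frequency below 0.01.  MAF counts
X copies: two alleles per mother or girl, one per father or boy.  Male
heterozygote calls are impossible on X; they are set missing with a counted
warning rather than aborting, since arrays do emit them and the EM machinery
absorbs missingness naturally.  Chromosome labels `X` and `23` are accepted
as equivalent; the missing allele code is `0`.

## Simulator

`simulate_triads` draws phased configurations directly from the normalized
case-conditional cell distribution per sex — an exact sampler, equivalent to
prospective simulation plus ascertainment of affected children but without a
rejection loop — then unphases (mothers and girls become unordered pairs)
and masks calls at the requested missing rate.  Defaults follow the power-
study regime the package targets: a single SNP, MAF 0.2, 600 triads, equal
case sex ratio, no missingness, significance level 0.05, 1000 replicates
(tests and the acceptance script use 400–500 replicates with tolerances
widened to the corresponding Monte-Carlo error).  For sex-stratified models
the simulated sample is halved (300 triads of one sex), reflecting a fixed
genotyping budget split by sex.

What the simulator does *not* emulate: linkage disequilibrium between
windows (`simulate_independent_snps` generates independent markers),
genotyping error (only missingness), population stratification, de novo
variation, and maternal or parent-of-origin effects.  Passing tests
therefore validate the estimator and test calibration under the model's own
sampling assumptions, not robustness to violations of them.

## Numerical choices and edge cases

* Frequencies live on the simplex via softmax; r on the log scale — Wald
  inference on log-RR is standard for relative risks.
* Negative LRT statistics beyond −1e-8 raise an internal-consistency error;
  tiny negative values from round-off clip to 0.  If the optimizer ends
  below the null likelihood, the null solution is returned (the models are
  nested, so this can only be a numerical artifact).
* Monomorphic markers get a placeholder second allele label and are removed
  by the MAF filter.
* Ties in reference-haplotype choice break to the lexicographically
  smallest label, making scans deterministic.
* Power grids derive one seed per cell from the master seed, so results are
  reproducible and independent of evaluation order.

## Design notes

* The likelihood uses all three family members for frequency estimation
  (the triad-cell likelihood above), not founders only.
* Exact closed-form identities (e.g. fitted RR = transmitted/untransmitted
  ratio from heterozygous mothers in complete single-SNP sex-stratified
  data) hold when the data's empirical margins sit at the model's fitted
  values; the test fixtures are constructed that way.  For general data the
  joint MLE also draws information about r from the ascertained parental
  genotype margins, and the simple ratio is only approximate.
* Window p-values are the overall LRT; per-haplotype Wald p-values are
  deliberately not used for ranking, keeping one test per window.

## Limitations

Case-control hybrid designs, autosomal models, maternal/imprinting effects,
profile-likelihood or bootstrap CIs, LD-aware multi-window inference and
annotation of nearby genes are out of scope.  Very rare haplotypes near the
pruning floor can leave Wald CIs anti-conservative; the LRT is the primary
test for exactly that reason.
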