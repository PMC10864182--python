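# Methods

This note documents the statistical models implemented in `magwas`, the
conventions and defaults chosen where the methodology left room, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Summary-statistics model and conventions

All analyses operate on per-variant case-control association summaries:
effect-allele frequency f, log-odds effect β, standard error, two-sided
p-value, case/control counts and imputation accuracy R². Coordinates
are 1-based; windows are inclusive on both ends; "distance from lead"
is always |pos − pos_lead|. One canonical tab-separated dialect is used
throughout (columns `SNP CHR BP A1 A2 EAF BETA SE P N_CAS N_CON INFO
N_STUDIES DIRECTION`, `.` for missing); alternative dialects are
declared explicitly via a column map, never sniffed.

**QC filters.** Variants are retained when the imputation info score is
≥ 0.7 and the effective allele count 2·MAF·(1−MAF)·N·R² is ≥ 50. For
small studies — by default those with half effective sample size below
2,000, a cutoff the methodology leaves open — a minimum MAF of 0.05 is
additionally required. Indels are recoded to `I` (longer allele) and
`D` (shorter); positions carrying two or more distinct indel patterns
become unresolvable after recoding and all their indel records are
dropped, as are equal-length multi-base allele pairs.

**Harmonization.** Records are oriented to a reference allele pair by
sign-flipping β and complementing f when swapped, resolving strand
flips by complementing. Palindromic SNVs (A/T, C/G) are orientable only
by frequency: they are aligned by minor/major-allele rank when both
EAFs are available and both < 0.42 or both > 0.58, and excluded
otherwise. The 0.42/0.58 band is a conventional choice balancing loss
of variants against mis-orientation risk.

**Scale conversions.** Mixed-model score statistics are converted to
the linear scale by β = score/variance, se = √variance/variance, then
to approximate log-odds by dividing both by π(1−π), with π the case
fraction; the z-statistic is invariant under the second step. The half
effective sample size is computed as 2/(1/n_cases + 1/n_controls); for
the published multi-ancestry totals this yields ≈ 559,331.6 against a
printed 559,332, consistent with per-study summation before rounding in
the original accounting — the pooled-count formula is used here and the
one-unit discrepancy documented rather than hidden.

**Extreme p-values.** p-values are stored as ordinary doubles; every
internal comparison happens on the z or χ² scale, and a log-scale
helper (`z_to_neglog10p`, built on the normal log-survival function) is
provided for reporting statistics beyond the double-precision floor.
Storing log10 p throughout was considered and rejected: no quantity in
the pipeline is compared below ~1e−308.

## Meta-analysis

Fixed-effects inverse-variance weighting follows the standard form
(weights 1/se²); heterogeneity is Cochran's Q with
I² = max(0, (Q−(k−1))/Q), defined as 0 for a single study. The genomic
inflation factor uses the median method — λ = median(χ²)/0.4549 — which
is robust and conventional; regression-based alternatives exist but the
median is what the rescaling formula λ₁,₀₀₀ = 1 + (λ−1)(1/n_cases +
1/n_controls)·500 was applied to. λ₁,₀₀₀ uses crude case/control
counts: with λ = 1.687 and 345,389/1,469,702 this reproduces the
published 1.001 at three decimals, which effective counts would not.

LDSC-intercept correction divides each χ² by the intercept
(equivalently scales se by √intercept) and recomputes p; β is
untouched. The intercept is always a supplied input — LDSC regression
itself is out of scope. Variants present in fewer than two studies are
removed after pooling.

Loci span lead ± 250 kb; leads on one chromosome closer than 500 kb
merge transitively (if A–B and B–C are close, A,B,C form one locus —
the only reading under which the pairwise rule is consistent), the
merged locus taking the minimum-p member as its lead. A lead is novel
iff every catalogue variant satisfies r² < 0.1 *and* distance > 250 kb;
when the LD panel lacks either variant the rule degrades to distance
only, with a logged warning. Conditional selection of independent
signals (COJO-style) is out of scope; leads are taken as given.

## Transferability (PAT)

Credible sets for transferability are built in the *discovery* data:
lead plus proxies with r² ≥ 0.8 within 50 kb whose discovery p is below
100× the lead's. The discovery p is used for that filter (sets exist
before any target lookup). The penalization factor P_f is the OLS slope
of −log₁₀(min member p in a null-trait target scan) on set size N —
the log scale is the only choice dimensionally consistent with the
threshold exponent P_f·(N−1). Published constants (AFR 0.008341,
EAS 0.007378, SAS 0.006847, HIS 0.003147) are available as
`PF_CONSTANTS`; fits from fewer than 10 null loci are refused.

Replication power assumes an additive log-odds effect at α = 0.05 (the
plain level, not the penalized per-locus threshold): expected
se = 1/√(2f(1−f)·N·φ(1−φ)) with φ the case fraction, noncentrality
(β/se)², and power the noncentral-χ²₁ upper tail beyond 3.8415. A
locus's power is the maximum over its credible-set members present in
the target data. The PAT ratio divides observed transferable calls by
summed powers; its 95% CI is a 1,000-replicate percentile bootstrap
over loci, resampling each locus's (call, power) pair jointly. Loci
with no member in the target data count toward neither sum.
Nontransferable calls require a member with power > 0.8, no member with
target p < 0.05, and no variant within 50 kb of the lead with
p < 1e−3; transferable and nontransferable are mutually exclusive by
construction.

## Fine mapping

Each locus (assumed single-causal; loci with secondary signals are
excluded upstream) comprises all panel variants with r² > 0.1 to the
lead. Per variant, the five ancestry-group estimates are pooled by
fixed effects; I² measures cross-group heterogeneity (0 when only one
group observes the variant — the member is retained, pooled over
whatever is available). The prior is max(ε, 1−I²) normalized, ε = 0.01:
the methodology specifies only that heterogeneous variants get smaller
prior mass, so the simplest monotone form was chosen and is
config-exposed. Posterior weight is literally χ²·prior ("proportional
to its chi-square test statistic and the prior"); an approximate
Bayes-factor weighting (Wakefield, prior variance 0.04) was considered
as an alternative reading but the literal form is the default. PIPs
normalize to 1; the 99% credible set accumulates descending PIPs (ties
broken by position) until ≥ 0.99. The single-ancestry comparator drops
the prior and uses one group's χ². With one group the two modes
coincide exactly, since all I² = 0.

The χ²-proportional posterior is an approximation, not a calibrated
Bayesian posterior; its empirical coverage is therefore asserted by
simulation (below) rather than assumed.

**DENTIST-S / SLALOM.** T = (zᵢ − r·z_lead)²/(1−r²) with signed r from
the supplied panel, referred to χ²₁. The screen applies only to loci
with max PIP > 0.1, tests every panel variant within 1 Mb of the lead
(the locus's minimum-p variant), flags outliers with p < 1e−4 and
r² > 0.6, and calls the locus robust iff none exist. Variants in
perfect LD with the lead are skipped. The screen assumes the z-scores
and the panel describe the same population mix: screening pooled
multi-ancestry statistics against a single-ancestry panel will flag
genuine panel mismatch (this is visible, deliberately, in the examples).

## Mendelian randomization

Instruments: exposure variants with p < 5e−8, LD-clumped greedily by
ascending p at r² > 0.001 within 10,000 kb; if fewer than ten survive,
reselection at p < 5e−6; fewer than three is a hard error. Outcome
records are aligned to the exposure effect allele; palindromic variants
with MAF > 0.42 on either side are dropped, others resolved by
frequency. Exposure and outcome must come from different samples — the
pipeline asserts distinct inputs but sample-overlap bookkeeping is the
caller's responsibility.

Estimators: IVW (origin-constrained WLS of β_out on β_exp, weights
1/se_out²); MR-Egger (free intercept, instruments oriented to positive
β_exp, residual scale floored at 1, t-tests on n−2 df); weighted median
(inverse-variance-weighted median of Wald ratios, se by 1,000-replicate
parametric bootstrap); simple and weighted mode (mode of the
kernel-smoothed ratio density, bandwidth multiplier default 1 on the
0.9·min(sd, mad)·n^(−1/5) scale, se by bootstrap). Heterogeneity is
Cochran's Q of β_out around θ̂·β_exp with weights 1/se_out², on n−1 df.

Outlier handling is a deterministic simplification of the
residual-sum-and-outlier approach: while the global Q test rejects at
0.05 and more than three instruments remain, the largest Q-contributor
is removed, each removal logged with the Q decomposition at that step.
The audit trail makes the substitution transparent; the simulation
studies confirm it removes a planted outlier essentially always and
reduces estimation error.

## Synthetic data generator

Summary statistics are simulated directly from the standard
multivariate-normal model: z ~ MVN(R·λ, R) with λⱼ = βⱼ·√(2fⱼ(1−fⱼ)·
n_eff_half), seⱼ = 1/√(2fⱼ(1−fⱼ)·n_eff_half), βⱼ = zⱼ·seⱼ. LD is
block-diagonal AR-1 (rᵢⱼ = ρ^|i−j| within a block), positive definite
by construction and sampled per block by Cholesky factorization.
Ancestry-specific allele frequencies follow a Balding–Nichols beta
model around shared ancestral frequencies (drift parameter F, defaults
0.05–0.15 depending on the emulated group). Group-specific missingness
is introduced by masking. Identical seeds give identical output.

Note one deliberate convention: the generator's standard error uses the
score-information scale 2f(1−f)·n_eff_half, whereas the power
calculation uses the case-control asymptotic 2f(1−f)·N·φ(1−φ) — the
two differ by a factor of two for a balanced design (N·φ(1−φ) =
n_eff_half/2). Both forms are standard in different corners of the
literature; each is used where it is conventionally defined. The PAT
validation is insensitive to the discrepancy because its study designs
put per-locus power near 1 under either convention; users combining
the generator with the power module at marginal power should align the
conventions themselves.

What the generator does **not** emulate: individual genotypes,
realistic demographic or coalescent LD structure (AR-1 blocks only),
X-chromosome dosage, covariate adjustment, sample overlap between
studies, or winner's curse beyond what thresholded discovery induces.
Passing validation on this generator demonstrates internal consistency
of the statistical machinery, not robustness to the messiness of real
cohort data (array differences, population stratification, phenotype
heterogeneity).

## Validation studies and problem sizes

`magwas.benchmarks` runs the package's empirical validation; the
acceptance script reports the recovered numbers.

- **PAT parameter recovery**: 200 replicates per transferable fraction
  τ ∈ {0, 0.3, 1}; 40 loci of 15 variants; discovery ρ = 0.97 with
  n_eff_half 50,000 (so every causal locus is catalogued and credible
  sets span 1–7 proxies); target ρ = 0.7 with n_eff_half 20,000; causal
  log-odds 0.1; F = 0.05/0.10. P_f is estimated once per study from 200
  null-trait loci. Mean PAT ratio recovers τ within 0.05; at τ = 0 the
  observed fraction matches an independent Monte-Carlo computation of
  the penalized threshold's false-call rate.
- **Fine-mapping calibration**: 500 single-causal loci of 40 variants,
  EUR (ρ = 0.95, n_eff_half 30,000) plus AFR (ρ = 0.8, 15,000), shared
  β = 0.08. The multi-ancestry 99% credible set contains the causal
  variant in ≥ 95% of loci and its median size does not exceed the
  European-only median.
- **DENTIST-S calibration**: 200 consistent loci (50 variants,
  ρ = 0.9, β = 0.17, n_eff_half 10,000) give a per-variant outlier rate
  ≤ 5e−4 (the statistic is exactly χ²₁ under consistency); a planted
  sign flip two positions from the causal variant (r² ≈ 0.66) is
  flagged in ≥ 95% of applied loci.
- **Meta-analysis exactness**: IVW matches a statsmodels WLS oracle
  (unit scale) to 1e−10 over 1,000 random inputs; λ of 100,000 null
  p-values is 1 ± 0.02.
- **MR recovery**: 200 replicates, 50 instruments, θ = 0.3; IVW, Egger
  and weighted median recover θ within 0.02; the Egger intercept
  recovers planted directional pleiotropy 0.05 within 0.01; pruning
  removes a planted outlier in ≥ 95% of replicates.

These sizes keep the full validation under two minutes on one CPU with
Monte-Carlo error comfortably inside each tolerance.

## Known limitations

- Single-causal fine mapping only; no SuSiE-style multiple-signal
  decomposition, functional priors or colocalization.
- The heterogeneity prior's functional form is a documented stand-in
  for a method whose exact prior is not public; conclusions that hinge
  on the precise prior shape should use the config-exposed alternatives.
- P_f depends strongly on the LD and power regime of the null scan used
  to estimate it; constants estimated in one setting do not carry to
  another.
- The MR outlier step is deterministic heterogeneity pruning, not a
  simulation-based global test.
- λ₁,₀₀₀ uses crude counts by design; studies quoting effective counts
  will differ.
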