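# Methods

## Scope and model

`lipidmr` implements a two-sample summary-statistics MR screen: many
continuous exposures (lipid species, cholesterol fractions, SD units)
against binary outcomes (log-odds scale), followed by cross-cohort
meta-analysis, reverse MR and two-step mediation. All causal effects are
carried internally as log-odds per exposure SD; odds ratios appear only at
reporting boundaries (result tables, forest tables).

The identifying assumptions are the usual instrumental-variable triplet —
instruments associate with the exposure, affect the outcome only through
it, and are independent of confounders — plus, for MR-Egger, InSIDE
(instrument strength independent of direct effects). The estimators are
the standard suite; what this package adds is the orchestration (selection
rule, filter ordering, provenance accounting) and a ground-truth generator
that makes the whole chain testable by parameter recovery.

## Synthetic data generator

`simulate_triplet` draws, for each of `n_snps` candidate SNPs:

- allele frequency `eaf`: minor-allele frequency uniform on `maf_range`
  (default 0.05–0.5), with the effect allele being minor or major with
  equal probability; allele pairs are non-palindromic by construction so
  strand can always be resolved (palindromes are injected separately);
- a true exposure effect `gamma` from a half-normal with scale `effect_sd`
  (default 0.3) left-truncated at `effect_floor` (default 0.025). The panel
  models *published* genome-wide-significant lipid loci: per-allele effects
  on SD-standardized lipid traits at such loci are a few tenths of an SD,
  and having already passed a discovery threshold they sit clear of the
  detection boundary. The truncation matters for MR-Egger: effects at the
  boundary get their estimated sign flipped during Egger orientation, which
  would dilute an injected directional-pleiotropy signal — an artifact of
  boundary-strength instruments, not of the estimator. The effect allele is
  coded as the trait-increasing allele, the orientation under which
  directional pleiotropy is defined;
- optionally, a direct mediator effect `delta` (for the
  `mediator_snp_fraction` of SNPs, same distribution, zero exposure
  effect), and a fraction `null_fraction` of completely null SNPs;
- a horizontal-pleiotropy effect `alpha ~ N(pleiotropy_mean,
  pleiotropy_sd²)` added to the outcome only, so InSIDE holds by default.

True associations follow the causal graph: exposure `gamma`; mediator
`a_true·gamma + delta`; outcome `theta_total·gamma + b_true·delta + alpha`,
with `theta_total` the *total* exposure effect (so the indirect part is
`a_true·b_true` and the direct part `theta_total − a_true·b_true`).
Estimated betas add independent Gaussian noise per trait with
SE = 1/√(2·eaf·(1−eaf)·n) — the standard variance approximation for an
SD-standardized trait, which also makes the reported SE a deterministic
function of the configuration. Exposure, mediator and outcome noise are
independent, mirroring non-overlapping two-sample GWAS. The outcome is
generated directly on the log-odds scale (linear approximation) rather
than via individual-level logistic simulation, since every downstream
method consumes summary statistics only.

What the generator does *not* emulate: LD between instruments (clumping is
exercised with user-supplied LD matrices), allele-frequency differences
between cohorts, sample overlap, winner's-curse in the discovery GWAS
beyond the truncation above, and non-collapsibility of the odds ratio.
Recovery results here therefore validate the estimators and the pipeline
plumbing, not robustness to those real-data complications.

`simulate_study` extends this to a lipid-panel screen: each lipid gets a
disjoint instrument block, all traits are reported over the union panel,
and per-cohort causal effects can be jittered (`between_cohort_sd`) to
induce genuine heterogeneity for the meta-analysis — only for truly causal
lipids, so a null lipid stays null in every cohort.

## Harmonization

Records are intersected on SNP id and the outcome is re-expressed on the
exposure's effect allele: allele swaps negate the outcome beta and reflect
its frequency; strand complements are re-labelled; combinations of both are
handled. Palindromic variants (A/T, C/G) cannot be strand-resolved from
alleles, so they are oriented by allele frequency when both traits'
minor-allele frequencies are below `palindrome_maf_limit` (default 0.42, a
conventional cutoff) and dropped otherwise. Irreconcilable allele pairs are
dropped as mismatches. Every intersected SNP receives exactly one action
(`none`, `flipped`, `swapped`, `dropped_palindromic`, `dropped_mismatch`),
so action counts partition the intersection — a property the tests enforce.

## Instrument selection

Defaults follow the screening conventions: exposure threshold p < 5×10⁻⁶
(reverse direction 5×10⁻⁸), greedy clumping keeping the smallest-p index
SNP and removing same-chromosome SNPs within 10,000 kb at r² ≥ 0.001 (ties
on p broken lexicographically by SNP id for determinism; SNPs absent from
the LD matrix are treated as unlinked and logged), removal of variants
associated with the outcome at p < 5×10⁻⁵ (p recomputed as a two-sided
normal test of beta/se), and Steiger filtering. Steiger variance explained
is approximated as t²/(t²+n−2) with t = beta/se for both continuous and
binary traits (log-odds treated as continuous); the formula is isolated in
one function so a different approximation can be swapped in. Per-SNP F
statistics ((beta/se)²) are reported as a diagnostic; no F cutoff is
applied. MR-PRESSO outlier removal runs once (remove flagged SNPs, refit),
not iterated to convergence — the common practice, with bounded runtime.

The outcome-association filter is applied in the forward/reverse screens
only. It is deliberately *not* applied on the mediation legs: it exists to
purge horizontally-pleiotropic variants when screening mostly-null
exposures, and for an exposure with a genuine downstream effect every valid
instrument is outcome-associated, so the filter would empty the instrument
set precisely when the effect is real.

## Estimators and numerical choices

- Wald-ratio SEs are first-order (`|se_out/beta_exp|`), matching the
  conventional IVW weighting; a `second_order` flag adds the exposure term.
- IVW is the closed-form weighted regression through the origin; its
  equivalence to an independent WLS solver is a standing test. MRE
  inflates the SE by √max(1, Q/(k−1)); the truncation at 1 means MRE can
  never be *more* precise than FE.
- MR-Egger orients exposure betas non-negative (flipping outcome betas in
  tandem), fits a weighted line with intercept, and scales both SEs by
  √max(1, Q_egger/(k−2)). All p-values in the suite are two-sided normal;
  with ~50 instruments the difference from t-based tests is within the
  calibration tolerances the validation battery enforces.
- Weighted median: ratios ordered, inverse-variance weights normalized,
  estimate interpolated at cumulative weight 0.5. Weighted mode: weighted
  normal-kernel density over ratios with bandwidth
  `phi · 0.9·min(sd, mad)·k^(−1/5)` (MAD on the normal-consistent scale),
  argmax on a 512-point grid spanning the ratios ±3 bandwidths. Both get
  parametric-bootstrap SEs (redraw betas from their reported sampling
  distributions; 1000 replicates by default, seeded from the pipeline
  seed).
- MR-PRESSO: observed statistic is the weighted RSS of outcome betas
  around leave-one-out IVW predictions (closed-form LOO updates); the null
  distribution re-simulates outcome betas around those predictions and
  recomputes the statistic, giving a global p with resolution
  1/(n_sim+1); per-SNP outlier p-values use the per-observation analogue
  with Bonferroni flagging.
- Primary-estimate selection: MR-Egger when the intercept test is
  significant at 0.05 *and* |intercept| ≥ 0.01 — the intercept-magnitude
  floor reads the conventional "intercept < 0.01 and p > 0.05" declaration
  of no pleiotropy as a compound condition, so a statistically significant
  but trivially small intercept does not hand the analysis to Egger's much
  wider intervals; otherwise MRE-IVW when Q is significant at 0.05;
  otherwise FE-IVW. The suite always reports all estimates alongside the
  selected one.
- Meta-analysis: DerSimonian–Laird, chosen over REML for its closed form
  and because it is the conventional "random-effects model" default; τ² is
  truncated at zero; pooling is on log-OR, never on OR. I² = max(0,
  (Q−df)/Q).
- Mediation delta method: a, b, c treated as mutually independent (they
  come from separate two-sample fits; no covariance is estimable from
  summary data — a documented limitation since a and c share instruments).
  The SE of the proportion uses the gradient form
  √((b/c)²se_a² + (a/c)²se_b² + (ab/c²)²se_c²), which stays finite when a
  or b is exactly 0. Proportions are reported in percent. `b` is the plain
  (unadjusted) mediator→outcome effect — the product method, not
  multivariable MR — with mediator instruments associated with the
  upstream exposure (p < 5×10⁻⁵) excluded so `b` is the mediator's own
  effect rather than a mixture through the exposure. The "interactive
  mediation test" is the delta-method Wald z test of the proportion,
  consistent with CIs symmetric about the point estimate.
- Degenerate inputs: single-SNP sets fall back to the Wald ratio; two-SNP
  sets skip Egger and select between FE/MRE on Q alone; pairs with fewer
  than `min_instruments` (default 2) usable SNPs are recorded as
  `insufficient_instruments`, never fatal.

## Validation experiments (study conditions)

`lipidmr.experiments` fixes the replicated experiments the test suite and
the reproduction script run; problem sizes are 50-SNP panels (60 for
mediation, half of them mediator instruments) with n = 100,000 per trait,
1000 replicates for calibration/recovery, 500 for pleiotropy, mediation and
meta-analysis, 100 for the MR-PRESSO spike-in:

- null calibration: type-I error of the selected primary estimate and
  rejection rates of Cochran's Q and the Egger intercept near 5%;
- effect recovery: mean FE-IVW within Monte-Carlo error of the true
  log-OR 0.2, CI coverage near 95%;
- pleiotropy: mean Egger intercept recovers 0.05 while IVW is measurably
  biased;
- MR-PRESSO: a 10·SE spiked outlier is top-ranked and the global test
  rejects at p ≤ 0.01 in ≥95% of replicates;
- mediation: mean estimated proportion recovers 80% with near-nominal
  delta-method CI coverage, and indirect + direct reconstructs the total
  to machine precision;
- meta-analysis: pooled log-OR recovers 0.15 and τ² recovers 0.0025 within
  simulation error over 4 cohorts.

The Jensen-type bias of the ratio a·b/ĉ (of order se_c²/c², here ~4×10⁻⁴
relative) and the attenuation from exposure-side noise (~3×10⁻⁴ relative)
are real but an order of magnitude below the Monte-Carlo resolution of
these experiments.

## Known limitations

First-order Wald SEs ignore exposure-side uncertainty, giving slight
undercoverage when instruments are weak (not the regime simulated here).
The mediation delta method ignores the a–c covariance from shared
instruments. No multivariable MR, SIMEX-corrected Egger, robust/penalized
IVW or Bayesian variants. No reference-panel LD computation, proxy-SNP
lookup, genome-build liftover or VCF input. Reverse-MR results on
synthetic data are mostly "insufficient instruments" by design — a binary
outcome with no simulated upstream genetics has nothing to instrument it
beyond what Steiger filtering removes.
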