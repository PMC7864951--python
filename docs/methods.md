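# Methods

## Data model and transforms

A methylome dataset is a probe manifest (probe id, chromosome, 1-based
position; positions sorted within chromosome) plus a probes × subjects
matrix of beta-values strictly inside (0, 1). Linear modelling uses
M-values, `M = log2(β/(1−β))`, clipped at `eps = 1e−6` from the
boundaries; the logit scale is closer to homoscedastic and the log base is
the array-analysis convention. `beta_to_m`/`m_to_beta` are exact inverses
on the clipped range.

Probe filtering removes ids found in named exclusion lists
(cross-reactive, sex-chromosome, near-SNP, user-supplied); a probe in
several lists is attributed to the first, and the filter report counts
removals per reason. Imprinting QC flags somatic-cell contamination:
every maternally imprinted locus must average **strictly below 10 %**
methylation and every paternally imprinted locus **strictly above 85 %**
per subject; boundary values fail. Missing beta entries are rejected at
construction (optional mean imputation is deliberately not a default).

## Per-CpG EWAS

For each probe, ordinary least squares of the M-values on male age
adjusted for male BMI, smoking and infertility (female age is *not* in
the methylation models; it is in the outcome models). The p-value is the
two-sided t-test on the age coefficient with residual degrees of freedom;
classical (non-robust) standard errors. The reported effect size comes
from refitting the identical design on beta-values and is expressed as
percent methylation per 5 years (`5 × slope × 100`). The scan is a single
matrix solve across all probes; constant probes return NA ("untestable"),
are excluded from the multiplicity denominator, and never become p = 1.
Benjamini–Hochberg q-values follow the step-up rule
`q_(i) = min_{j≥i} p_(j)·m/j` capped at 1; the Bonferroni threshold is
`0.05/m` over tested probes.

## Co-methylation regions (A-clustering)

Per chromosome, a greedy left-to-right scan extends the current cluster
to the next probe iff (a) the gap to the previous probe is ≤ `max_gap`
(default 1000 bp — a consecutive-probe rule, not a span rule) and (b) the
linkage correlation reaches `corr_threshold` (default 0.5). Correlation
is Spearman on M-values; linkage `single` compares the candidate with its
nearest member (the previous probe), `average` with the mean correlation
over members. Only clusters of ≥ 2 probes are emitted; clusters are
disjoint and the scan is deterministic. The correlation type, threshold
and linkage are exposed because no canonical parameterization exists for
array data; raising the threshold can only shrink the clustered probe
count (tested as a property).

## GEE DMR scan

Each region is tested by an identity-link GEE on the long data (one row
per subject × probe) with the subject as the cluster, an exchangeable
working correlation, and cluster-robust sandwich variance; p-values use
the normal approximation. Fits are delegated to statsmodels' GEE, which
implements exactly this estimating-equation iteration; with one probe per
subject the estimate and sandwich SE coincide with OLS + HC0 (tested to
1e−8). As in the EWAS, inference is on M-values and the reported percent
effect comes from a beta-scale refit. Non-converging regions are reported
NA and excluded from the BH denominator. The plain sandwich is
anti-conservative with few clusters, so `small_sample=True` switches to
the bias-reduced (Mancl–DeRouen-style) covariance; the default remains
the plain sandwich.

## Annotation and enrichment

All interval work uses BED semantics: 0-based half-open intervals,
membership by any overlap of ≥ 1 bp (abutting intervals do not overlap).
Regions spanning 1-based probe positions `[start, end]` convert to
`[start−1, end)`. Nearest-gene assignment picks the gene whose TSS
minimizes the unsigned distance to the region (0 if inside), subject to a
1500 bp window; strand is ignored and exact ties break to the
lexicographically smallest gene id with all tied ids recorded.
Enrichment per feature is a two-sided Fisher exact test contrasting DMRs
against **non-DMR** regions — disjoint rows are the only valid 2×2
construction, although "DMRs versus the entire region set" is a common
loose phrasing. The sample odds ratio is reported, Haldane-corrected
(+0.5 per cell) when a zero cell occurs. Direction summaries report the
percent of member DMRs that are hypermethylated; a feature with no member
DMRs reports NA, not 0 %.

## ART outcome models

Fertilization and embryo-quality outcomes are per-couple success
proportions; the oocyte (or fertilized-embryo) count enters as a
**frequency weight**, exactly equivalent to expanding each couple into
one row per oocyte (tested against the row-expanded fit). Live birth is a
single event and is modelled unweighted. Covariates: male BMI, smoking,
infertility and female age. Estimation is Newton–Raphson IRLS with
step-halving, so the weighted log-likelihood is non-decreasing across
iterations (asserted in tests); convergence requires every score
component below 1e−8, or a Newton step at the float64 floor. Complete
separation raises an error naming the diverging covariate. Wald 95 % CIs
are `exp(b ± 1.96·SE)`. Frequency weights treat oocytes within a couple
as independent; the standard errors inherit that assumption — a known
limitation of this design, and the reason the dispersion correction
appears in the mediation selection step below.

## High-dimensional mediation

**Candidates.** DMRs (q < 0.05) assigned to a gene within 1500 bp of a
TSS; the mediator value is the subject-wise mean M-value of the region's
probes.

**Stage 1.** The outcome is regressed on each candidate separately plus
female age, male BMI, smoking and infertility (oocyte weights for
fertilization, none for live birth); BH across candidates keeps q < 0.05.
With frequency-weighted proportions this screen is anti-conservative —
unmodelled couple-level variation over-disperses the weighted binomial —
so it behaves as a generous prefilter, as intended.

**Stage 2 (leave-one-out SIS + MCP).** For each of the n subsamples
obtained by removing one couple: sure independence screening ranks
candidates by the magnitude of the standardized univariate coefficient
against the raw outcome and keeps the top `d = floor(m/log m)`; then an
MCP-penalized logistic model (γ = 3, 100-value λ path geometrically
spaced over [0.01·λ_max, λ_max]) is fitted with the intercept, **male
age** and the covariates unpenalized. A candidate's frequency is the
share of subsamples whose selected support contains it; the final set is
frequency ≥ 20 % (boundary included). The procedure is deterministic
given the data.

Four numerical choices matter here and were each forced by measurable
failures of the naive alternative:

* *Weight normalization.* Observation weights are scaled to mean 1
  inside the solver (the ncvreg convention). With raw oocyte weights the
  per-column curvature is ≈ mean weight, which collapses the MCP firm
  threshold `(u − λ·sign u)/(v − 1/γ)` into soft thresholding and leaves
  entering coefficients biased all along the path.
* *Orthogonal projection.* Penalized columns are projected orthogonal to
  the unpenalized block (in the weighted metric) before standardization.
  Candidate mediators correlate strongly with age, so their *marginal*
  score — which gates path entry in coordinate descent — can be near zero
  even when their *partial* likelihood gain is large (a suppression
  effect); penalizing partial effects makes entry order track the
  adjusted association. The span of the model is unchanged because the
  unpenalized block is refit freely at every λ.
* *Dispersion-scaled extended BIC.* λ is chosen by
  `deviance/φ + df·(log n + 2γ_EBIC·log p)` with γ_EBIC = 0.5 (the
  standard Chen–Chen choice) and p the size of the candidate pool the
  screened columns came from. φ is the Pearson dispersion of the
  saturated screened model: frequency weights inflate the binomial
  deviance ~15×, and screened candidates are extreme order statistics
  that a plain log n penalty can never reject.
* *Exposure in the model.* Male age is unpenalized in the stage-2
  outcome model (standard in high-dimensional mediation, e.g. HIMA):
  without it the age-driven mediators are nearly collinear and the
  selector keeps an arbitrary one of them.

**Estimator.** With the selected mediators `M₁…M_K`: linear regressions
of each mediator on age + covariates give `α_k`; the full outcome
logistic (age + mediators + covariates) gives the direct coefficient
`θ_dir` and the `β_k`; the reduced model (no mediators) gives `θ_tot`.
Nested logistic coefficients are not directly comparable (the latent
residual variance π²/3 is fixed), so the total effect is rescaled by
`c = s_full/s_reduced`, `s = sqrt(var(η) + π²/3)` (weighted variance of
the linear predictor). Then `NIE_log = c·θ_tot − θ_dir`,
`NDE_log = θ_dir`, `proportion = NIE_log/(c·θ_tot)`; the decomposition
`NIE + NDE = c·TE` holds identically, and in the identity-link limit
(c = 1) the difference of coefficients equals the product Σα_k·β_k
exactly. Per-mediator products α_k·β_k are reported for interpretation.
95 % CIs are percentile bootstrap over couples (default B = 1000;
pipeline default 200) with the mediator set held fixed — they quantify
estimation, not selection, uncertainty. A total effect within 1e−8 of
zero marks the proportion undefined.

## Synthetic cohort generator

The generator defines the study conditions; all draws descend from one
seed through named substreams, so outputs are byte-identical per config.

* **Layout**: probes are placed per chromosome by cycling a layout of
  (region size, intra-region gap, inter-region gap) entries; the default
  interleaves 3/2/4-probe regions (gaps 250–500 bp) among isolated probes
  3 kb apart, giving ≈ 2,400 true regions per 20,000 probes.
* **Baselines**: a two-component mixture near β = 0.05 and β = 0.95
  (weights 0.45/0.55) reproduces the bimodal sperm methylome; planted
  sites get intermediate baselines (β ∈ [0.25, 0.75]), where regulatory
  age drift is biologically plausible and the beta scale is informative.
* **Age effects**: planted on the M scale. For a configured per-5-year
  beta drift, the M slope is calibrated numerically (root-finding on a
  noise-free age grid) so that the *linear regression of beta on age over
  the cohort range* equals the configured drift — a pure tangent-slope
  conversion under-delivers where the logit curve bends. Per-CpG drifts
  are drawn log-uniformly on [0.2, 11.7] % (mean ≈ 2.8 %), 91 %
  hypermethylating; region drifts share the range with 57 %
  hypermethylating.
* **Noise**: per-probe Gaussian M noise (SD 0.3) with a subject-level
  shared factor inside each region contributing fraction
  `within_region_rho = 0.6` of the variance (a free parameter; array
  studies do not report it).
* **Mediators**: `n_true_mediators` regions (default 4) receive slope
  α_k M-units/year; the fertilization model adds Σβ_k·(region-mean M) of
  the *realized* (noisy) mediator values, so the indirect path is carried
  by the data. Defaults split the fertilization total effect
  log(0.92)/year as 64 % indirect / 36 % direct. Each mediator region is
  guaranteed a TSS within the 1500 bp assignment window so the
  TSS-restriction step cannot silently drop planted truth.
* **Outcomes**: oocytes are negative-binomial (mean 15.1, dispersion
  4.66 → SD ≈ 8.0) truncated at ≥ 1; fertilized and embryo-quality
  counts are binomial with logistic rates (day-3 0.57, day-5 0.10,
  transfer-quality 0.30) and their own age log-ORs (log 0.94, log 0.85,
  log 0.93); live birth is Bernoulli (rate 0.319, age log-OR log 0.80).
  Covariates: male age uniform on [21, 45]; BMI N(27.5, 4.5²); smoking
  8.5 %; male-factor infertility 23.4 %; female age = male age − 1.5 +
  N(0, 3²), clipped to [18, 60]. Small fixed covariate effects enter the
  outcome linear predictors.
* **Annotation**: CpG islands around every third region with ±2 kb
  shores and shelves and open sea as the complement (a true partition);
  promoters/exons/introns derived from the generated TSSs; random
  enhancer, nucleosome-retention and TFBS intervals.

What the generator does **not** emulate: probe-chemistry artefacts (Type
I/II, Noob), batch effects, cell-type mixtures, genomic inflation,
realistic LD-like long-range correlation, or annotation geometry beyond
the simple partition above. Recovery of planted truth therefore
demonstrates correctness of the estimators under the assumed generative
model, not robustness to the technical artefacts of real arrays.

## Verification strategy and problem sizes

Oracles are independent re-computations: exhaustive contiguous-partition
growth for the clustering scan, full hypergeometric enumeration for
Fisher p-values, row-expansion for frequency weights, OLS + HC0 for the
single-cluster GEE, the textbook step-up for BH, and grid minimization of
the penalized objective for univariate MCP. Calibration and recovery
simulations run at reduced scale chosen to keep the full suite within a
routine CI budget: the null EWAS calibration uses 100 replicates of
5,000 probes × 100 subjects; outcome-OR recovery 100 replicates at
n = 500; mediation-proportion recovery 100 replicates at n = 2000;
leave-one-out stability recovery 20 replicates at n = 150 with ~200
candidate regions; the end-to-end run uses the default 100 couples ×
20,000 probes with B = 200 bootstrap.

## Known limitations

* The stability-selection scenario with α = 0.05, β = 0.8 has limited
  conditional power: once the age-shared signal is adjusted for, each
  mediator's own deviance gain straddles the selection threshold, and the
  measured all-three-recovered rate is ≈ 0.8 rather than the ≥ 0.9 a
  marginal-power calculation would suggest. The false-selection behaviour
  (median 0) is as designed. A selector that ignores false-selection
  control would trivially push sensitivity to 1; we keep the calibrated
  one.
* Frequency-weight standard errors treat oocytes as independent within a
  couple.
* Bootstrap CIs condition on the selected mediator set (no
  selection-uncertainty propagation).
* GEE normal-approximation p-values are anti-conservative below roughly
  50–100 subjects unless `small_sample=True`.
* Real-array preprocessing (normalization, batch correction,
  cross-reactive-probe discovery) is out of scope; exclusion lists are
  user-supplied.
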