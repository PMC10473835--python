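# Methods

## Bridging normalization

Two cohorts measured on separate plate sets share no samples except pooled
plasma controls ("bridge" samples): two per plate, four plates per cohort,
eight per cohort. Because the bridge aliquots come from one pool, any
systematic difference between their readings in the two cohorts is
technical. For each protein the offset

    X_p = median(bridge NPX, cohort A) − median(bridge NPX, cohort B)

is subtracted from every cohort-A value, study and bridge alike, and from
cohort A's per-protein LOD (so a value's below-LOD status cannot change
under bridging). The median over eight replicates uses the midpoint of the
two central order statistics; with so few replicates this convention is
observable and is therefore fixed and tested. The construction guarantees
post-bridge bridge-median equality to machine precision, is
translation-equivariant (adding a constant to cohort A changes X by that
constant and leaves the bridged data unchanged), and removes cohort-wide
technical offsets without touching genuine biology — properties the test
suite checks directly. Offsets are undefined for proteins with fewer than
two bridge readings in either cohort; such proteins pass through unadjusted
with a warning rather than being silently dropped.

Which cohort receives the subtraction is a configuration choice; the
default subtracts from cohort A (the first argument). Inter-plate control
normalization is assumed to have happened upstream in the vendor pipeline,
so the package models only small residual plate effects and does not
re-normalize plates.

## Below-LOD handling

Values below the limit of detection are retained exactly as measured —
censoring to the LOD or imputing would truncate the lower tail and bias
downstream regressions. The LOD is used only for exclusion: a protein is
dropped when strictly more than 25% of study samples (bridge samples are
not in the denominator) lie strictly below its LOD. A value exactly equal
to the LOD counts as detected. Three family modes exist because exclusion
counts can legitimately be tallied per cohort or jointly:

* `per_cohort` (default): each cohort drops its own censored proteins, so
  the cohorts can retain different panels; the cross-cohort contrast then
  uses the intersection of retained panels, since a contrast needs the
  protein measured in both cohorts.
* `both`: one shared list — excluded only if censored above threshold in
  both cohorts.
* `either`: the conservative union.

## PCA outlier screening

Per cohort, study samples are screened once (no iteration) with PCA on the
centered, unit-variance-scaled matrix; a sample is flagged when its PC1
or PC2 score is more than 3 SD from that component's mean. Under a
Gaussian null the per-sample flag probability is 1 − (1 − 2Φ(−3))² ≈ 0.54%,
and the suite checks the empirical rate against this closed form. Scaling
is on by default for screening (NPX columns can have very different
variances); for joint two-cohort ordination plots scaling is typically
left off because NPX is already on a common log2 scale. Component signs
follow the convention that each component's largest-magnitude loading is
positive, making score outputs deterministic. A zero-variance component
contributes no flags, and zero-variance features are dropped (with a
warning) before scaled PCA. Because the rule is applied once, the pipeline
is idempotent only when the remaining data has no mass beyond 3 SD; the
suite demonstrates idempotence on bounded-noise data, which is the honest
statement of the property.

The pipeline stage order is fixed: bridge → LOD filter → outlier removal.
Bridging first, because offsets are defined on the full panel; LOD
filtering before PCA, so the screen operates on the analysable panel.

## Moderated differential expression

Per protein, OLS of NPX on an intercept, a cohort indicator and covariates
(age in years, sex reference-coded with `male` as reference, BMI in kg/m²,
all untransformed). The cohort coefficient is the log2 fold change.
Samples with missing covariates are dropped for all proteins; samples with
a missing response are dropped per protein (pairwise complete). The design
must be full column rank; proteins with fewer than one residual degree of
freedom are skipped with a recorded reason.

Variance moderation uses the standard scaled-inverse-chi-squared
empirical-Bayes construction. The prior (d0, s0²) is moment-matched on the
log residual variances: with e_g = log s²_g − ψ(df_g/2) + log(df_g/2), the
excess of var(e) over mean ψ′(df/2) identifies ψ′(d0/2) (solved by Newton
iteration on the trigamma function), and s0² follows from the mean. When
the observed spread does not exceed the sampling expectation, d0 = ∞ and
every posterior variance equals s0²; when the variances are exactly equal
(a degenerate input), s0² is that common value. Posterior variances are

    s²_post = (d0·s0² + df·s²_g)/(d0 + df)

and t_mod = β/(u·s_post) with d0 + df degrees of freedom. The d0 = 0 limit
reproduces classical OLS inference exactly, which the suite verifies to
1e-10 relative error against an independently coded per-protein oracle.
Moderation is the default and can be disabled (`moderated=False`), since
with several hundred samples per cohort the two differ little. Fewer than
10 proteins triggers a low-confidence warning on the prior.

FDR is Benjamini–Hochberg within one contrast family (all proteins of the
scan); the gate is FDR < 0.05. The ±0.5 log2 fold-change lines on volcano
plots are display thresholds only, never significance gates. The paired
pre/post contrast (dietary-intervention design) uses the mean
within-subject difference and the paired t-test; post = pre exactly gives
beta 0 with p = 1 and a degeneracy flag.

## Association scans

Factor scans fit, per protein, OLS of the analyte on one factor plus
adjustment covariates. The default adjustment for any of {age, sex, BMI}
is the other two; environmental exposures are adjusted for age and sex.
FDR is controlled across proteins within each (factor, cohort) family and
binned into stars: \*\*\* < 0.0001, \*\* < 0.005, \* < 0.05, strict
inequalities. A standardized option z-scores analyte and continuous factor
so betas are scale-free. The pQTL scan uses additive dosage models with
age + sex adjustment (the covariate set is an assumption, configurable),
reports unadjusted p-values and flags 5×10⁻⁸ (genome-wide) and 5×10⁻⁶
(suggestive); monomorphic SNPs are skipped with a reason.

## Two-layer clustering and enrichment

Food-derived metabolites (the `food_derived` flag is curated input, not
computed here) are clustered with Ward linkage on Euclidean distances of
per-feature z-scores, cut at k = 2. The proteome is clustered with k-means
(Euclidean, 100 random restarts, lowest within-cluster sum of squares
kept, seed-reproducible). Labels are canonical — cluster 1 is the cluster
with the lower mean of the clustered data ("lower-expressed"), ties broken
by size then smallest member id — so repeated runs compare equal.
Enrichment of annotations across proteome clusters uses Pearson chi-square
without continuity correction (so the 2×2 statistic equals the closed-form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), verified to 1e-10), Fisher's exact test
when any expected 2×2 cell is below 5, and Mann–Whitney U for continuous
annotations (rank-biserial effect), with BH FDR across annotations.

The metabolite × protein matrix fits protein ~ metabolite + age + sex per
pair, with both sides z-scored so betas are standardized; metabolite
intensities are assumed log-scale on input and missing values are excluded
pairwise, never imputed. The FDR family is the whole matrix by default
(most conservative sensible choice); a per-protein family is available by
flag. Class summaries aggregate medians and significant fractions without
new inference. The full matrix is always exported; `top_pairs` is a
display filter only.

## Synthetic cohorts: what is emulated, what is not

The generator reproduces the structure the pipeline must survive: two
cohorts of 318 and 416 study samples on a 92-protein log2 panel; four
plates per cohort with two bridge controls each; a cohort-wide technical
offset (default 0.5 log2; bridge replicate noise sd 0.05 log2, the
precision of technical replicates of one pool; residual plate offsets sd
0.05 log2, small because inter-plate normalization is upstream); sparse
cohort effects of 35 up-regulated proteins spanning 0.3–1.9 log2 and 20
down-regulated spanning −0.8 to −0.3; age (0.01 log2/year), sex (−0.2 log2
for females) and BMI (0.02 log2 per kg/m²) effects on protein subsets; LOD
censoring at the 30% quantile for 18 proteins in both cohorts plus two
more in cohort A only (so the per-cohort rule retains 72 and 74 proteins);
1.6% of samples moved to ±6 SD on both of the two leading PCs (outliers
are planted after all other structure, so the screen sees them on its
leading components); per-protein noise variances from a
scaled-inverse-chi-squared(d0 = 4, s0² = 0.25) family — deliberately the
family the moderation engine assumes, making prior recovery a fair test;
a 400-metabolite matrix (288 food-derived) with two latent diet clusters
shifting 80 metabolites by 1.5 log units and 30 proteins by 0.5 log2; one
metabolite coupled to five proteins at −0.3 log2 per SD; and six
Hardy–Weinberg SNPs (MAF 0.1–0.4) with no true protein effects. Metadata
mirrors the two populations' profiles (median ages 30 vs 23, BMI 23.8 vs
22.3, ~51% female, 79% urban residency and the exposure frequencies of the
first cohort).

All randomness flows from one seed through integer-indexed generator
streams, so identical configs give byte-identical outputs on any platform.

Not emulated: non-Gaussian and skewed NPX error, plate-position and
freeze–thaw artefacts, correlated protein modules beyond the injected
structures, LD between SNPs, metabolite missingness below detection, and
real dietary covariance structure. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that real
cohort differences of any particular size will be detected.

## Numerical choices

Medians: midpoint convention for even counts. Below-LOD: strict `<`;
exclusion rule: strict `>` 25%. PCA via SVD with the largest-|loading|
sign convention; mean-fill for missing cells with provenance. Trigamma
inversion by Newton iteration (50 iterations, relative tolerance 1e-10).
p-values clipped to (tiny, 1]. CSV floats written as `%.17g` and parsed
with round-trip precision so read→write→read is exact. K-means tie-breaks
are removed by canonical relabelling. Report hashes strip wall-clock
timings so reruns hash identically.

## Problem sizes in the tests and acceptance script

The suite runs the replicated checks at the sizes the properties are
stated for: 200 null replicates at 318/416 × 92 for FDR control, 200 × 700
Gaussian samples for the outlier-rule calibration, 100 runs for the
two-layer cluster association, 500 proteins at df = 100 for prior
recovery. The acceptance script uses 100 null replicates and 50 cluster
runs, which gives the same estimates to well within their Monte-Carlo
error at a few seconds' runtime.

## Known limitations

* Bridging assumes the pooled controls behave like study plasma for every
  protein; matrix effects that differ between pool and study samples are
  not detectable from bridge data alone.
* The 3-SD rule is applied once by design; heavily contaminated data can
  mask additional outliers.
* Moderation assumes exchangeable variances across the panel; strong
  variance–mean structure would call for a trended prior, which is not
  implemented.
* Factor scans are marginal one-factor-at-a-time models with fixed
  adjustment sets, not a joint model; collinear exposures will share
  signal.
* k is fixed at 2 for both clustering layers; no model-selection
  (silhouette, gap statistic) is performed.
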