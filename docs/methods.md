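# Methods

## Scope and model overview

`proteffect` analyses protein-group quantification matrices from label-free
DIA experiments with a two-group (two-diet) design of 8 biological
replicates per group. The statistical core is (i) an empirical-Bayes
moderated two-sample t-test on preprocessed log2-like intensities, (ii) a
dual p-value/fold-change rule for calling differentially abundant proteins
(DAPs), and (iii) an empirical effect-size construction that compares the
DAP percentage between groups against the DAP percentage obtained when the
*same* group's replicates are split in half and compared against themselves.

The within-group comparisons are a genuine negative control: they pass
through the identical pipeline — detection filter, normalization,
imputation, testing, calling — so their DAP percentage estimates the
combined false-call rate of biology-free variation plus every artefact the
pipeline itself introduces. The between/within ratio is therefore an
effect-size measure that is robust to miscalibration anywhere upstream.

## Preprocessing

**Detection filter.** A protein enters a comparison when it has at least
`min_detect` (default 3) observed values out of `group_size` (default 4)
replicates in at least one of the two groups (`any_group`; `all_groups`
demands it in both). Zero intensities in the input are treated as
non-detections, i.e. missing, because a zero MaxLFQ value is the absence of
a quantification, not a measurement. The filtered row count is the
comparison's "total", the denominator of the DAP percentage — it varies
between comparisons because different sample subsets detect different
proteins, and only the filter may cause this (normalization and imputation
never drop proteins the filter kept).

**Variance-stabilizing normalization.** Each sample s is calibrated by an
affine map and passed through the generalized log:
h_s(x) = arsinh(a_s·x + b_s)/ln 2. At high intensity h_s ≈ log2(2·a_s·x), so
differences of normalized values read as log2 ratios; at low intensity the
arsinh compresses rather than explodes. Parameters are fitted per sample by
least trimmed squares (trim fraction 0.1) against the across-sample
row-median reference profile, with two alternating reference/fit passes.
Numerical choices: the scale is parameterized as exp(log a) to keep it
positive (the transform is then strictly increasing, so within-sample ranks
are preserved); the optimizer is started from a median-matched scale; and
because the offset b is identified only by the faint tail of the intensity
distribution, an extra penalty residual charges for the log2 distortion the
offset induces at the 5th-percentile intensity — without it, b can drift to
values that bend the transform around a handful of faint proteins.

A consequence of trimming worth knowing: the trimmed fit fully rejects
differential (outlying) rows only while their fraction stays within the trim
fraction. With ≳10–20% strongly differential proteins of predominantly one
sign, a small calibration bias (a few hundredths of a log2 unit) can leak
in, exactly as with any robust location estimator past its breakdown point.

**MLE imputation.** Per comparison, proteins are treated as i.i.d.
observations of a multivariate normal over the comparison's samples
(p = 8 variables). The EM algorithm estimates the mean and covariance in the
presence of missing cells, grouping rows by missingness pattern; missing
cells are replaced by their conditional means given the row's observed
cells. Observed cells are never altered, all-missing rows are dropped (they
cannot pass the detection filter anyway), and the completion is
deterministic. Numerics: a minute ridge (1e-12 × mean diagonal) keeps the
covariance positive definite for degenerate (perfectly correlated) data —
kept this small so that conditional means stay within ~1e-9 of their exact
closed forms; convergence is declared at a relative log-likelihood change
below 1e-10 or at parameter stagnation (the likelihood grows without bound
as the covariance approaches singularity, so a parameter criterion is
needed precisely in the degenerate case); the log-likelihood is asserted
non-decreasing except once the covariance is within the ridge-dominated
regime; at most 1000 iterations, after which a convergence error carries
the likelihood trace.

Imputation happens after normalization, per comparison, on the columns of
the two groups being compared — the statistics downstream are per
comparison, so sharing information across unrelated samples would leak
between comparisons.

## Moderated test and DAP calling

For each protein, group means on the normalized scale give
Δ = mean(g2) − mean(g1) (log2 fold change; the raw-scale fold change 2^Δ is
a ratio of geometric means). The pooled residual variance s² has
d = n₁ + n₂ − 2 degrees of freedom. The variance ensemble is modelled as
scaled-F around a prior (s²₀, d₀) estimated by moment matching on log s²
(mean and variance of log s² corrected by digamma/trigamma terms; d₀ from
trigamma inversion by Newton iteration). Each protein's variance is shrunk
to its posterior s²_post = (d₀·s²₀ + d·s²)/(d₀ + d), and

    t = Δ / sqrt(s²_post · (1/n₁ + 1/n₂))

is referred to Student-t with d + d₀ df (standard normal when d₀ = ∞, which
is also the estimate whenever the spread of log variances does not exceed
the chi-square sampling expectation; exact zero variances are offset to
1e-5 × the median variance before taking logs). The implementation agrees
with the reference empirical-Bayes implementation in R (limma's `eBayes`) to
~1e-13 on the t statistic in both the finite and infinite prior-df regimes;
the one deliberate difference is that with d₀ = ∞ p-values use the normal
reference rather than a capped total df, which changes p by < 1e-3 at these
group sizes.

**Calling.** increased ⇔ 2^Δ ≥ 1.3 and p < 0.05; decreased ⇔ 2^Δ ≤ 0.76 and
p < 0.05; otherwise unchanged. Boundary fold changes qualify (≥/≤); a p
exactly at the cutoff does not (<). Unadjusted p-values are used for
calling — at n = 4 per group, FDR adjustment costs more power than its
type-I control is worth — while Benjamini–Hochberg adjusted values are
computed and written alongside. Note the printed thresholds are slightly
asymmetric (0.76 ≠ 1/1.3 = 0.769), so label-swap symmetry under group
exchange is only exact when the reciprocal threshold is configured.
Volcano coordinates are (Δ, −log10 p) with unadjusted p.

## Effect-size construction

Halving: each diet's 2×`group_size` replicates are split into two halves.
The default split is deterministic by replicate number (lowest
`group_size` replicates = half 1), which makes runs exactly reproducible
with no seed bookkeeping; a seeded random split is available
(`assign_halves(..., mode="random")`). Which four replicates form a half is
arbitrary by design — the within-diet comparison is a null either way.

Three comparisons per tissue: within g1 (half 1 vs half 2 of diet 1),
within g2, and between (half 1 of diet 1 vs half 1 of diet 2; optionally
all 8 vs all 8). Percentages are rounded half-even to two decimals.
Tissue-level summaries aggregate into the mean within-group percentage, the
mean between-group percentage (arithmetic means over the comparisons run,
reported to one decimal) and their ratio.

## PLS-DA

Two-class PLS-DA is PLS1 regression of a ±1 class indicator on the
(auto)scaled matrix, fitted by NIPALS with deflation of X and y per
component. Autoscaling (mean-center + unit variance per protein) is the
default, matching the common metabolomics convention; zero-variance
proteins are dropped under autoscaling. Signs are fixed by making each
weight vector's largest-magnitude element positive. Scores of different
components are exactly orthogonal; per-component explained X variance is
‖t p′‖²/‖X‖², which for PLS need not decrease with component number. The
95% confidence ellipse of a class's 2-D scores uses the sample mean and
covariance scaled by the chi-square(2) quantile; fewer than 3 points or a
singular covariance is an error.

## PRM validation

Transition areas are summed per (peptide, sample) and log2-transformed; a
zero total area is a non-detection (missing). The protein-level value per
sample is the unweighted mean of its peptides' log2 sums — unweighted
because peptide response factors are unknown and a mean is symmetric in
them. Groups are compared with the pooled two-sample Student t (two-sided;
t > 0 when group 2 exceeds group 1). Zero pooled variance degenerates to
(t = 0, p = 1) for equal means and is an error for unequal means, where no
finite statistic exists. Concordance with the DIA analysis is the fraction
of shared proteins whose fold-change direction agrees.

## Growth indices

SGR = (ln W_final − ln W_initial)/days × 100 (%/day);
FCR = feed intake / wet weight gain (dimensionless);
RFI = daily intake / geometric-mean body weight in kg (g·kgBW⁻¹·day⁻¹).
A 12-week trial is 84 days. Reporting precision is three decimals.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with known
ground truth:

* log2 baselines ~ Normal(20, 2) — MaxLFQ-like intensities around 10⁶;
* per-protein residual variances ~ InverseGamma(shape 3, scale 0.08),
  i.e. typical residual SDs near 0.2 log2 units, matching the scaled-F
  ensemble the moderated test assumes;
* a fraction `pi_dap` (default 0.1) of proteins carries a diet effect of
  ±`effect_log2fc` (default 1.5) with equal sign probability;
* per-sample log2 shifts ~ Normal(0, 0.5) — the normalization challenge;
* missingness is applied to the *scaled* intensity through a logistic
  detection curve (threshold 17, slope 1.5 on the log2 scale, ~15–20%
  missing cells overall), so low-abundance cells go missing
  preferentially (MNAR), after sample scaling because detection depends on
  what the instrument saw;
* defaults sized like one tissue of an 8+8 feeding trial with 4000
  proteins (tests use 250–4000 depending on what they measure).

A PRM layer re-expresses a protein subset (the strongest planted
responders) as 2–4 peptides × 3–6 transitions with Dirichlet-weighted area
apportionment and lognormal noise around the same latent abundances, so
DIA/PRM concordance has a shared ground truth. A growth layer draws
tank-level records with gain ≡ final − initial by construction.

What the generator does **not** emulate: correlated proteins (co-regulation,
shared peptides), batch structure or drift within a group, heavy-tailed or
outlier contamination, interference/carry-over in PRM, and
missingness-at-random mixtures. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, calibration of the
null pipeline, and recovery of planted effects — not robustness to every
pathology of real instrument data.

## Known limitations

* Two groups only; no covariates, pairing, or multi-factor designs.
* The normalization's trimmed fit assumes differential proteins are a
  minority within the trim fraction (see above).
* EM imputation treats proteins as exchangeable draws from one multivariate
  normal per comparison; strongly multimodal abundance distributions are
  summarized by a single covariance.
* PLS-DA offers no cross-validation or permutation testing; it is an
  ordination/visualization aid, not a classifier with error control.
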