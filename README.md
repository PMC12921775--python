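# proteffect

Differential protein abundance and empirical effect-size estimation for
label-free DIA proteomics feeding trials.

## The problem

A feeding trial compares two diets (A and B) by quantifying the proteome of
several tissues with data-independent acquisition (DIA) mass spectrometry.
The search engine (e.g. DIA-NN) delivers a protein-group × sample intensity
matrix (`report.pg_matrix.tsv`); the analysis must decide which proteins are
differentially abundant (DAPs) between diets, and — harder — how large the
dietary effect is relative to the biological and technical noise floor.

`proteffect` implements the full post-search pipeline:

1. **Ingestion** of pg_matrix TSVs and sample-design tables (`proteffect.io`).
2. **Preprocessing** (`proteffect.preprocess`): detection filtering (≥ 3 of 4
   replicates per group), variance-stabilizing normalization
   h_s(x) = arsinh(a_s·x + b_s)/ln 2 with per-sample affine calibration, and
   maximum-likelihood (EM, multivariate normal) imputation by conditional
   means.
3. **Moderated testing** (`proteffect.diffabund`): empirical-Bayes shrinkage
   of per-protein variances, s²_post = (d₀s²₀ + d·s²)/(d₀ + d), the moderated
   t referred to Student-t with d + d₀ df, BH-adjusted p-values reported, and
   the dual DAP rule: p < 0.05 (unadjusted) and raw fold change 2^Δ ≥ 1.3 or
   ≤ 0.76.
4. **Effect size** (`proteffect.effectsize`): each diet's 8 replicates are
   split into halves of 4; A vs A and B vs B comparisons form an empirical
   null, A vs B carries the signal. The percentage of DAPs among the proteins
   surviving the detection filter in each comparison is the effect-size
   scale; the between/within ratio is the headline multiplier.
5. **Ordination** (`proteffect.multivariate`): two-class PLS-DA via NIPALS
   with score-plot confidence ellipses.
6. **Targeted validation** (`proteffect.targeted`): PRM transition-area
   summation, log2 transform, peptide→protein rollup, pooled Student t, and
   direction concordance with the DIA calls.
7. **Growth indices** (`proteffect.growth`): SGR, FCR, RFI.
8. **Synthetic data** (`proteffect.simulate`): ground-truth DIA-like
   matrices with planted effects, per-sample scale shifts and
   intensity-dependent (MNAR) missingness, plus PRM tables and growth
   records, so every stage is testable without any download.

## Worked example

```python
import proteffect as pe

cfg = pe.SimConfig(seed=7, n_proteins=2000)   # two diets × 8 replicates
matrix, truth = pe.generate_matrix(cfg)       # raw pg_matrix + ground truth
design = pe.generate_design(cfg)
res = pe.EffectSizeStudy(matrix, design, pe.AnalysisConfig(seed=7)).fit()
print(res.summary())
```

```
Within- vs between-group effect size
================================================
tissue comparison  total  increased  decreased  total_changed  pct_changed
 brain  within_g1   1826          7          7             14         0.77
 brain  within_g2   1780          6          3              9         0.51
 brain    between   1803         97         98            195        10.82
------------------------------------------------
mean within-group DAP percentage:  0.6%
mean between-group DAP percentage: 10.8%
between/within ratio:              16.91
```

Reading the output: each row is one four-vs-four comparison run end to end
(filter → normalize → impute → moderated test → call). The `total` column is
the number of proteins passing the detection filter *for that comparison*,
which is why it differs between rows. The within-diet rows estimate the
false-call floor (~0.6% here); the between-diet row recovers most of the
planted 10% of diet-responsive proteins, so the between/within ratio far
exceeds 1 — a diet effect well above the noise floor.

The same machinery is available from the shell:

```bash
proteffect simulate --seed 7 --n-proteins 2000 --out sim/
proteffect effectsize --matrix brain=sim/pg_matrix.tsv --design sim/design.tsv --out report/
proteffect growth --records growth.tsv --out indices.tsv
```

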