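# hdlc — likelihood-based testing of regional genetic colocalization

`hdlc` decides whether two traits share their genetic architecture at a
genomic locus — for example a plasma protein and a disease around the
protein's encoding gene — using only GWAS summary statistics (per-variant
Z-scores and sample sizes) and an LD reference for the region. Instead of
enumerating causal-variant configurations, it quantifies colocalization
through a single parameter, the **local genetic correlation**

```
rG = h12 / sqrt(h1² · h2²),
```

where `h1²`, `h2²` are the two traits' regional SNP heritabilities and
`h12` their regional genetic covariance, and tests

```
H0: |rG| ≤ r0      vs.      HA: |rG| > r0
```

for a user-chosen colocalization threshold `r0 ∈ [0, 1)`. `r0 = 0` is the
standard test of any shared regional signal; `r0 = 0.5` (the suggested
default for biomarker work) demands that the effect vectors be strongly
proportional, not merely correlated.

## Model

Regional Z-score vectors of the two traits are modelled jointly as a
zero-mean multivariate normal,

```
Σᵢᵢ = (Nᵢ hᵢ²/M)·L + R,        Σ₁₂ = (√(N1·N2) h12/M)·L,
```

with `R` the M×M LD correlation matrix and `L = R·R` the LD score matrix
(its diagonal holds the classical per-variant LD scores). Because `R` and
`L` share eigenvectors, the 2M-dimensional likelihood factors into M
independent 2×2 problems in the eigen-basis of `R`, which is what makes
the fit fast (milliseconds per region).

Heritabilities are estimated by single-trait maximum likelihood, then the
profile likelihood of `h12` is maximized with and without the null
constraint `|h12| ≤ r0·√(ĥ1²ĥ2²)` (safeguarded Newton–Raphson, step
tolerance 1e-6). For `r0 > 0` the LRT statistic Λ follows the
chi-bar-square mixture `½χ²₀ + ½χ²₁` under the null boundary, giving
`p = ½·Pr(χ²₁ ≥ Λ)`; at `r0 = 0` the constraint is an equality and the
plain `χ²₁` tail applies. A profile-likelihood 95% CI for `rG` is
reported alongside.

## Worked example

`examples/01_test_one_region.py` simulates a 300-variant cis region with
true `rG = 0.8` (protein N = 30,000, disease N = 300,000) and tests it at
two thresholds:

```
r0=0.0: rG_hat=+0.798 [95% CI +0.678, +0.876]  Lambda=  65.937  p=4.66e-16
r0=0.5: rG_hat=+0.798 [95% CI +0.678, +0.876]  Lambda=  15.896  p=3.35e-05
```

The estimate recovers the simulated correlation; the `r0 = 0.5` line says
the correlation credibly *exceeds* 0.5 — strong colocalization — not just
that it is nonzero. The other examples cover the file-based
sumstats workflow (cis windows, MAF filtering, allele harmonization,
top-SNP heritability) and operating-characteristic evaluation on a
simulation grid (AUC by colocalization threshold, boundary-null
calibration).

## Command line

A thin CLI wraps the same library calls and writes a manifest and log per
run:

```
hdlc test --sumstats1 protein.tsv --sumstats2 disease.tsv \
          --ld region.ld --ld-snplist region.snplist \
          --r0 0 --r0 0.5 --out results/
hdlc simulate --scenario scenario.txt --out sim/
hdlc evaluate --replicates sim/replicates.tsv --out eval/
```

Results are TSV (one row per region and threshold: heritabilities,
`h12`, `rG`, Λ, p, CI, flags) with Benjamini–Hochberg adjustment across
regions by default.

## Simulation and evaluation framework

`hdlc.simulate` reproduces the evaluation design end to end: causal
effects drawn from a bivariate normal with target heritabilities and
correlation, either a fraction (polygenic) or a count (sparse) of causal
variants, and Z-scores generated three ways — individual-level
(standardized genotypes, phenotypes with unit total variance, marginal
regression), conditional-on-effects summary sampling, or directly from
the model's multivariate normal. `hdlc.evaluation` provides rank-based
ROC/AUC, TPR at fixed FPR, top-N rediscovery rates between independent
cohorts, and chi-bar-square null-calibration summaries.

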