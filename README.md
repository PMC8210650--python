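# paleokin

Kinship inference for sparse ancient-DNA genotypes, with the co-burial,
spatial and radiocarbon statistics used to interpret relatedness among
archaeologically excavated individuals.

Ancient genomes are typically sequenced at 0.01–5× coverage, so genotypes
are pseudo-haploid — one randomly sampled read per site treated as
homozygous — riddled with missingness, and biased by post-mortem damage.
`paleokin` is for researchers who need to ask, from such data: *which of
these co-buried individuals were biological kin, what exactly was the
relationship, and do burial practices track genetic relatedness?*

## What it computes

**Kinship.** The kinship coefficient θ is the probability that single
alleles drawn from two individuals are identical by descent; the Cotterman
coefficients (k₀, k₁, k₂) are the probabilities of sharing 0, 1 or 2
alleles IBD at a locus, with

&nbsp;&nbsp;&nbsp;&nbsp;θ = k₁/4 + k₂/2.

Two estimators are provided: a windowed mismatch-rate statistic (P0 in
1-Mbp windows, normalised by the cohort median, so 1 − P0/median ≈ θ) and a
maximum-likelihood EM fit of (k₀, k₁, k₂) from per-site genotype-pair
likelihoods with background allele frequencies and an explicit error rate.
Estimates carry bootstrap confidence intervals and are reported only above
overlap thresholds (≥ 5,000 autosomal SNPs, ≥ 800 X SNPs) below which such
estimators are unreliable.

**Calibrated classification.** Because the sampling spread of θ̂ depends on
the SNP overlap, degrees of relatedness (1st/2nd/3rd/unrelated) are called
against quantile ranges simulated from pedigrees at matched SNP counts —
including X-chromosome transmission (fathers pass their single X to
daughters only), which separates mother-son (θ_X = 1/2), sisters (3/8),
father-son (0) and the rest among first-degree pairs. A rule-based
classifier combines θ_auto, θ_X, the θ_auto/θ_X ratio moments, mtDNA
sharing, sex, age class and radiocarbon death order into ranked pedigree
labels with explicit exclusion reasons.

**Site statistics.** Outgroup f3 / D statistics with weighted block
jackknife, 1 − f3 genetic distances, a Mantel test against burial-plan
distances, a within-building similarity permutation test, a within-group
diversity permutation contrast, and Fisher exact tests (conditional-MLE
odds ratio) on with/without-relative co-burial counts.

**Radiocarbon.** Ward–Wilson χ² combination of replicate ages,
probability-method calibration against a calibration-curve table (standard
IntCal layout), 95% ranges rounded outward to 5 years, and pairwise
died-first probabilities from independent calibrated posteriors.

**Synthetic cohorts.** A first-class generator produces every input the
pipeline consumes — pedigree-structured genotypes with coverage-dependent
missingness and error, maternal-line mtDNA, kin-clustered burial layouts,
radiocarbon measurements — with ground-truth tables attached, so the whole
pipeline is testable end to end.

## Worked example

```python
from paleokin import SimConfig, generate_dataset, ml_cotterman, fisher_exact
from paleokin.kinship_core import bootstrap_theta, classify_degree
from paleokin.pipeline import RunConfig, calibrate_ranges

data = generate_dataset(SimConfig(seed=7))          # 14-member cohort
panel = data.panel.subset(data.panel.autosomal_mask())
gm = data.observed.subset_snps(data.panel.autosomal_mask())

est = ml_cotterman(gm, panel, ("C0", "F0"), eps=0.005)
lo, hi = bootstrap_theta(gm, panel, ("C0", "F0"), n_boot=100, seed=0)
print(f"pair C0-F0: theta = {est.theta_auto:.3f} "
      f"(95% CI {lo:.3f}-{hi:.3f}, {est.n_snps_auto} SNPs)")

ranges, _ = calibrate_ranges(RunConfig(seed=7, n_calibration_reps=15))
call = classify_degree(est.theta_auto, est.n_snps_auto, ranges)
print(f"degree call: {call.degree}")

res = fisher_exact([[8, 2], [6, 14]])
print(f"co-burial contrast: OR = {res.odds_ratio:.1f}, p = {res.p_value:.3f}")
```

prints

```
pair C0-F0: theta = 0.237 (95% CI 0.202-0.272, 5000 SNPs)
degree call: 1st
co-burial contrast: OR = 8.6, p = 0.019
```

C0–F0 is a true parent-offspring pair (θ expectation 0.25); at 5,000
pseudo-haploid SNPs the estimate lands at 0.237 with a CI well clear of
both the unrelated and second-degree ranges, so the simulation-calibrated
call is first degree. The Fisher test reproduces a with/without-relative
contrast between two groups of burial sites: individuals in the first group
were co-buried with an identified close relative far more often (8 of 10)
than in the second (6 of 20).

A command-line interface mirrors the library:
`paleokin simulate | ranges | estimate | classify | sitestats | c14 | run`,
each stage reading and writing plain TSV/YAML.

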