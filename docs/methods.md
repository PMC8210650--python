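# Methods

`paleokin` estimates biological kinship between pairs of individuals from
sparse, error-prone genotype data of the kind produced by ancient-DNA
sequencing, and couples those estimates with the archaeological statistics
(co-burial contingency, burial-distance correlation, radiocarbon ordering)
used to interpret them. This note records the models, the defaults, and the
choices made where the design was genuinely open.

## Genotype model and cleaning rules

Calls live in an individuals × SNPs matrix with an explicit missing state.
Two ploidy regimes are supported: diploid (0/1/2 alt-allele counts) and
pseudo-haploid, the ancient-DNA standard in which one sequencing read is
drawn per site and treated as a homozygous call (values 0/1 only). Male X
chromosomes are haploid in either regime.

Cleaning follows the conventions of low-coverage ancient-DNA work:

- **Transversion-only panels.** Post-mortem cytosine deamination produces
  C→T (and, read on the opposite strand, G→A) miscalls, so C/T and A/G SNPs
  are removed before any estimation.
- **Damage masking.** At remaining transition-like sites, an observed T
  where the reference genome carries C, or an observed A where it carries
  G, is coded missing.
- **X panel preparation.** Pseudo-autosomal regions (supplied as half-open
  bp intervals — coordinates are a configuration input, since the reference
  build determines them) are excluded, and a minor-allele-frequency floor
  of 0.10 (inclusive) is applied where background frequencies are known.
- **Strand-ambiguous (A/T, C/G) SNPs** are dropped when merging panels.

SNP positions are 1-based inclusive; PAR intervals half-open `[start, end)`.

## Kinship estimation

Two estimators are implemented; they are methodologically independent and a
test asserts they rank a mixed cohort concordantly (Spearman ≥ 0.9).

**Windowed mismatch rate.** For each pair, the mismatch rate *P0* of
pseudo-haploid calls is computed in non-overlapping 1-Mbp windows and
averaged (unweighted by default; a SNP-weighted variant is behind a flag —
pair-specific missingness means the realised windows differ per pair).
Dividing by the median *P0* across all pairs — the level of an average
unrelated pair — and subtracting from one gives a kinship-coefficient
proxy: unrelated pairs sit near 0, parent-offspring near 0.25, identical
genomes near 0.5.

**Maximum-likelihood Cotterman coefficients.** The Cotterman coefficients
(k0, k1, k2) are the probabilities that a pair shares 0, 1 or 2 alleles
identical by descent at a locus; the kinship coefficient is
θ = k1/4 + k2/2. Per SNP, the likelihood of the observed calls given m
shared alleles uses the classical conditional genotype-pair distributions
under Hardy–Weinberg with background allele frequencies (an input, never
estimated from the cohort itself), and an explicit symmetric allele-error ε
(default 0.005). For pseudo-haploid calls the observation is one sampled
allele per individual: the two sampled alleles are IBD with probability
m/4, giving a two-component site likelihood.

*Identifiability.* With single sampled alleles and no linkage information,
the likelihood depends on (k0, k1, k2) only through θ: the decomposition is
a ridge and only θ is identifiable. Downstream classification therefore
uses θ; the full decomposition is meaningful on diploid data (and is what
the identity-pair and grid-search tests exercise).

*Optimisation.* EM over the 2-simplex, initialised at (1/3, 1/3, 1/3),
accelerated by squared extrapolation (SQUAREM) with a monotonicity
safeguard: an extrapolated step is taken only when it does not decrease the
log-likelihood, so the recorded trajectory is non-decreasing. Plain EM
creeps near simplex boundaries (an unrelated pair at 157k SNPs has its MLE
on the k0 edge); convergence is therefore declared on KKT stationarity
(max_m mean_i(L_im/mix_i) − 1 < 1e-8) or on a log-likelihood gain below
1e-9 with the KKT residual already below 1e-5. At these tolerances the EM
solution matches an exhaustive simplex grid search (step 0.001) to well
under 0.005 per coefficient on 50-SNP toys.

**Uncertainty** is a percentile bootstrap over SNP columns (100 replicates,
2.5/97.5 percentiles).

**Thresholds.** Autosomal estimates are reported only for pairs sharing
≥ 5,000 SNPs and X estimates only with ≥ 800 (both inclusive). Below these
overlaps, kinship estimators produce spurious non-zero values for pairs
that cannot be close relatives; pairs failing the autosomal threshold are
excluded with a recorded reason, pairs failing only the X threshold keep
their autosomal estimate.

## Pedigree simulation and calibrated ranges

Because the sampling error of θ̂ depends strongly on the SNP overlap,
classification boundaries come from simulation at matched SNP counts rather
than fixed cutoffs.

Founder haplotypes are drawn per-site Bernoulli from the panel frequencies.
This removes any external-data dependency but means founders carry no
background linkage disequilibrium; that is acceptable here because every
downstream estimator is single-SNP-likelihood based, and it is the main
respect in which passing tests do not speak to LD-aware methods or to
real-data haplotype structure.

Autosomal transmission draws crossovers from a Poisson process on the
genetic map (1 per Morgan); a stationary gamma-renewal process with a shape
parameter is available for crossover-interference stress tests (the
default is Poisson — interference is irrelevant to single-SNP kinship
statistics). The X chromosome uses a four-segment model: three distinct cut
points drawn among SNP positions split the maternal X, and each segment is
copied whole from one of the two maternal haplotypes with probability 1/2.
Sons receive only the maternal gamete; daughters also receive their
father's single X unchanged. Cut points are drawn without replacement
(coincident cuts would silently reduce the segment count). Pedigree-derived
oracles for this model — mother-son and father-daughter X kinship 1/2,
sisters 3/8, brother-sister and mother-daughter 1/4, father-son 0 — are
verified both by path counting on the pedigree graph and by realized
IBD-label transmission.

Range tables store, per (statistic, relationship class, SNP count), the
0.025 and 0.975 quantiles of the simulated estimate distribution; the
unrelated class uses [0, q0.95] (one tail, zero as the natural lower edge).
Lookups between tabulated SNP counts use the nearest lower count, whose
bounds are wider — the conservative direction. The default simulation
pedigree is a configurable three-generation design (founder couple,
married-in spouses, grandchildren) that yields pairs of every class through
third degree; per-class pair counts are reported by the code rather than
fixed, since they follow from the configured shape.

For the autosomal/X θ ratio used to separate, e.g., mother-daughter from
sisters, the ratio moments are computed by the independence-product
formulas μ(a/x) = μ(a)·μ(1/x) and σ²(a/x) = μ(a²)·μ(1/x²) − μ(a/x)², which
equal the mean and variance over the full product grid of the two sample
sets (a property the tests assert to 1e-12). Samples with θx below 1e-3 are
excluded from the reciprocal moments (the formulas are undefined at zero)
and the exclusion count is reported.

## Relationship classification

A degree call (1st/2nd/3rd/unrelated) is the interval containing θ̂ in the
range table; overlapping intervals produce an explicit ambiguity set, a θ̂
above every interval is flagged "possible inbred/identical" (inbreeding is
deliberately not modelled — a 9-state Jacquard decomposition is not
identifiable at these SNP counts — so it surfaces as a flag), and a θ̂ in a
gap is assigned the nearest interval with an `out_of_range` flag.

Within a called degree, pedigree labels are screened by hard constraints —
sex configuration, mtDNA sharing where the label implies a maternal line
and sharing is estimable, θ_X inside the label's interval (the union of the
simulated interval and a ±0.12 band around the pedigree expectation, since
small calibration samples yield over-narrow quantiles and θ_X at the
800-SNP threshold carries sampling noise near 0.04), and the existence of a
parent/child orientation consistent with sexes and age classes. Survivors
are ranked by squared standardised distance of (θ_auto, θ_auto/θ_X) from
class expectations. Two pieces of soft evidence enter the ranking but never
exclude: observed mtDNA sharing mildly favours maternal-line labels
(sharing without a maternal path remains possible in a homogeneous
population, so it cannot disqualify), and a death-order probability ≥ 0.9
favours the orientation whose parent died first (a parent can outlive an
offspring, so the opposite ordering is penalised, not vetoed). mtDNA
"sharing" is operationalised as identical haplogroup labels or a mismatch
rate below a configurable ceiling, because consensus-sequence mismatches at
the observed scale are attributable to sequencing error.

Labels tied within 0.5 of the best score are reported together — same-sex
adult/child first-degree pairs, for instance, legitimately return both
parent-offspring and sibling labels.

## Population-genetic and burial statistics

Outgroup f3(O; A, B) is the per-SNP product (f_O − g_A)(f_O − g_B) averaged
over SNPs, with pseudo-haploid g ∈ {0, 1}; when the outgroup chromosome
count is supplied, the finite-sample correction f(1−f)/(n−1) — the unbiased
estimate of the sampling variance of f̂_O — is subtracted. 1 − f3 serves as
pairwise genetic distance. The D statistic is the standard ABBA-BABA ratio
Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz) with |Z| ≥ 3 flagged significant; when y
and z are identical the ratio is 0/0 and D is reported as 0 by symmetry.
Standard errors use a weighted block jackknife over contiguous physical
blocks (default 5 Mb — the cited analyses delegate this to external
software without printing a block size), with per-block SNP counts as
weights and the Busing-style weighted pseudovalue variance; a test checks
the SE against direct leave-one-block-out recomputation.

Resampling tests: the diversity contrast permutes group membership and
compares |Δ mean within-group distance| (10,000 permutations by default;
this design is conservative, which the log notes); the Mantel test
correlates upper-triangle spatial and genetic distances with one-sided p
from joint row/column permutations (default 9,999 plus the identity; exact
enumeration available and used as the n=4 oracle); the within-building test
compares mean within-building f3 similarity against random reassignment
preserving building sizes. All permutation p-values use the
(count + 1)/(n_perm + 1) convention and are seeded; calibration suites
verify uniform null p at the Kolmogorov–Smirnov α = 0.01 level.

Fisher exact tests on 2×2 tables report the conditional maximum-likelihood
odds ratio (maximising the noncentral hypergeometric likelihood given the
margins — the convention of the R implementation, and the one that
reproduces the published odds ratios) and the two-sided p by probability
ordering with a 1e-7 relative tie slack. Degenerate zero-margin tables
return p = 1 with an OR of 0, infinity, or 1 depending on the observed
cells. The co-burial statistic counts an individual as "with relative" when
at least one other member of its building cluster is called 1st–3rd-degree
related. Before spatial tests, one member of each close pair is removed
greedily in descending coverage order (ties by id), which leaves a maximal
set with no retained close pair.

## Radiocarbon

Replicate conventional ages are combined by inverse-variance weighted mean
after the Ward–Wilson χ² homogeneity test (T = Σ(x_i − x̄)²/σ_i² against
the 5% critical value at n − 1 df). Calibration is by the probability
method on a curve table in the standard IntCal layout (cal BP grid, curve
mean, curve σ): posterior mass per grid year proportional to the normal
density with variance σ_meas² + σ_curve², normalised on the grid. 95%
regions are assembled by descending-probability inclusion, merged into
contiguous runs, and rounded outward to 5 years. Internally all dates are
cal BP; reports convert via cal BCE = cal BP − 1949.

Death order between two individuals assumes independent calibrated
posteriors (no stratigraphic prior): P(A died first) sums pA·pB over grid
pairs where A's year is earlier, with ties at the grid resolution given
half weight — the symmetric choice, and the one that makes
P(A first) + P(B first) = 1 exactly.

## Synthetic cohorts

The generator produces every pipeline input with ground truth attached:
panel frequencies uniform on [maf_min, 1 − maf_min] (default floor 0.10),
pedigree genotypes as above, per-individual retention probabilities
emulating the coverage spread of ancient cohorts, pseudo-haploidization
with symmetric allele-flip error (default 0.005; an asymmetric damage-like
mode exists for stress tests), maternal-line mtDNA with founder divergence
1% and per-individual observation error, burial layouts in which connected
first-degree components anchor to buildings with a tunable clustering
strength, and radiocarbon measurements drawn around a supplied curve. The
default panel sizes, 5,000 autosomal and 800 X SNPs, are the minimum pair
overlaps at which estimates are reported — the regime the calibration is
about. Every generator is a pure function of (config, seed).

## Problem sizes in the shipped checks

The acceptance script regenerates everything at run time: 6 pedigree
replicates at the full 157,172-SNP panel for error-free parameter recovery,
2,000 X gametes for class means, 100 training and 500 test pairs at 5,000
SNPs for classification accuracy, 20 random 50-SNP toys for the EM/grid
comparison, 1,000 null replicates (399 permutations each) for the
permutation-calibration studies, and 2,000 replicate pairs for the
Ward–Wilson null. These sizes give Monte Carlo error comfortably inside
the assertion bands while keeping a full run around a minute.

## Known limitations

- No background LD in founders: LD-aware estimators cannot be benchmarked.
- No contamination, reference bias, or read-level error structure in the
  degradation model — error is a per-call symmetric flip.
- Cotterman decomposition unidentifiable from pseudo-haploid data (only θ);
  the package reports θ in that regime rather than pretending otherwise.
- No inbreeding coefficients; elevated θ̂ surfaces as a flag only.
- Independent-posterior death order ignores stratigraphic constraints.
- The classifier's soft-evidence weights (0.5 for mtDNA concordance, 0.75
  for death-order direction, 0.5 winner window) are heuristic ranking
  devices, not calibrated probabilities.
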