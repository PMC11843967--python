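# Methods

This note records the models, parameter choices, numerical details and
known limitations behind `cfmethyl`, in the spirit of a statistical
software methods appendix. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and the synthetic generator

The unit of data is the CpG count matrix: per site and sample, a
methylated count M and total count N from strand-merged bisulfite
calls. The generator emulates the structure the analysis assumes:

- **Genome.** Desk-scale chromosomes with CpG positions at geometric
  spacing (default mean 100 bp, the order of genome-wide CpG density).
  Region-recovery experiments use 30 bp spacing, the island-like
  density at which multi-CpG regions are actually callable — with a
  100 bp mean gap, consecutive CpGs are farther apart than the 100 bp
  DMR merge distance about 37% of the time, so a true region fragments
  below the 4-CpG minimum no matter how strong the signal. This is a
  property of the calling rules, not of the test.
- **Methylation landscape.** A latent mean is drawn per 1 kb window
  from a Beta distribution with mean `baseline_mean` (default 0.83, the
  global weighted mCG level typical of plasma cfDNA) and between-window
  sd 0.15, shared by all CpGs in the window and clipped to
  (0.01, 0.99). Within-window constancy is the simplest structure that
  gives smoothing something to exploit.
- **Counts.** Coverage is 1 + Poisson(mean − 1) so every site is
  observed (missingness is exercised separately by masking); methylated
  counts are beta-binomial with dispersion φ (default 0.05 — a
  moderate, plausible value for cfDNA, treated as a parameter to vary,
  not an estimate), parameterized by shape (μ(1−φ)/φ, (1−μ)(1−φ)/φ) so
  φ = 0 degenerates to binomial.
- **Planted regions** shift group 2's mean by δ inside declared
  intervals. At a 0.83 baseline only hypomethylating shifts of
  magnitude ~0.25 are expressible — a +0.25 shift saturates at the
  clip and the realized difference falls below the 0.1 calling
  threshold — so recovery experiments plant δ = −0.25.
- **Mixtures.** Marker methylation of a sample is R·p for tissue
  proportions p on the simplex, optionally binomially resampled at
  finite coverage and perturbed by truncated Gaussian noise.
- **External summaries.** Each shared site receives a direction equal
  to the internal one with a set concordance probability, plus an
  independent significance flag — enough to drive the concordance
  statistics with a known truth.

What the generator does *not* emulate: read-level bisulfite conversion
error, mapping bias, fragment-length structure, co-methylation decay
beyond the 1 kb window, or realistic chromosome-scale features (CpG
island methylation dips at TSSs, for instance — metagene profiles on
synthetic data are flat by construction). Passing recovery tests
therefore demonstrates correctness of the machinery under the stated
model, not performance on real plasma WGBS.

## Differential methylation test

Group means are smoothed by coverage-weighted pooling over a ±250 bp
window (500 bp total; window 0 reduces to the raw per-site pooled
fraction). The Wald variance applies the beta-binomial variance of a
pooled proportion,

    Var_g = mu(1-mu) * [(1-phi) * sum(N) + phi * sum(N^2)] / sum(N)^2,

to the *same window aggregation* that produced the smoothed mean. An
alternative — smoothed means over a strictly per-site variance — makes
the statistic conservative by roughly the number of pooled sites
(the smoothed difference has far less sampling noise than a single
site's), which would defeat the nominal-level behaviour the null
calibration test enforces; at window 0 the two formulations coincide.
Sites covered in only one group are excluded and logged; an exactly 0
or 1 smoothed mean triggers a 1e-8 variance floor.

Dispersion shrinkage: per site, φ̃ maximizes the beta-binomial
log-likelihood of all samples (group means fixed at their smoothed
values, clipped to [1e-4, 1−1e-4]) minus λ(log φ − m₀)²/(2s₀²), λ = 1.
The prior location m₀ and scale s₀ are the mean and sd of log
method-of-moments estimates over usable sites, where *usable* means the
moment estimate is positive: negative moment estimates (common at low
replication) carry no information about log φ, and clipping them to the
lower bound instead would drag m₀ about one log-unit below the truth
and make the test anti-conservative. s₀ is floored at 0.5 so the prior
never becomes dogmatic; log φ is searched in [−8, −0.02] by
golden-section to 1e-6, vectorized across sites. Sites with fewer than
two covered samples take exp(m₀) directly.

Calibration is the design criterion: on a 20,000-site null (5 vs 5,
10×, φ = 0.05) the raw p < 0.05 rate must sit in [0.03, 0.07] and FDR
control must return essentially nothing; both are asserted in the
suite and recomputed by the acceptance script.

## DMR calling

Sites with p < `p_threshold` (0.05) are chained while consecutive
significant sites are ≤ `merge_dist` (100 bp) apart; a candidate spans
[first, last + 1) and must satisfy length ≥ 50 bp, ≥ 4 CpGs counting
*all* tested CpGs in the bounds, ≥ 50% of them significant, and a
coverage-weighted |difference| > 0.1. The 4-CpG count deliberately
includes non-significant interior CpGs (the stricter
significant-CpGs-only reading is available by raising `pct_sig` to 1).
The region end is exclusive, so a single-CpG region has length 1.
`areaStat` is the sum of Wald statistics over member CpGs. Calls are
independent of chromosome processing order; an independent validator
in the tests re-derives all five filters for every call.

## Annotation and enrichment

Regions receive every feature class they overlap by ≥ 1 bp (the
multi-assignment convention of genome annotation tools); percentages
are shares of assignments, so a single-best normalization must be
derived by the user if wanted. Expected fractions are merged (never
double-counted) feature lengths over genome length. Conventions:
promoter = [TSS−1000, TSS) strand-aware, 1–5 kb upstream likewise,
shores within 2 kb of an island edge, shelves within (2, 4] kb,
distance ties resolved to the nearest island. The synthetic annotation
fixture builds each layer (gene-context and CGI-context) as an exact
partition of the genome under a construction precedence (gene-body
parts over promoter over 1–5 kb over intergenic, earlier-placed genes
first), which the tests assert.

## Concordance statistics

The two-sided Fisher p-value sums hypergeometric probabilities not
exceeding the observed table's, with a 1 + 1e-7 relative tie tolerance
(standard practice to stabilize floating-point ties); weights are
computed from log-gamma functions, and the suite checks every table
with n ≤ 40 against exact integer enumeration. The odds ratio is the
conditional MLE: the ψ solving E_ψ[a | margins] = a under the
noncentral hypergeometric distribution, found by bisection on log ψ
(the conditional mean is strictly increasing) to 1e-12; an observed
count at the support boundary yields the 0/∞ sentinel. When the margins
fix the table completely the conditional likelihood is flat in ψ and
the estimate is reported as 1 (the null value) with p = 1. For the
table (1, 1; 3, 2) the estimate is √½ ≈ 0.71 analytically — notably
not the cross-product ratio 0.67, which is why the conditional
convention is used.

## Deconvolution

The constrained least-squares problem is solved by a Lawson–Hanson
style active-set method: the equality-constrained subproblem on the
free tissues is solved through its KKT system, infeasible steps are
truncated at the first zero crossing and that coordinate pinned, and
pinned coordinates re-enter when their KKT multiplier is negative
(tolerance 1e-8). The solver is exact at the constraints, deterministic
and typically converges in a handful of iterations for 14 tissues.
Rank-deficient panels raise an error naming the collinearity; missing
marker values are dropped pairwise. Marker classification: Type I if
exactly one tissue's one-vs-rest gap reaches `tau1` (0.2) — requiring
uniqueness keeps gradually-spread markers out of the class — else
Type II if the across-tissue sd reaches `tau2` (0.1). Both classes are
pooled for estimation by default. Group comparison of estimated
proportions uses the two-sided Mann–Whitney U test (exact null for
combined n ≤ 20 without ties, normal approximation with tie correction
otherwise) — a documented choice of this package, with direction
reported as the sign of the group-mean difference.

## Metagene profiles

Scale-regions geometry: fixed-width flank bins (default 10 kb / 100
bins) and a body linearly rescaled to 100 bins, half-open bin edges
with boundary sites assigned rightward, minus-strand genes reversed so
bin 0 is 5′-most. Bin values are unweighted means of site fractions
(bedGraph semantics; a coverage-weighted mode is available via the
`weights` argument), per-gene profiles are averaged unweighted across
genes, and empty bins propagate as missing. Track averaging over
replicates is per-site and unweighted, using whichever tracks define a
site.

## Problem sizes and defaults

The test suite and acceptance script run the study conditions at desk
scale: 20,000-site nulls, 1 Mb dense genomes with 20 planted 1 kb
regions, 1,000-marker panels with 100 mixture replicates, 10,000-region
enrichment nulls. Stage defaults (500 bp smoothing window, λ = 1, DMR
thresholds p < 0.05 / Δ > 0.1 / 50 bp / 4 CpGs / merge 100 bp /
50% significant, τ₁ = 0.2, τ₂ = 0.1, ±10 kb metagene flanks) are the
package-wide defaults exposed in `PipelineConfig`, and the pipeline
records every parameter, seed and output hash in its manifest so reruns
are verifiably byte-identical.

## Known limitations

Two-group designs only (no covariates, no paired tests); p-values rely
on the normal approximation to the Wald statistic and degrade at very
low coverage; the DMR caller is rule-based, not model-based (no HMM
refinement); deconvolution reports point estimates without bootstrap
uncertainty; and the published 14-tissue reference values are not
bundled — the panel here is synthetic, so tissue labels in examples are
illustrative.
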