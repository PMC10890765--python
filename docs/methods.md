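# Methods

## The generative model

`meripower` treats a MeRIP-seq experiment as paired counts over candidate
regions. For region *i* and sample *j*, input counts X_ij and IP counts
Y_ij are Poisson draws whose rates are scaled by per-library size factors
(s^x_j, s^y_j) and mixed over gamma-distributed latent abundances sharing a
region scale θ_i:

    X_ij ~ Poisson(s^x_j λ^x_ij),  λ^x_ij ~ Gamma(shape α^x_ij, scale θ_i)
    Y_ij ~ Poisson(s^y_j λ^y_ij),  λ^y_ij ~ Gamma(shape α^y_ij, scale θ_i)

The gamma shapes encode the methylation level μ_ij and its biological
dispersion φ_i: α^y_ij = μ_ij(φ_i⁻¹ − 1), α^x_ij = (1 − μ_ij)(φ_i⁻¹ − 1).
Integrating the gamma layer gives negative-binomial marginals — for the
input, NB(size (1 − μ_ij)(φ_i⁻¹ − 1), prob s^x_j θ_i / (1 + s^x_j θ_i)) —
and the latent IP fraction λ^y/(λ^x + λ^y) is Beta(α^y, α^x), so
conditional on totals the IP counts are beta-binomial with the same (μ, φ).
The simulator exposes both the two-stage Gamma→Poisson path and the NB
marginal path; they are the same law and the test suite verifies their
agreement by two-sample KS tests and a chi-square goodness of fit against
the printed marginal.

Methylation depends on condition through a logit link,
logit(μ_ij) = α_i + z_j β_i with z_j ∈ {0, 1}. The logit link is used
uniformly (it keeps μ in (0,1) for any effect size and makes β_i a
log-odds ratio); a log-link variant was considered and rejected because it
cannot bound μ.

### Assumptions

- Two balanced conditions; one IP and one input library per sample pair.
- A common dispersion φ_i per region across samples and conditions.
- Region counts are independent across regions given their parameters.
- Effects enter only the methylation level, not expression (input means).

## Calibration from pilot data

Candidate regions are found by pooling bin counts across samples and
testing IP enrichment with an exact conditional binomial test: given
n = x + y pooled counts, y is referred to Binomial(n, p0) with
p0 = Σs^y / (Σs^x + Σs^y), one-sided. Per-bin p-values are BH-adjusted at
0.05 and significant bins are merged into maximal runs (default bin width
50 bp, no gap bridging; a `max_gap` option absorbs short interruptions).

On candidate regions the following are estimated:

- **Size factors** — library sums divided by the pooled median library sum
  across all 2N libraries. The construction makes factors invariant to
  globally rescaling counts and equivariant under sample relabeling.
- **Location and scale** — per region, (α_i, β_i, φ_i, θ_i) by joint
  maximum likelihood over the paired NB marginals (Nelder-Mead on
  (α, β, log θ, logit φ), moment starts, method-of-moments fallback
  flagged on failure).
- **A second dispersion route** — beta-binomial regression of rounded
  normalized IP counts on rounded normalized totals, ML over
  (α, β, logit φ). Counts are rounded to the nearest integer; regions with
  fewer than three usable samples return the moment estimate flagged, with
  φ at its lower clamp.
- **Dispersion arbitration** — for each route, data are simulated from the
  shared (α, β, θ) with that route's φ and a Laplace-smoothed KL divergence
  between real and simulated pooled count histograms is computed per
  region. A paired one-sided Wilcoxon test across regions (level 0.05)
  keeps the beta-binomial dispersions only if their KL is significantly
  lower; otherwise — including exact ties and the single-region case,
  which falls back to a direct KL comparison — the NB dispersions are
  kept. This NB-default reflects that the NB route is also the source of
  the location estimates.
- **θ rescaling** — after a first-round simulation, each θ_i is multiplied
  by the ratio of real to simulated mean total counts (pseudo-count 0.5 in
  the denominator), closing the loop so simulated library totals track the
  pilot. One rescaling round is the default.

Baseline and scale distributions can also be abstracted into samplers:
empirical (resampling the estimates) or parametric (normal by moments for
α; log-normal around a least-squares regression of log θ on log φ for θ).
Empirical is the default everywhere.

Numerical clamps: φ ∈ (1e−6, 1−1e−6), θ ∈ (1e−6, 1e6), μ ∈ (1e−6, 1−1e−6);
logit-scale parameters are capped at ±12 during caller fits.

## Planting effects and synthesizing designs

A simulated design plants exactly round(0.10·M) DMRs (proportion
configurable) chosen uniformly at random. A planted region keeps its pilot
effect estimate when |β̂| exceeds the median |β̂| of all regions, and
otherwise draws |β| ~ U(1, 2) with a random sign (the pilot estimate's sign
is kept when reused). Size factors for the proposed design reuse the pilot
factors in order when the target group size does not exceed the pilot pair
count and resample them with replacement otherwise; a depth factor
multiplies every factor to emulate deeper or shallower sequencing.

## The built-in DMR caller

Per region the caller fits the beta-binomial regression above with a
moderated dispersion: the region-wise excess-variance moment estimate is
shrunk toward the across-region median with a fixed prior weight
(`prior_df`, default 10 pseudo-observations), and H0: β_i = 0 is tested
with a Wald statistic referred to a t distribution with residual-plus-prior
degrees of freedom. The (α_i, β_i) fit is a damped Newton iteration on the
exact beta-binomial log-likelihood, vectorised across regions (digamma /
trigamma evaluations on whole matrices), so a 2000-region call takes tens
of milliseconds. Benjamini-Hochberg adjustment is applied across regions.

The moderation strength was fixed at 10 after measuring calibration on
self-generated data: without moderation the t(2n−2) reference is honest but
has essentially zero power at 2–3 replicates per group; with much stronger
moderation (≥ 50 prior df) the test loses FDR control under the global
null. At 10 prior df the empirical FDR stays at or below nominal + 3
Monte-Carlo SE at every sample size examined while small designs retain
usable power. With only two replicates per group the realized FDR can still
brush its nominal level from above when effects are present — a known
behaviour of moderated tests at minimal replication.

Any external caller can be plugged in through a four-argument command
contract (X TSV, Y TSV, sample sheet, output path; output columns
region_id, stat, pvalue); BH is applied by the package in both modes so
result schemas match exactly.

## Power assessment

Every replicate of a grid cell re-plants effects, re-synthesizes the
design, simulates counts and calls DMRs once; the calls are then summarised
at every nominal FDR, effect cutoff Δ and input-expression stratum without
re-simulation. Regions are non-DMR (β = 0), non-targeted (0 < |β| < Δ) or
targeted (|β| ≥ Δ); a region is discovered when q < nominal FDR. Metrics:
FDR = P0/P, precision = (P1+P2)/P, power = (P1+P2)/(R1+R2), targeted power
= P2/R2, FDC = P0/P2. A ratio with an empty denominator is undefined for
that replicate and excluded from the mean; the count of defined replicates
is reported next to every summary. Strata are quantile bins of per-region
mean normalized input counts (breaks 0/10/30/50/70/90/100%), computed
within each replicate with minimum-rank ties (a constant vector falls
entirely into stratum 1).

Per-replicate random streams derive from
SeedSequence(master, cell index, replicate index), so grids are
reproducible and embarrassingly parallel in principle; two runs with the
same configuration and seed write byte-identical tables.

## The synthetic pilot generator

Because no public pilot is bundled, a seeded generator emulates the
structure calibration assumes: α_i ~ Normal(−0.5, 0.8) on the logit scale
(unimodal baseline methylation centred below 0.5), φ_i ~ Beta(2, 18)
(dispersion mostly below 0.2 but with a tail — "substantial" biological
variability), θ_i ~ LogNormal(2.0, 0.7) (region totals of a few hundred to
a few thousand reads at the default five 50-bp bins per region), relative
library sizes uniform on (0.5, 1.5), and 10% DMRs with |β| ~ U(1, 2).
Within a region the gamma shape is split evenly across bins, so
region-aggregated counts follow the region's exact (μ, φ, θ) hierarchy
while individual bins are noisier — the truth table is exact at the unit
downstream estimation uses.

What the generator does **not** emulate: GC and positional coverage biases,
exon/isoform structure, correlated regions, expression (input-mean)
differences between conditions, and background non-enriched bins outside
candidate regions. Tests passing on this generator therefore demonstrate
the statistical machinery is self-consistent and correctly calibrated for
the assumed model, not that the model captures every artifact of a
particular laboratory protocol; with real pilot data, calibration quality
should be judged with `validate_against_pilot` (mean-total fold changes,
histogram KL, methylation-ratio KS per region).

## Problem sizes and defaults

Default pilot: 2000 candidate regions, 5 bins each, 3 sample pairs per
condition. Default grid: sample sizes {2, 3, 5, 7, 10}, nominal FDR
{0.05, 0.1, 0.15, 0.2}, Δ ∈ {1.5, 2, 4, 6, 8, 10}, depth factor 1, 100
replicates per cell. The bundled checks and the acceptance script use
20–30 replicates per cell and a subset of Δ values, sizes chosen so the
full pipeline (calibration plus grids) completes in minutes on one core;
replicate counts are configuration, not structure, and scale up without
code changes. Qualitative trends (power rising with sample size, nominal
FDR and depth; variability falling with replication) are evaluated at
grid cells where the targeted class is populated and power is interior —
at Δ = 1.5 and nominal FDR 0.10 — because boundary cells (no discoveries,
or a near-empty targeted class) carry no information about a trend.

## Known limitations

- The built-in caller is a moderated beta-binomial Wald test, not a
  re-implementation of any published empirical-Bayes caller; absolute power
  numbers at minimal replication are conservative relative to callers with
  stronger information sharing. Comparisons of grid *shapes* across
  callers should use the plugin interface.
- Only balanced two-group designs are modelled; no covariates, pairing, or
  more than two conditions.
- Dispersion is region-wise constant; sample-specific dispersion is out of
  scope.
- The BAM front-end assigns reads by 5′ position only; no junction or
  isoform awareness.
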