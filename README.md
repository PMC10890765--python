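# meripower

Simulation-based statistical power evaluation for differential RNA
methylation (m⁶A) studies using MeRIP-seq.

MeRIP-seq quantifies transcriptome-wide N6-methyladenosine by sequencing a
methylation-enriched immunoprecipitated (IP) library alongside an input
(background expression) library for every sample. Detecting differentially
methylated regions (DMRs) between two conditions hinges on study-design
choices — how many replicates per group, how deeply to sequence, which
effect sizes matter — but closed-form power formulas do not exist for the
paired overdispersed counts this assay produces. `meripower` answers design
questions by simulation: it learns the statistical characteristics of pilot
data, synthesizes realistic datasets under candidate designs, calls DMRs,
and reports power and error rates against the planted truth.

## Model

For candidate region *i* and sample *j*, input and IP counts follow a
hierarchical Gamma-Poisson model:

    X_ij ~ Poisson(s^x_j λ^x_ij),   λ^x_ij ~ Gamma(α^x_ij, θ_i)
    Y_ij ~ Poisson(s^y_j λ^y_ij),   λ^y_ij ~ Gamma(α^y_ij, θ_i)

with gamma shapes tied to the methylation level μ_ij and dispersion φ_i by
α^y_ij = μ_ij(φ_i⁻¹ − 1) and α^x_ij = (1 − μ_ij)(φ_i⁻¹ − 1), and
logit(μ_ij) = α_i + z_j β_i for a two-group indicator z_j. Marginally the
counts are negative binomial, e.g.
X_ij ~ NB((1 − μ_ij)(φ_i⁻¹ − 1), s^x_j θ_i / (1 + s^x_j θ_i)), and the
latent methylation fraction is Beta(α^y, α^x). β_i is the condition effect
as a log-odds ratio; 10% of regions are planted as true DMRs by default.

Calibration estimates every generative quantity from pilot candidate-region
counts: median-of-library-sums size factors, per-region (α_i, β_i, φ_i, θ_i)
from the joint negative-binomial likelihood, a second dispersion estimate
from beta-binomial regression on normalized counts, a KL-divergence
arbitration between the two dispersion sets, and a fold-change rescaling of
θ_i against first-round simulated counts.

Designs are scored with five metrics derived from a three-way confusion
table (non-DMR / non-targeted DMR / targeted DMR with |β| ≥ Δ): FDR,
precision, power, targeted power, and false discovery cost (expected false
positives per detected targeted DMR), averaged over simulation replicates,
overall and within six input-expression strata.

## Worked example

```python
import numpy as np
from meripower import PilotSpec, generate_pilot, AssessmentConfig, run_power_grid
from meripower.estimation import estimate_region_params

pilot = generate_pilot(PilotSpec(n_regions=400, n_per_group=3, seed=5))
params, sf = estimate_region_params(pilot.to_region_counts(),
                                    rng=np.random.default_rng(0), nsim_kl=2)
cfg = AssessmentConfig(sample_size=(2, 3, 5), nominal_fdr=(0.05, 0.1),
                       delta=(1.5,), nsim=10)
res = run_power_grid(params, sf, cfg, seed=7)
```

Running `python examples/05_power_grid.py` (the script around this snippet)
prints:

```
mean power over 10 replicates (overall, delta = 1.5):
  nominal FDR 0.05: n=2: 0.01, n=3: 0.11, n=5: 0.42
  nominal FDR 0.1: n=2: 0.06, n=3: 0.24, n=5: 0.52
```

Each number is the fraction of truly differential regions detected at that
q-value threshold, averaged over 10 simulated experiments: moving from 2 to
5 replicates per group raises power from ~0 to ~0.4–0.5 on this pilot, and
a looser nominal FDR buys power at the cost of more false discoveries. The
full table also carries targeted power, FDC, precision and per-stratum
values, and exports to TSV/xlsx with optional line plots.

The `examples/` directory walks through every stage (pilot generation,
region discovery, calibration, simulation + calling, grids, precomputed
`quick_power` tables); the `meripower` CLI exposes the same stages as
subcommands (`simulate-pilot`, `discover`, `estimate`, `simulate`, `call`,
`assess`, `quickpower`, `report`).

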