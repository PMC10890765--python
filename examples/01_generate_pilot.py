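"""Generate a synthetic MeRIP-seq pilot dataset and inspect its structure.

The generator draws paired IP/input bin counts from a hierarchical
Gamma-Poisson model: each candidate region has a baseline methylation level
(logit scale), a methylation dispersion phi in (0,1), a count scale theta,
and 10% of regions carry a condition effect (log-odds ratio in [1, 2]).
"""

import numpy as np

from meripower import PilotSpec, generate_pilot

spec = PilotSpec(n_regions=500, n_bins_per_region=5, n_per_group=3, seed=1)
pilot = generate_pilot(spec)

rc = pilot.to_region_counts()
print(f"regions: {pilot.n_regions}, bins: {len(pilot.bins)}, "
      f"samples: {len(pilot.samples)} (pairs of IP+input libraries)")
print(f"true DMRs planted: {int(pilot.truth['is_dmr'].sum())} "
      f"({100 * pilot.truth['is_dmr'].mean():.0f}% of regions)")
print(f"mean region total (IP+input) count: {(rc.X + rc.Y).mean():.0f}")
ratio = rc.Y.sum() / (rc.X.sum() + rc.Y.sum())
print(f"overall IP fraction of counts: {ratio:.2f} "
      "(reflects the baseline methylation distribution)")
print(f"median true dispersion phi: {np.median(pilot.truth['phi']):.3f} "
      "(biological variability of methylation between replicates)")
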