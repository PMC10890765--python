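"""Consult a precomputed power grid without running any simulation.

The packaged scenarios were computed at build time from fully synthetic
pilots, with their generating recipes (specs and seeds) embedded so each
table can be regenerated bit-for-bit.
"""

from meripower import quick_power
from meripower.quickpower import available_scenarios

print("packaged scenarios:", available_scenarios())
res = quick_power("synthetic_small")
print(f"loaded {len(res.table)} summary rows; "
      f"grid seed {res.metadata['seed']}, "
      f"pilot seed {res.metadata['recipe']['pilot_spec']['seed']}")

sub = res.select(stratum="all", metric="power", nominal_fdr=0.05, delta=1.5)
for _, row in sub.sort_values("sample_size").iterrows():
    print(f"  n = {int(row['sample_size'])}/group: "
          f"mean power {row['mean']:.2f} (sd {row['sd']:.2f}, "
          f"{int(row['n_defined'])} replicates)")
print("values are means over the scenario's simulation replicates;")
print("regenerate with scripts/make_quickpower_fixture.py to verify.")
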