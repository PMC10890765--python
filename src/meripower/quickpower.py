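"""Precomputed power grids for instant consultation.

``quick_power`` serves power-evaluation tables computed at package build
time from fully synthetic pilot datasets, for users who want design
guidance without running simulations themselves. Each scenario ships with
provenance metadata (generator spec, seeds, grid settings) sufficient to
regenerate the table bit-for-bit with
``scripts/make_quickpower_fixture.py``.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from meripower.containers import PowerGridResult, ValidationError

_DATA_PACKAGE = "meripower.data.quickpower"

#: recipes for the packaged scenarios; every entry is fully seeded so the
#: shipped tables can be regenerated bit-for-bit
SCENARIO_RECIPES: dict[str, dict] = {
    "synthetic_small": {
        "pilot_spec": {
            "n_regions": 150, "n_bins_per_region": 2, "n_per_group": 3,
            "seed": 20240601,
        },
        "estimation_seed": 7,
        "grid_seed": 11,
        "assessment": {
            "sample_size": [2, 3, 5],
            "nominal_fdr": [0.05, 0.1],
            "delta": [1.5, 2.0],
            "depth_factor": [1.0],
            "nsim": 4,
        },
    },
}


def build_scenario(name: str) -> PowerGridResult:
    """Recompute a packaged scenario from its recorded recipe and seeds."""
    import numpy as np

    from meripower.assess import AssessmentConfig, run_power_grid
    from meripower.estimation import estimate_region_params
    from meripower.synthetic_pilot import PilotSpec, generate_pilot

    if name not in SCENARIO_RECIPES:
        raise ValidationError(
            f"unknown scenario {name!r}; recipes exist for {sorted(SCENARIO_RECIPES)}"
        )
    recipe = SCENARIO_RECIPES[name]
    pilot = generate_pilot(PilotSpec(**recipe["pilot_spec"]))
    params, sf = estimate_region_params(
        pilot.to_region_counts(),
        rng=np.random.default_rng(recipe["estimation_seed"]),
        nsim_kl=2,
    )
    cfg = AssessmentConfig(
        **{k: tuple(v) if isinstance(v, list) else v
           for k, v in recipe["assessment"].items()}
    )
    result = run_power_grid(params, sf, cfg, seed=recipe["grid_seed"])
    result.metadata["scenario"] = name
    result.metadata["recipe"] = recipe
    return result


def available_scenarios() -> list[str]:
    """Names of the packaged precomputed scenarios."""
    root = resources.files(_DATA_PACKAGE)
    return sorted(
        p.name[: -len(".tsv")] for p in root.iterdir() if p.name.endswith(".tsv")
    )


def quick_power(scenario: str = "synthetic_small") -> PowerGridResult:
    """Load a packaged precomputed PowerGridResult (no simulation)."""
    root = resources.files(_DATA_PACKAGE)
    tsv = root / f"{scenario}.tsv"
    if not tsv.is_file():
        raise ValidationError(
            f"unknown scenario {scenario!r}; available: {available_scenarios()}"
        )
    with resources.as_file(tsv) as path:
        table = pd.read_csv(path, sep="\t")
    meta = root / f"{scenario}.meta.json"
    metadata = json.loads(meta.read_text()) if meta.is_file() else {}
    return PowerGridResult(table=table, metadata=metadata)
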