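"""Power assessment: confusion counts, the five metrics, and design grids.

Each simulated region is one of three truth classes — non-DMR (beta = 0),
non-targeted DMR (0 < |beta| < delta) or targeted DMR (|beta| >= delta) —
and is either discovered (q < nominal FDR) or not. From the resulting
confusion counts the five metrics are

    FDR            = P0 / P
    precision      = (P1 + P2) / P
    power          = (P1 + P2) / (R1 + R2)
    targeted power = P2 / R2
    FDC            = P0 / P2   (false positives per targeted true positive)

Ratios with an empty denominator are undefined for that replicate and are
excluded from grid averages; the count of defined replicates is reported
alongside each mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from meripower.containers import (
    ConfusionSummary,
    DMRCallResult,
    PowerGridResult,
    PowerMetrics,
    RegionParams,
    SizeFactors,
    ValidationError,
    METRIC_NAMES,
)
from meripower.simulate import SimulationConfig, assign_effects, simulate_counts, synthesize_design
from meripower.caller import call_dmrs

DEFAULT_BREAKS = (0.0, 10.0, 30.0, 50.0, 70.0, 90.0, 100.0)


@dataclass
class AssessmentConfig:
    """Design grid and replication settings for a power sweep."""

    sample_size: tuple = (2, 3, 5, 7, 10)
    nominal_fdr: tuple = (0.05, 0.10, 0.15, 0.20)
    delta: tuple = (1.5, 2.0, 4.0, 6.0, 8.0, 10.0)
    depth_factor: tuple = (1.0,)
    nsim: int = 100
    strata_breaks: tuple = DEFAULT_BREAKS
    dmr_prop: float = 0.10
    effect_floor: float = 1.0
    effect_ceiling: float = 2.0
    quantile_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.nsim < 1:
            raise ValidationError("nsim must be >= 1")
        if any(d <= 0 for d in self.delta):
            raise ValidationError("delta cutoffs must be > 0")
        b = list(self.strata_breaks)
        if b[0] != 0 or b[-1] != 100 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValidationError("strata breaks must increase strictly from 0 to 100")

    @property
    def n_strata(self) -> int:
        return len(self.strata_breaks) - 1


def classify_regions(
    truth_beta: np.ndarray,
    qvalues: np.ndarray,
    delta: float,
    nominal_fdr: float,
    subset: np.ndarray | None = None,
) -> ConfusionSummary:
    """Confusion counts at effect cutoff delta and discovery threshold nominal_fdr.

    ``subset`` optionally restricts counting to a boolean mask of regions
    (used for stratified summaries).
    """
    beta = np.asarray(truth_beta, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    if beta.shape != q.shape:
        raise ValidationError("truth and calls must cover the same regions")
    if subset is None:
        subset = np.ones(beta.shape, dtype=bool)
    called = (q < nominal_fdr) & subset
    not_called = ~(q < nominal_fdr) & subset
    cls0 = beta == 0
    cls2 = np.abs(beta) >= delta
    cls1 = ~cls0 & ~cls2
    return ConfusionSummary(
        n0=int((cls0 & not_called).sum()), p0=int((cls0 & called).sum()),
        n1=int((cls1 & not_called).sum()), p1=int((cls1 & called).sum()),
        n2=int((cls2 & not_called).sum()), p2=int((cls2 & called).sum()),
    )


def compute_metrics(cm: ConfusionSummary) -> PowerMetrics:
    """The five metrics; any ratio with empty denominator is NaN (undefined)."""

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return PowerMetrics(
        fdr=_ratio(cm.p0, cm.p),
        precision=_ratio(cm.p1 + cm.p2, cm.p),
        power=_ratio(cm.p1 + cm.p2, cm.r1 + cm.r2),
        targeted_power=_ratio(cm.p2, cm.r2),
        fdc=_ratio(cm.p0, cm.p2),
    )


def stratify_by_input(
    mean_input: np.ndarray, breaks: tuple = DEFAULT_BREAKS
) -> np.ndarray:
    """Assign each region to a quantile stratum of mean input counts.

    Percentile rank uses minimum ranks (ties share the lowest rank, so a
    constant vector lands entirely in stratum 1); intervals are left-open,
    right-closed, with the lowest interval closed at 0. Returns 1-based
    stratum labels.
    """
    mean_input = np.asarray(mean_input, dtype=float)
    m = mean_input.size
    if m == 0:
        raise ValidationError("need at least one region to stratify")
    pct = 100.0 * rankdata(mean_input, method="min") / m
    internal = np.asarray(breaks[1:-1], dtype=float)
    return np.searchsorted(internal, pct, side="left") + 1


def _summarise(values: list[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        return float("nan"), float("nan"), 0
    sd = float(defined.std(ddof=1)) if defined.size > 1 else float("nan")
    return float(defined.mean()), sd, int(defined.size)


def run_power_grid(
    params: RegionParams,
    pilot_sf: SizeFactors,
    cfg: AssessmentConfig,
    seed: int = 0,
    caller=None,
) -> PowerGridResult:
    """Sweep the design grid with nsim replicates per (sample size, depth) cell.

    Every replicate re-plants effects, re-synthesizes the design, simulates
    counts, calls DMRs once, and is then summarised at every nominal FDR,
    delta cutoff and input stratum. Per-replicate random streams derive
    deterministically from (seed, cell index, replicate index). ``caller``
    is any callable with the built-in caller's signature returning a
    :class:`DMRCallResult`; the default is the built-in beta-binomial Wald
    test.
    """
    import inspect

    if caller is None:
        caller = call_dmrs
    caller_params = inspect.signature(caller).parameters
    pass_truth = "truth" in caller_params
    records: dict[tuple, list[float]] = {}
    failures: dict[tuple, int] = {}
    cells = [(n, d) for n in cfg.sample_size for d in cfg.depth_factor]

    for cell_idx, (n, depth) in enumerate(cells):
        failures[(n, depth)] = 0
        for rep in range(cfg.nsim):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), cell_idx, rep])
            )
            sim_cfg = SimulationConfig(
                n_per_group=int(n),
                depth_factor=float(depth),
                dmr_prop=cfg.dmr_prop,
                effect_floor=cfg.effect_floor,
                effect_ceiling=cfg.effect_ceiling,
                quantile_cut=cfg.quantile_cut,
            )
            planted = assign_effects(params, sim_cfg, rng)
            sf, samples = synthesize_design(pilot_sf, sim_cfg, rng)
            sim = simulate_counts(planted, sf, samples, rng)
            try:
                kwargs = {"region_ids": planted.region_ids}
                if pass_truth:
                    kwargs["truth"] = sim.truth
                res = caller(sim.X, sim.Y, sf, samples, **kwargs)
            except Exception:
                failures[(n, depth)] += 1
                continue
            q = res.qvalue
            beta = planted.beta
            mean_input = (sim.X / sf.sx[None, :]).mean(axis=1)
            strata = stratify_by_input(mean_input, cfg.strata_breaks)

            for fdr_level in cfg.nominal_fdr:
                for delta in cfg.delta:
                    layers = [("all", None)] + [
                        (f"stratum{k}", strata == k)
                        for k in range(1, cfg.n_strata + 1)
                    ]
                    for label, mask in layers:
                        cm = classify_regions(beta, q, delta, fdr_level, subset=mask)
                        pm = compute_metrics(cm)
                        for metric, value in pm.as_dict().items():
                            key = (int(n), float(depth), float(fdr_level),
                                   float(delta), label, metric)
                            records.setdefault(key, []).append(value)

    rows = []
    for key, values in records.items():
        mean, sd, n_def = _summarise(values)
        n, depth, fdr_level, delta, label, metric = key
        rows.append(
            {
                "sample_size": n, "depth_factor": depth, "nominal_fdr": fdr_level,
                "delta": delta, "stratum": label, "metric": metric,
                "mean": mean, "sd": sd, "n_defined": n_def, "nsim": cfg.nsim,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["sample_size", "depth_factor", "nominal_fdr", "delta", "stratum", "metric"]
    ).reset_index(drop=True)
    meta = {
        "seed": int(seed),
        "failures": {f"{n}x{d}": c for (n, d), c in failures.items()},
        "config": {
            "sample_size": list(cfg.sample_size),
            "nominal_fdr": list(cfg.nominal_fdr),
            "delta": list(cfg.delta),
            "depth_factor": list(cfg.depth_factor),
            "nsim": cfg.nsim,
            "strata_breaks": list(cfg.strata_breaks),
            "dmr_prop": cfg.dmr_prop,
            "effect_floor": cfg.effect_floor,
            "effect_ceiling": cfg.effect_ceiling,
            "quantile_cut": cfg.quantile_cut,
        },
    }
    return PowerGridResult(table=table, metadata=meta)
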