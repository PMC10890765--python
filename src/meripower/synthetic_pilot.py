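"""Seeded generator of pilot-like MeRIP-seq datasets.

Emulates the statistical structure a real pilot provides: paired IP/input
negative-binomial bin counts with region-specific baseline methylation on
the logit scale, beta-distributed methylation dispersion, log-normal count
scale, library-size heterogeneity, and a minority of regions carrying
condition effects. Every drawn parameter is recorded in a truth table so
downstream estimation can be scored against it.

Bins within a region split the region's gamma shape evenly, so aggregated
region counts follow the region's (mu, phi, theta) hierarchy exactly while
individual bins are noisier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from meripower.containers import (
    RegionCounts,
    RegionParams,
    SizeFactors,
    ValidationError,
)
from meripower.simulate import simulate_counts

BIN_WIDTH = 50
REGION_GAP = 100


@dataclass
class PilotSpec:
    """Generative settings for one synthetic pilot.

    n_per_group counts pilot sample *pairs* per condition (two conditions).
    baseline_logit_mean/sd parameterise the normal distribution of region
    baseline methylation on the logit scale; dispersion_a/b the Beta
    distribution of methylation dispersion phi in (0,1); theta_log_mean/sd
    the log-normal count-scale parameter. Library sizes (relative) are
    uniform on library_size_range. Effects are uniform magnitudes on
    effect_range (log-odds) with random sign, planted in a dmr_prop
    fraction of regions.
    """

    n_regions: int = 2000
    n_bins_per_region: int = 5
    n_per_group: int = 3
    baseline_logit_mean: float = -0.5
    baseline_logit_sd: float = 0.8
    dispersion_a: float = 2.0
    dispersion_b: float = 18.0
    theta_log_mean: float = 2.0
    theta_log_sd: float = 0.7
    library_size_range: tuple[float, float] = (0.5, 1.5)
    dmr_prop: float = 0.10
    effect_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_bins_per_region", "n_per_group"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for name in ("baseline_logit_sd", "dispersion_a", "dispersion_b", "theta_log_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValidationError("library_size_range must be positive with low <= high")
        if not 0.0 <= self.dmr_prop <= 1.0:
            raise ValidationError("dmr_prop must lie in [0, 1]")
        lo, hi = self.effect_range
        if lo > hi:
            raise ValidationError("effect_range low must be <= high")


@dataclass
class PilotDataset:
    """Bin-level pilot counts plus the parameters that generated them."""

    bins: pd.DataFrame  # chrom, start, end, strand, bin_id, region_id
    regions: pd.DataFrame  # chrom, start, end, strand, region_id
    X: np.ndarray
    Y: np.ndarray
    samples: pd.DataFrame
    truth: pd.DataFrame  # region_id, alpha, beta, phi, theta, is_dmr
    size_factors: SizeFactors

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_region_counts(self) -> RegionCounts:
        """Aggregate bin counts to their region of origin (column sums)."""
        codes = self.bins["region_id"].to_numpy()
        order = self.regions["region_id"].to_numpy()
        idx = {rid: k for k, rid in enumerate(order)}
        rows = np.array([idx[c] for c in codes], dtype=int)
        m = len(order)
        X = np.zeros((m, self.X.shape[1]), dtype=np.int64)
        Y = np.zeros_like(X)
        np.add.at(X, rows, self.X)
        np.add.at(Y, rows, self.Y)
        return RegionCounts(regions=self.regions.copy(), X=X, Y=Y, samples=self.samples.copy())


def _coordinates(n_regions: int, n_bins: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    width = n_bins * BIN_WIDTH
    starts = np.arange(n_regions) * (width + REGION_GAP)
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + width,
            "strand": "+",
            "region_id": [f"region_{i + 1}" for i in range(n_regions)],
        }
    )
    bin_start = (starts[:, None] + np.arange(n_bins)[None, :] * BIN_WIDTH).ravel()
    rid = np.repeat(regions["region_id"].to_numpy(), n_bins)
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": bin_start,
            "end": bin_start + BIN_WIDTH,
            "strand": "+",
            "bin_id": [f"bin_{i + 1}" for i in range(n_regions * n_bins)],
            "region_id": rid,
        }
    )
    return bins, regions


def generate_pilot(spec: PilotSpec) -> PilotDataset:
    """Draw a complete pilot dataset from the Gamma-Poisson hierarchy."""
    rng = np.random.default_rng(spec.seed)
    m, nb = spec.n_regions, spec.n_bins_per_region
    n = 2 * spec.n_per_group

    alpha = rng.normal(spec.baseline_logit_mean, spec.baseline_logit_sd, size=m)
    phi = np.clip(rng.beta(spec.dispersion_a, spec.dispersion_b, size=m), 1e-6, 1 - 1e-6)
    theta = np.clip(rng.lognormal(spec.theta_log_mean, spec.theta_log_sd, size=m), 1e-6, 1e6)

    n_dmr = int(round(spec.dmr_prop * m))
    is_dmr = np.zeros(m, dtype=bool)
    if n_dmr:
        is_dmr[rng.choice(m, size=n_dmr, replace=False)] = True
    beta = np.zeros(m)
    if n_dmr:
        mag = rng.uniform(spec.effect_range[0], spec.effect_range[1], size=n_dmr)
        beta[is_dmr] = mag * rng.choice([-1.0, 1.0], size=n_dmr)

    lo, hi = spec.library_size_range
    lib_x = rng.uniform(lo, hi, size=n)
    lib_y = rng.uniform(lo, hi, size=n)
    med = np.median(np.concatenate([lib_x, lib_y]))
    names = [f"A{j + 1}" for j in range(spec.n_per_group)] + [
        f"B{j + 1}" for j in range(spec.n_per_group)
    ]
    samples = pd.DataFrame(
        {
            "sample": names,
            "condition": ["A"] * spec.n_per_group + ["B"] * spec.n_per_group,
            "pair": list(range(1, spec.n_per_group + 1)) * 2,
        }
    )
    sf = SizeFactors(lib_x / med, lib_y / med, names)

    # bins share the region's (alpha, beta, theta); the gamma shape is split
    # evenly so region-aggregated counts keep the region's phi exactly
    gamma_tot_bin = (1.0 / phi - 1.0) / nb
    phi_bin = np.clip(1.0 / (gamma_tot_bin + 1.0), 1e-6, 1 - 1e-6)

    bins, regions = _coordinates(m, nb)
    bin_params = RegionParams(
        pd.DataFrame(
            {
                "region_id": bins["bin_id"].to_numpy(),
                "alpha": np.repeat(alpha, nb),
                "beta": np.repeat(beta, nb),
                "phi": np.repeat(phi_bin, nb),
                "theta": np.repeat(theta, nb),
                "is_dmr": np.repeat(is_dmr, nb),
            }
        )
    )
    sim = simulate_counts(bin_params, sf, samples, rng, mode="gamma_poisson")

    truth = pd.DataFrame(
        {
            "region_id": regions["region_id"].to_numpy(),
            "alpha": alpha,
            "beta": beta,
            "phi": phi,
            "theta": theta,
            "is_dmr": is_dmr,
        }
    )
    return PilotDataset(
        bins=bins,
        regions=regions,
        X=sim.X,
        Y=sim.Y,
        samples=samples,
        truth=truth,
        size_factors=sf,
    )


def write_pilot(dataset: PilotDataset, directory: str | os.PathLike) -> dict[str, str]:
    """Write a pilot dataset as plain-text files; returns the path map.

    Layout: regions.bed and bins.bed (BED6, bins carry their region of
    origin in a 7th column), X.tsv / Y.tsv count matrices (rows = bins,
    header = sample ids), samples.tsv, truth.tsv, size_factors.tsv.
    """
    from meripower import io as mio

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "regions_bed": os.path.join(directory, "regions.bed"),
        "bins_bed": os.path.join(directory, "bins.bed"),
        "x_tsv": os.path.join(directory, "X.tsv"),
        "y_tsv": os.path.join(directory, "Y.tsv"),
        "samples_tsv": os.path.join(directory, "samples.tsv"),
        "truth_tsv": os.path.join(directory, "truth.tsv"),
        "size_factors_tsv": os.path.join(directory, "size_factors.tsv"),
    }
    mio.write_bed(dataset.regions, paths["regions_bed"], name_col="region_id")
    mio.write_bed(dataset.bins, paths["bins_bed"], name_col="bin_id", extra_cols=["region_id"])
    ids = dataset.bins["bin_id"]
    mio.write_count_matrix(dataset.X, ids, dataset.samples["sample"], paths["x_tsv"])
    mio.write_count_matrix(dataset.Y, ids, dataset.samples["sample"], paths["y_tsv"])
    dataset.samples.to_csv(paths["samples_tsv"], sep="\t", index=False)
    truth = dataset.truth.copy()
    truth["is_dmr"] = truth["is_dmr"].astype(int)
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    pd.DataFrame(
        {
            "sample": dataset.size_factors.samples,
            "sx": dataset.size_factors.sx,
            "sy": dataset.size_factors.sy,
        }
    ).to_csv(paths["size_factors_tsv"], sep="\t", index=False)
    return paths


def read_pilot(directory: str | os.PathLike) -> PilotDataset:
    """Read back a dataset written by :func:`write_pilot` (lossless)."""
    from meripower import io as mio

    directory = str(directory)
    regions = mio.read_bed(os.path.join(directory, "regions.bed"), name_col="region_id")
    bins = mio.read_bed(
        os.path.join(directory, "bins.bed"), name_col="bin_id", extra_cols=["region_id"]
    )
    ids_x, samples_x, X = mio.read_count_matrix(os.path.join(directory, "X.tsv"))
    ids_y, samples_y, Y = mio.read_count_matrix(os.path.join(directory, "Y.tsv"))
    if list(ids_x) != list(ids_y) or list(samples_x) != list(samples_y):
        raise ValidationError("X.tsv and Y.tsv disagree on rows or samples")
    samples = pd.read_csv(os.path.join(directory, "samples.tsv"), sep="\t")
    truth = pd.read_csv(
        os.path.join(directory, "truth.tsv"),
        sep="\t",
        dtype={"region_id": str},
    )
    if len(truth):
        truth["is_dmr"] = truth["is_dmr"].astype(bool)
    else:
        truth["is_dmr"] = truth.get("is_dmr", pd.Series(dtype=bool)).astype(bool)
    sf_tab = pd.read_csv(os.path.join(directory, "size_factors.tsv"), sep="\t")
    sf = SizeFactors(
        sf_tab["sx"].to_numpy(), sf_tab["sy"].to_numpy(), sf_tab["sample"].astype(str).tolist()
    )
    return PilotDataset(
        bins=bins, regions=regions, X=X, Y=Y, samples=samples, truth=truth, size_factors=sf
    )
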