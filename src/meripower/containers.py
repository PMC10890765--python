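"""Core data containers shared across the pipeline.

Count matrices are plain integer numpy arrays with rows = genomic features
(bins or candidate regions) and columns = sample pairs; feature coordinates
and sample metadata travel alongside in small pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for sample sheets
SAMPLE_COLUMNS = ("sample", "condition", "pair")
#: canonical column order for feature (bin/region) coordinate tables
COORD_COLUMNS = ("chrom", "start", "end", "strand")

GRID_KEYS = ("sample_size", "depth_factor", "nominal_fdr", "delta", "stratum", "metric")
METRIC_NAMES = ("fdr", "precision", "power", "targeted_power", "fdc")


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


def _check_counts(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValidationError(f"{name} must contain integer counts")
    if (arr < 0).any():
        raise ValidationError(f"{name} contains negative counts")
    return arr.astype(np.int64, copy=False)


def check_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    if samples["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample sheet")
    return samples.reset_index(drop=True)


def group_indicator(samples: pd.DataFrame) -> np.ndarray:
    """Two-group 0/1 indicator from the sample sheet's condition labels.

    Conditions are ordered by first appearance; exactly two are required.
    """
    conds = samples["condition"].astype(str)
    levels = list(dict.fromkeys(conds))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 conditions, found {levels}")
    return (conds == levels[1]).to_numpy().astype(np.int64)


@dataclass
class BinCounts:
    """Paired IP (Y) and input (X) counts over genomic bins."""

    bins: pd.DataFrame
    X: np.ndarray
    Y: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = _check_counts("X", self.X)
        self.Y = _check_counts("Y", self.Y)
        if self.X.shape != self.Y.shape:
            raise ValidationError("X and Y must share shape")
        self.samples = check_sample_sheet(self.samples)
        if self.X.shape[1] != len(self.samples):
            raise ValidationError("count columns do not match sample sheet rows")
        missing = [c for c in COORD_COLUMNS if c not in self.bins.columns]
        if missing:
            raise ValidationError(f"bin table missing columns {missing}")
        if len(self.bins) != self.X.shape[0]:
            raise ValidationError("bin table rows do not match count rows")
        if len(self.bins) and not (self.bins["start"] < self.bins["end"]).all():
            raise ValidationError("bin starts must be < ends")
        self.bins = self.bins.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass
class RegionCounts:
    """Aggregated paired counts over candidate regions (one row per region)."""

    regions: pd.DataFrame  # region_id + coordinates
    X: np.ndarray
    Y: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = _check_counts("X", self.X)
        self.Y = _check_counts("Y", self.Y)
        if self.X.shape != self.Y.shape:
            raise ValidationError("X and Y must share shape")
        self.samples = check_sample_sheet(self.samples)
        if "region_id" not in self.regions.columns:
            raise ValidationError("region table requires a region_id column")
        if len(self.regions) != self.X.shape[0]:
            raise ValidationError("region table rows do not match count rows")
        self.regions = self.regions.reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]

    @property
    def region_ids(self) -> pd.Series:
        return self.regions["region_id"]


@dataclass
class SizeFactors:
    """Per-sample-pair normalisation constants for input (sx) and IP (sy)."""

    sx: np.ndarray
    sy: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sx = np.asarray(self.sx, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        if self.sx.shape != self.sy.shape or self.sx.ndim != 1:
            raise ValidationError("sx and sy must be 1-D arrays of equal length")
        if (self.sx <= 0).any() or (self.sy <= 0).any():
            raise ValidationError("size factors must be strictly positive")
        if not self.samples:
            self.samples = [f"pair{j + 1}" for j in range(len(self.sx))]

    def __len__(self) -> int:
        return len(self.sx)


@dataclass
class RegionParams:
    """Per-region generative parameters of the Gamma-Poisson hierarchy.

    Required columns: region_id, alpha (baseline logit methylation), beta
    (condition effect, log-odds ratio), phi (methylation dispersion in (0,1)),
    theta (gamma scale > 0), is_dmr. ``mu0 = expit(alpha)`` is derived.
    Optional columns carry the per-route dispersion estimates (phi_nb, phi_bb),
    the arbitration outcome (dispersion_source) and convergence flags.
    """

    table: pd.DataFrame

    REQUIRED = ("region_id", "alpha", "beta", "phi", "theta", "is_dmr")

    def __post_init__(self) -> None:
        from scipy.special import expit

        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"RegionParams missing columns {missing}")
        t = self.table.reset_index(drop=True).copy()
        phi = t["phi"].to_numpy(float)
        theta = t["theta"].to_numpy(float)
        if ((phi <= 0) | (phi >= 1)).any():
            raise ValidationError("phi must lie strictly in (0, 1)")
        if (theta <= 0).any():
            raise ValidationError("theta must be strictly positive")
        t["mu0"] = expit(t["alpha"].to_numpy(float))
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def alpha(self) -> np.ndarray:
        return self.table["alpha"].to_numpy(float)

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy(float)

    @property
    def phi(self) -> np.ndarray:
        return self.table["phi"].to_numpy(float)

    @property
    def theta(self) -> np.ndarray:
        return self.table["theta"].to_numpy(float)

    @property
    def is_dmr(self) -> np.ndarray:
        return self.table["is_dmr"].to_numpy(bool)

    @property
    def region_ids(self) -> pd.Series:
        return self.table["region_id"]

    def replace(self, **columns) -> "RegionParams":
        t = self.table.copy()
        for name, values in columns.items():
            t[name] = values
        return RegionParams(t)


@dataclass
class SimulatedDataset:
    """Region-level IP/input counts synthesized for a proposed design."""

    X: np.ndarray
    Y: np.ndarray
    samples: pd.DataFrame
    size_factors: SizeFactors
    truth: pd.DataFrame  # region_id, beta, is_dmr

    def __post_init__(self) -> None:
        self.X = _check_counts("X", self.X)
        self.Y = _check_counts("Y", self.Y)
        if self.X.shape != self.Y.shape:
            raise ValidationError("X and Y must share shape")
        self.samples = check_sample_sheet(self.samples)
        if len(self.truth) != self.X.shape[0]:
            raise ValidationError("truth table must cover every region")

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]


@dataclass
class DMRCallResult:
    """Per-region differential methylation test results."""

    table: pd.DataFrame  # region_id, beta_hat, se, stat, pvalue, qvalue

    COLUMNS = ("region_id", "beta_hat", "se", "stat", "pvalue", "qvalue")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"DMRCallResult missing columns {missing}")
        p = self.table["pvalue"].to_numpy(float)
        q = self.table["qvalue"].to_numpy(float)
        if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
            raise ValidationError("p-values and q-values must lie in [0, 1]")
        self.table = self.table.reset_index(drop=True)[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def qvalue(self) -> np.ndarray:
        return self.table["qvalue"].to_numpy(float)


@dataclass
class ConfusionSummary:
    """Cell counts of the three-way truth x binary-call confusion table.

    Truth rows: non-DMR (beta = 0), non-targeted DMR (0 < |beta| < delta),
    targeted DMR (|beta| >= delta). Columns: not called / called.
    """

    n0: int
    p0: int
    n1: int
    p1: int
    n2: int
    p2: int

    def __post_init__(self) -> None:
        for name in ("n0", "p0", "n1", "p1", "n2", "p2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def r0(self) -> int:
        return self.n0 + self.p0

    @property
    def r1(self) -> int:
        return self.n1 + self.p1

    @property
    def r2(self) -> int:
        return self.n2 + self.p2

    @property
    def n(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def p(self) -> int:
        return self.p0 + self.p1 + self.p2

    @property
    def total(self) -> int:
        return self.n + self.p

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.n0 + other.n0, self.p0 + other.p0,
            self.n1 + other.n1, self.p1 + other.p1,
            self.n2 + other.n2, self.p2 + other.p2,
        )


@dataclass
class PowerMetrics:
    """The five design-evaluation metrics; undefined ratios carried as NaN."""

    fdr: float
    precision: float
    power: float
    targeted_power: float
    fdc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "fdr": self.fdr,
            "precision": self.precision,
            "power": self.power,
            "targeted_power": self.targeted_power,
            "fdc": self.fdc,
        }


@dataclass
class PowerGridResult:
    """Long-format table of metric summaries over a design grid.

    One row per (sample_size, depth_factor, nominal_fdr, delta, stratum,
    metric); ``stratum`` is "all" or "stratum1".."stratumK". ``mean`` and
    ``sd`` summarise the defined replicates; ``n_defined`` counts them and
    ``nsim`` the replicates attempted.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    COLUMNS = GRID_KEYS + ("mean", "sd", "n_defined", "nsim")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"PowerGridResult missing columns {missing}")
        t = self.table.reset_index(drop=True)
        if t.duplicated(subset=list(GRID_KEYS)).any():
            raise ValidationError("duplicate grid keys in PowerGridResult")
        bad = set(t["metric"]) - set(METRIC_NAMES)
        if bad:
            raise ValidationError(f"unknown metric names {sorted(bad)}")
        if (t["nsim"] < 1).any():
            raise ValidationError("nsim must be >= 1")
        if (t["n_defined"] > t["nsim"]).any():
            raise ValidationError("n_defined cannot exceed nsim")
        self.table = t

    def select(self, **keys) -> pd.DataFrame:
        out = self.table
        for name, value in keys.items():
            out = out[out[name] == value]
        return out
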