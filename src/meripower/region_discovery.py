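"""Candidate-region discovery: conditional binomial IP-enrichment + bump merging.

Bin-level paired counts are screened for IP-over-input enrichment with an
exact conditional binomial test (pooled across samples), the per-bin
p-values are Benjamini-Hochberg adjusted, and runs of significant bins are
merged into candidate regions. Bins without enrichment are discarded: they
lack the IP signal that defines a methylated region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from meripower.containers import BinCounts, RegionCounts, SizeFactors, ValidationError


@dataclass
class CandidateRegion:
    """A maximal run of enriched bins with aggregated per-sample counts."""

    region_id: str
    chrom: str
    start: int
    end: int
    strand: str
    bin_indices: list[int]
    x: np.ndarray  # aggregated input counts per sample
    y: np.ndarray  # aggregated IP counts per sample
    min_adj_p: float


def count_bins(
    input_bams: list[str],
    ip_bams: list[str],
    bin_size: int,
    samples: pd.DataFrame,
) -> BinCounts:
    """Reduce coordinate-sorted, indexed BAMs to bin counts.

    Each read is assigned to the single bin containing its 5'-most aligned
    base (reference start for forward reads, last aligned base for reverse
    reads). Only bins with at least one read in any library are kept.
    Requires :mod:`pysam`.
    """
    import pysam

    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    if len(input_bams) != len(samples) or len(ip_bams) != len(samples):
        raise ValidationError("one input BAM and one IP BAM required per sample-sheet row")

    n = len(samples)
    counts: dict[tuple[str, int], np.ndarray] = {}

    def _scan(path: str, col: int, offset: int) -> None:
        with pysam.AlignmentFile(path, "rb") as af:
            if not af.has_index():
                raise IOError(f"{path}: missing BAM index (.bai)")
            for read in af.fetch():
                if read.is_unmapped:
                    continue
                pos5 = read.reference_end - 1 if read.is_reverse else read.reference_start
                key = (read.reference_name, pos5 // bin_size)
                if key not in counts:
                    counts[key] = np.zeros(2 * n, dtype=np.int64)
                counts[key][offset + col] += 1

    for j, path in enumerate(input_bams):
        _scan(path, j, 0)
    for j, path in enumerate(ip_bams):
        _scan(path, j, n)

    keys = sorted(counts)
    mat = (
        np.vstack([counts[k] for k in keys]) if keys else np.zeros((0, 2 * n), dtype=np.int64)
    )
    bins = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "start": [k[1] * bin_size for k in keys],
            "end": [(k[1] + 1) * bin_size for k in keys],
            "strand": "+",
            "bin_id": [f"bin_{i + 1}" for i in range(len(keys))],
        }
    )
    if not keys:
        bins = bins.astype({"start": np.int64, "end": np.int64})
    return BinCounts(bins=bins, X=mat[:, :n], Y=mat[:, n:], samples=samples)


def binomial_enrichment_test(bins: BinCounts, sf: SizeFactors) -> np.ndarray:
    """One-sided exact binomial tail probability of IP enrichment per bin.

    Counts are pooled across samples. Conditional on n = x + y, the IP total
    y is tested against Binomial(n, p0) with p0 = sum(sy) / (sum(sx) + sum(sy)),
    upper tail. Bins with n = 0 carry no evidence and get p = 1.
    """
    if len(sf) != bins.n_samples:
        raise ValidationError("size factors do not match sample count")
    x_tot = bins.X.sum(axis=1)
    y_tot = bins.Y.sum(axis=1)
    n_tot = x_tot + y_tot
    p0 = sf.sy.sum() / (sf.sx.sum() + sf.sy.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        p = binom.sf(y_tot - 1, n_tot, p0)
    p = np.where(n_tot == 0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def merge_significant_bins(
    pvals: np.ndarray,
    bins: BinCounts,
    alpha_bins: float = 0.05,
    max_gap: int = 0,
) -> list[CandidateRegion]:
    """BH-adjust bin p-values and merge significant runs into candidate regions.

    Significant bins (adjusted p < alpha_bins) on the same chromosome and
    strand are merged into maximal runs; up to ``max_gap`` consecutive
    non-significant bins may be bridged, in which case the bridged bins are
    absorbed into the region span and its aggregated counts. A genomic
    discontinuity (missing bins between consecutive rows) counts toward the
    gap as the equivalent number of absent bins. Non-significant bins
    outside any run are discarded.
    """
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) != bins.n_bins:
        raise ValidationError("pvals must align with bins")
    if bins.n_bins == 0:
        return []
    adj = multipletests(pvals, method="fdr_bh")[1]
    sig = adj < alpha_bins

    order = bins.bins.sort_values(["chrom", "strand", "start"]).index.to_numpy()
    regions: list[CandidateRegion] = []
    run: list[int] = []
    gap_buffer: list[int] = []
    gap_count = 0  # buffered bins plus virtual bins missing from the tiling
    prev_key: tuple | None = None
    prev_end: int | None = None

    def _flush() -> None:
        if not run:
            return
        members = sorted(run)
        sub = bins.bins.loc[members]
        regions.append(
            CandidateRegion(
                region_id="",
                chrom=str(sub["chrom"].iloc[0]),
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                strand=str(sub["strand"].iloc[0]),
                bin_indices=members,
                x=bins.X[members].sum(axis=0),
                y=bins.Y[members].sum(axis=0),
                min_adj_p=float(adj[members].min()),
            )
        )

    for idx in order:
        row = bins.bins.loc[idx]
        key = (row["chrom"], row["strand"])
        width = max(int(row["end"]) - int(row["start"]), 1)
        if key != prev_key:
            _flush()
            run, gap_buffer, gap_count = [], [], 0
            prev_key = key
            prev_end = None
        if prev_end is not None and int(row["start"]) > prev_end:
            gap_count += int(round((int(row["start"]) - prev_end) / width))
            if gap_count > max_gap:
                _flush()
                run, gap_buffer, gap_count = [], [], 0
        prev_end = int(row["end"])
        if sig[idx]:
            if run and gap_buffer:
                run.extend(gap_buffer)
            gap_buffer, gap_count = [], 0
            run.append(idx)
        else:
            gap_buffer.append(idx)
            gap_count += 1
            if gap_count > max_gap:
                _flush()
                run, gap_buffer, gap_count = [], [], 0
    _flush()

    regions.sort(key=lambda r: (r.chrom, r.strand, r.start))
    for k, r in enumerate(regions):
        r.region_id = f"candidate_{k + 1}"
    return regions


def regions_to_counts(
    regions: list[CandidateRegion], samples: pd.DataFrame
) -> RegionCounts:
    """Assemble candidate regions into a RegionCounts container."""
    if regions:
        tab = pd.DataFrame(
            {
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
                "strand": [r.strand for r in regions],
                "region_id": [r.region_id for r in regions],
                "min_adj_p": [r.min_adj_p for r in regions],
            }
        )
        X = np.vstack([r.x for r in regions])
        Y = np.vstack([r.y for r in regions])
    else:
        tab = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "region_id": pd.Series(dtype=str),
                "min_adj_p": pd.Series(dtype=float),
            }
        )
        n = len(samples)
        X = np.zeros((0, n), dtype=np.int64)
        Y = np.zeros((0, n), dtype=np.int64)
    return RegionCounts(regions=tab, X=X, Y=Y, samples=samples)
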