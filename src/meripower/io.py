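"""Plain-text readers and writers: BED coordinates, TSV/MTX count matrices.

All coordinates are 0-based half-open (BED convention). Count TSVs carry a
header row of sample ids and a first column of feature (bin/region) ids;
round trips are lossless.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from meripower.containers import BinCounts, RegionCounts, SizeFactors, ValidationError


class ParseError(ValidationError):
    """Raised when an on-disk file violates the expected schema."""


# ---------------------------------------------------------------- BED

def write_bed(
    table: pd.DataFrame,
    path: str | os.PathLike,
    name_col: str = "region_id",
    extra_cols: list[str] | None = None,
) -> None:
    """Write BED6 (+ optional extra columns); score fixed at 0."""
    cols = pd.DataFrame(
        {
            0: table["chrom"],
            1: table["start"].astype(int) if len(table) else table["start"],
            2: table["end"].astype(int) if len(table) else table["end"],
            3: table[name_col],
            4: 0 if len(table) else pd.Series(dtype=int),
            5: table["strand"],
        }
    )
    for k, c in enumerate(extra_cols or []):
        cols[6 + k] = table[c]
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_bed(
    path: str | os.PathLike,
    name_col: str = "region_id",
    extra_cols: list[str] | None = None,
) -> pd.DataFrame:
    extra_cols = extra_cols or []
    names = ["chrom", "start", "end", name_col, "score", "strand"] + extra_cols
    try:
        tab = pd.read_csv(
            path, sep="\t", header=None, names=names, dtype={"chrom": str, name_col: str}
        )
    except pd.errors.EmptyDataError:
        tab = pd.DataFrame({c: pd.Series(dtype=object) for c in names})
        tab["start"] = tab["start"].astype(int)
        tab["end"] = tab["end"].astype(int)
    out = tab[["chrom", "start", "end", "strand", name_col] + extra_cols].copy()
    return out


# ---------------------------------------------------------------- count TSV

def write_count_matrix(
    counts: np.ndarray,
    feature_ids,
    sample_ids,
    path: str | os.PathLike,
) -> None:
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64), columns=list(sample_ids))
    df.insert(0, "feature_id", list(feature_ids))
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | os.PathLike):
    """Read a count TSV -> (feature_ids, sample_ids, int matrix).

    Malformed headers and non-integer or negative entries raise
    :class:`ParseError` naming the offending line/cell (1-based file lines,
    header = line 1).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 1 or fields[0] != "feature_id":
        raise ParseError(
            f"{path}: line 1: malformed header (expected first column 'feature_id', got {fields[:1]})"
        )
    tab = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    sample_ids = list(tab.columns[1:])
    raw = tab[sample_ids]
    for col in sample_ids:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: line {i + 2}: non-integer count {raw[col].iloc[i]!r} "
                f"in column {col!r} (feature {tab['feature_id'].iloc[i]!r})"
            )
        if (vals < 0).any():
            i = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise ParseError(
                f"{path}: line {i + 2}: negative count {vals.iloc[i]} "
                f"in column {col!r} (feature {tab['feature_id'].iloc[i]!r})"
            )
    mat = raw.to_numpy(dtype=np.int64) if len(tab) else np.zeros((0, len(sample_ids)), dtype=np.int64)
    return tab["feature_id"].tolist(), sample_ids, mat


# ---------------------------------------------------------------- MTX variant

def write_count_matrix_mtx(
    counts: np.ndarray, feature_ids, sample_ids, prefix: str | os.PathLike
) -> None:
    """Sparse MatrixMarket triple: <prefix>.mtx, <prefix>.features.tsv, <prefix>.samples.tsv."""
    from scipy import io as spio
    from scipy.sparse import coo_matrix

    prefix = str(prefix)
    spio.mmwrite(prefix + ".mtx", coo_matrix(np.asarray(counts, dtype=np.int64)))
    pd.Series(list(feature_ids)).to_csv(prefix + ".features.tsv", sep="\t", index=False, header=False)
    pd.Series(list(sample_ids)).to_csv(prefix + ".samples.tsv", sep="\t", index=False, header=False)


def read_count_matrix_mtx(prefix: str | os.PathLike):
    from scipy import io as spio

    prefix = str(prefix)
    mat = np.asarray(spio.mmread(prefix + ".mtx").todense()).astype(np.int64)
    features = pd.read_csv(prefix + ".features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(features), len(samples)):
        raise ParseError(f"{prefix}.mtx: shape {mat.shape} does not match id files")
    return features, samples, mat


# ---------------------------------------------------------------- assembled containers

def read_bin_counts(directory: str | os.PathLike) -> BinCounts:
    """Read bins.bed + X.tsv + Y.tsv + samples.tsv into a BinCounts."""
    directory = str(directory)
    bed_path = os.path.join(directory, "bins.bed")
    has_region = False
    if os.path.exists(bed_path):
        with open(bed_path) as fh:
            first = fh.readline()
        has_region = first and len(first.rstrip("\n").split("\t")) >= 7
    bins = read_bed(bed_path, name_col="bin_id", extra_cols=["region_id"] if has_region else None)
    ids, sample_ids, X = read_count_matrix(os.path.join(directory, "X.tsv"))
    ids_y, sample_ids_y, Y = read_count_matrix(os.path.join(directory, "Y.tsv"))
    if ids != ids_y or sample_ids != sample_ids_y:
        raise ParseError(f"{directory}: X.tsv and Y.tsv disagree on features or samples")
    if ids != bins["bin_id"].tolist():
        raise ParseError(f"{directory}: bins.bed and count TSVs disagree on bin ids")
    samples = pd.read_csv(os.path.join(directory, "samples.tsv"), sep="\t")
    return BinCounts(bins=bins, X=X, Y=Y, samples=samples)


def write_region_counts(rc: RegionCounts, directory: str | os.PathLike) -> None:
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    write_bed(rc.regions, os.path.join(directory, "regions.bed"), name_col="region_id")
    write_count_matrix(rc.X, rc.region_ids, rc.samples["sample"], os.path.join(directory, "X.tsv"))
    write_count_matrix(rc.Y, rc.region_ids, rc.samples["sample"], os.path.join(directory, "Y.tsv"))
    rc.samples.to_csv(os.path.join(directory, "samples.tsv"), sep="\t", index=False)


def read_region_counts(directory: str | os.PathLike) -> RegionCounts:
    directory = str(directory)
    regions = read_bed(os.path.join(directory, "regions.bed"), name_col="region_id")
    ids, sample_ids, X = read_count_matrix(os.path.join(directory, "X.tsv"))
    ids_y, sample_ids_y, Y = read_count_matrix(os.path.join(directory, "Y.tsv"))
    if ids != ids_y or sample_ids != sample_ids_y:
        raise ParseError(f"{directory}: X.tsv and Y.tsv disagree on features or samples")
    samples = pd.read_csv(os.path.join(directory, "samples.tsv"), sep="\t")
    return RegionCounts(regions=regions, X=X, Y=Y, samples=samples)


def write_size_factors(sf: SizeFactors, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample": sf.samples, "sx": sf.sx, "sy": sf.sy}).to_csv(
        path, sep="\t", index=False
    )


def read_size_factors(path: str | os.PathLike) -> SizeFactors:
    tab = pd.read_csv(path, sep="\t")
    return SizeFactors(tab["sx"].to_numpy(), tab["sy"].to_numpy(), tab["sample"].astype(str).tolist())


def write_params(params, path: str | os.PathLike) -> None:
    tab = params.table.copy()
    tab["is_dmr"] = tab["is_dmr"].astype(int)
    tab.to_csv(path, sep="\t", index=False)


def read_params(path: str | os.PathLike):
    from meripower.containers import RegionParams

    tab = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    tab["is_dmr"] = tab["is_dmr"].astype(bool)
    return RegionParams(tab)
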