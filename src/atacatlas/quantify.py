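"""Peak x sample quantification: raw fragment counts over the standard
peak set, reads-per-million normalization, sample Pearson correlation on
the log10 scale, and average-linkage clustering of samples.

Counting follows BedTools ``intersect -c`` semantics: a fragment adds 1 to
every standard peak it overlaps by >= 1 bp (after merging, a short fragment
almost always overlaps at most one). The RPM denominator is the total
number of fragments in the sample's file — the stand-in for mapped reads —
not reads-in-peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .atlas import PeakAtlas
from .intervals import BedParseError


@dataclass
class CountMatrix:
    """Raw peak x sample fragment counts plus per-sample library sizes."""

    counts: pd.DataFrame  # peaks x samples, non-negative integers
    library_sizes: pd.Series  # total fragments per sample file

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for samples {sorted(missing)}")


@dataclass
class NormalizedMatrix:
    """RPM view of a count matrix with its log10(pseudocounted) companion."""

    rpm: pd.DataFrame
    log10: pd.DataFrame
    library_sizes: pd.Series
    pseudocount: float


def _read_fragment_frame(path: str | Path) -> pd.DataFrame:
    """Fast 3-column BED reader for fragment files (validated, chunk-free)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise BedParseError(f"{path}: malformed fragment BED ({exc})") from exc
    if df.empty:
        return df
    bad = (df["start"] < 0) | (df["end"] <= df["start"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise BedParseError(f"{path} line {line}: invalid interval")
    return df


def build_count_matrix(
    atlas: PeakAtlas,
    fragment_files: Mapping[str, str | Path],
) -> CountMatrix:
    """Count fragments overlapping each standard peak, per sample.

    Entry (p, s) is the number of fragments in sample s sharing >= 1 bp
    with peak p; a fragment spanning k peaks contributes to all k. The
    library size of s is the total number of fragments in its file. A
    sample with zero fragments yields an all-zero column and a warning.
    """
    if len(atlas) == 0:
        raise ValueError("atlas has no peaks")
    # per-chromosome sorted peak coordinate arrays with atlas row indices
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(atlas.peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: atlas.peaks[i].start)
        chrom_arrays[chrom] = (
            np.asarray([atlas.peaks[i].start for i in idxs], dtype=np.int64),
            np.asarray([atlas.peaks[i].end for i in idxs], dtype=np.int64),
            np.asarray(idxs, dtype=np.int64),
        )
    samples = list(fragment_files)
    mat = np.zeros((len(atlas), len(samples)), dtype=np.int64)
    lib = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        frags = _read_fragment_frame(fragment_files[sample])
        lib[j] = len(frags)
        if frags.empty:
            warnings.warn(f"sample {sample!r} has zero fragments", stacklevel=2)
            continue
        for chrom, sub in frags.groupby("chrom", sort=False):
            if chrom not in chrom_arrays:
                continue
            starts, ends, rows = chrom_arrays[chrom]
            fs = sub["start"].to_numpy()
            fe = sub["end"].to_numpy()
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            # each fragment covers the contiguous peak run [lo, hi)
            diff = np.zeros(len(starts) + 1, dtype=np.int64)
            np.add.at(diff, lo, 1)
            np.add.at(diff, hi, -1)
            mat[rows, j] += np.cumsum(diff[:-1])
    counts = pd.DataFrame(mat, index=atlas.peak_ids, columns=samples)
    return CountMatrix(counts, pd.Series(lib, index=samples, name="library_size"))


def normalize_rpm(
    cm: CountMatrix,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """RPM(p, s) = raw(p, s) x 1e6 / library_size(s); log10(RPM + pc) view."""
    zero = cm.library_sizes[cm.library_sizes <= 0]
    if len(zero):
        raise ValueError(
            f"zero library size for sample(s) {list(zero.index)}"
        )
    lib = cm.library_sizes.reindex(cm.counts.columns)
    rpm = cm.counts * 1e6 / lib
    log10 = np.log10(rpm + pseudocount)
    return NormalizedMatrix(rpm, log10, lib, pseudocount)


def sample_correlation(norm: NormalizedMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation of the log10 RPM matrix.

    Symmetric with unit diagonal. A zero-variance (constant) sample yields
    NaN sentinels in its row/column with a warning.
    """
    if norm.log10.shape[0] < 2:
        raise ValueError("need >= 2 peaks to correlate samples")
    constant = norm.log10.nunique(axis=0) == 1
    flat = constant[constant]
    if len(flat):
        warnings.warn(
            f"zero-variance sample(s) {list(flat.index)}: correlation undefined",
            stacklevel=2,
        )
    corr = norm.log10.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    corr.loc[flat.index, :] = np.nan
    corr.loc[:, flat.index] = np.nan
    for s in flat.index:
        corr.loc[s, s] = np.nan
    return corr


def cluster_samples(corr: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on distance 1 - r.

    Returns the leaf order (sample ids) and the scipy linkage matrix.
    Scipy's linkage is deterministic for a fixed input; equal-distance
    merges resolve by the earlier cluster index, so the leaf order is a
    stable function of the correlation matrix (not of input sample order
    at the topology level — permuting samples permutes leaves but leaves
    cophenetic distances unchanged).
    """
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains NaN; drop those samples")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    order = [corr.columns[i] for i in leaves_list(Z)]
    return order, Z


def replicate_clade_fraction(
    Z: np.ndarray,
    samples: Sequence[str],
    sample_to_tissue: Mapping[str, str],
) -> float:
    """Fraction of tissues whose two replicates merge with each other first.

    A tissue scores iff some linkage row joins exactly its two replicate
    leaves (they are mutual nearest leaves in the dendrogram). Tissues
    without exactly two samples are skipped.
    """
    n = len(samples)
    pair_rows = set()
    for a, b, *_ in Z:
        if a < n and b < n:
            pair_rows.add(frozenset((samples[int(a)], samples[int(b)])))
    tissues: dict[str, list[str]] = {}
    for s in samples:
        tissues.setdefault(sample_to_tissue[s], []).append(s)
    eligible = [v for v in tissues.values() if len(v) == 2]
    if not eligible:
        raise ValueError("no tissue has exactly two replicates")
    hits = sum(1 for pair in eligible if frozenset(pair) in pair_rows)
    return hits / len(eligible)
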