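"""Dataset-level quality control: the aggregate fragment-enrichment
profile around transcription start sites and the genomic-region
annotation proportions of the standard peak atlas.

The TSS enrichment score is the flank-normalized aggregate coverage at the
TSS: per-TSS fragment coverage is binned over a +/- half_width window
(strand-flipped for minus-strand TSSs), averaged over TSSs, and divided by
the mean of the outermost flank bins. Uniform coverage therefore scores
exactly 1; TSS-concentrated signal scores above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import PeakAtlas
from .intervals import GenomicInterval, TSSAnnotation


@dataclass
class TSSEnrichmentProfile:
    """Aggregate binned coverage around TSSs with its normalized view."""

    half_width: int
    bin_size: int
    flank: int
    bin_centers: np.ndarray  # bp offsets relative to the TSS
    raw: np.ndarray  # mean fragment coverage per bin over TSSs
    normalized: np.ndarray | None  # raw / flank mean; None if flank empty
    score: float | None  # normalized value at the TSS bin; None = undefined
    n_tss: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.bin_centers,
                "raw": self.raw,
                "normalized": (
                    self.normalized
                    if self.normalized is not None
                    else np.full_like(self.raw, np.nan)
                ),
            }
        )


def tss_enrichment(
    fragments: Sequence[GenomicInterval],
    tss: TSSAnnotation,
    half_width: int = 2000,
    bin_size: int = 10,
    flank: int = 100,
) -> TSSEnrichmentProfile:
    """Flank-normalized fragment enrichment around TSSs for one sample.

    A fragment contributes 1 to every bin it overlaps (the same >= 1 bp
    semantics as peak counting). The outermost ``flank`` bp on each side
    of the window define the normalization baseline; if their mean
    coverage is zero the score is undefined (None) and a warning is
    emitted.
    """
    if half_width % bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    if not 0 < flank < half_width:
        raise ValueError("flank must lie in (0, half_width)")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    n_bins = 2 * half_width // bin_size
    center_bin = n_bins // 2  # bin whose left edge is the TSS

    frag_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        grouped.setdefault(f.chrom, []).append((f.start, f.end))
    max_len = 0
    for chrom, pairs in grouped.items():
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        frag_by_chrom[chrom] = (arr[:, 0], arr[:, 1])
        max_len = max(max_len, int((arr[:, 1] - arr[:, 0]).max()))

    total = np.zeros(n_bins, dtype=np.float64)
    for t in tss:
        w_start = t.position - half_width
        w_end = t.position + half_width
        bins = np.zeros(n_bins + 1, dtype=np.int64)
        if t.chrom in frag_by_chrom:
            fs, fe = frag_by_chrom[t.chrom]
            # candidate fragments: start within (w_start - max_len, w_end)
            lo = np.searchsorted(fs, w_start - max_len, side="right")
            hi = np.searchsorted(fs, w_end, side="left")
            cs, ce = fs[lo:hi], fe[lo:hi]
            keep = ce > w_start
            cs, ce = cs[keep], ce[keep]
            b0 = np.maximum((cs - w_start) // bin_size, 0)
            b1 = np.minimum(-(-(ce - w_start) // bin_size), n_bins)
            np.add.at(bins, b0, 1)
            np.add.at(bins, b1, -1)
        curve = np.cumsum(bins[:-1])
        if t.strand == "-":
            curve = curve[::-1]
        total += curve

    raw = total / len(tss)
    n_flank_bins = flank // bin_size
    flank_mean = float(
        np.concatenate((raw[:n_flank_bins], raw[-n_flank_bins:])).mean()
    )
    if flank_mean <= 0:
        warnings.warn(
            "zero coverage in TSS flank bins: enrichment score undefined",
            stacklevel=2,
        )
        normalized, score = None, None
    else:
        normalized = raw / flank_mean
        score = float(normalized[center_bin])
    centers = (
        np.arange(n_bins) * bin_size - half_width + bin_size // 2
    ).astype(np.int64)
    return TSSEnrichmentProfile(
        half_width, bin_size, flank, centers, raw, normalized, score, len(tss)
    )


@dataclass
class RegionProportions:
    """Region-class composition of an annotated atlas."""

    fractions: dict[str, float]  # over classified peaks; sums to 1
    counts: dict[str, int]
    n_unassigned: int  # peaks with undefined TSS distance


def region_proportions(atlas: PeakAtlas) -> RegionProportions:
    """Fractions of standard peaks per genomic-region class.

    Peaks with an undefined TSS distance (no TSS on their chromosome) are
    excluded from the fractions and tallied as unassigned.
    """
    if not atlas.annotated:
        raise ValueError("atlas must be annotated before computing proportions")
    if len(atlas) == 0:
        raise ValueError("atlas is empty")
    counts: dict[str, int] = {}
    unassigned = 0
    for dist, cls in zip(atlas.tss_distance, atlas.region_class):  # type: ignore[arg-type]
        if dist is None:
            unassigned += 1
            continue
        counts[cls] = counts.get(cls, 0) + 1
    classified = sum(counts.values())
    if classified == 0:
        return RegionProportions({}, counts, unassigned)
    fractions = {c: n / classified for c, n in counts.items()}
    return RegionProportions(fractions, counts, unassigned)
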