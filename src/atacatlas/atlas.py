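"""Standard peak atlas: replicate-reproducible peaks per tissue, merged
across tissues, annotated with distance to the nearest TSS and a
promoter-proximal / distal class.

The replicate filter is the operative presence-in-both-replicates rule: a
peak survives iff it shares >= 1 bp with a peak called in the other
biological replicate. The full irreproducible-discovery-rate model is
deliberately not implemented; the overlap rule is the reproducible
specification of the filtering step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    TSSAnnotation,
    count_overlaps,
    distance_to_nearest_tss,
    merge_intervals,
    write_bed,
)

PROMOTER_PROXIMAL = "promoter-proximal"
DISTAL = "distal"


@dataclass
class PeakAtlas:
    """The merged standard peak set with optional TSS annotation.

    ``peaks`` are pairwise non-overlapping, sorted by (chrom, start), and
    carry stable ids ``peak_000001``... in that order. ``provenance[i]`` is
    the set of tissues contributing >= 1 source peak to standard peak i.
    Annotation fields are filled by :func:`annotate_atlas`.
    """

    peaks: list[GenomicInterval]
    provenance: list[frozenset[str]]
    tss_distance: list[int | None] | None = None
    region_class: list[str | None] | None = None
    nearest_gene: list[str | None] | None = None
    proximal_cutoff: int | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def peak_ids(self) -> list[str]:
        return [p.name for p in self.peaks]  # type: ignore[misc]

    @property
    def annotated(self) -> bool:
        return self.tss_distance is not None

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.peaks, path)

    def annotation_table(self) -> pd.DataFrame:
        if not self.annotated:
            raise ValueError("atlas is not annotated; run annotate_atlas first")
        return pd.DataFrame(
            {
                "peak_id": self.peak_ids,
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "tss_distance": self.tss_distance,
                "region_class": self.region_class,
                "nearest_gene": self.nearest_gene,
                "provenance": [",".join(sorted(s)) for s in self.provenance],
            }
        )


def reproducible_peaks(
    rep1: Sequence[GenomicInterval],
    rep2: Sequence[GenomicInterval],
    mode: str = "reference",
) -> list[GenomicInterval]:
    """Peaks present in both biological replicates (>= 1 bp overlap).

    mode="reference" (default) returns the rep1 intervals having an
    overlap in rep2 — the first replicate's coordinates survive.
    mode="union" merges the surviving intervals of both replicates.
    """
    if mode not in ("reference", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    kept1 = [
        iv for iv, c in zip(rep1, count_overlaps(rep1, rep2)) if c > 0
    ]
    if mode == "reference":
        return kept1
    kept2 = [
        iv for iv, c in zip(rep2, count_overlaps(rep2, rep1)) if c > 0
    ]
    if not kept1 and not kept2:
        return []
    return merge_intervals(kept1 + kept2)


def build_standard_peaks(
    per_tissue: Mapping[str, Sequence[GenomicInterval]],
) -> PeakAtlas:
    """Merge every tissue's reproducible peaks into the standard peak set.

    Output is invariant to tissue input order; each standard peak records
    which tissues contributed at least one overlapping source peak.
    """
    if not per_tissue:
        raise ValueError("at least one tissue is required")
    pooled = [iv for ivs in per_tissue.values() for iv in ivs]
    merged = merge_intervals(pooled) if pooled else []
    peaks = [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i + 1:06d}", 0.0)
        for i, iv in enumerate(merged)
    ]
    provenance: list[set[str]] = [set() for _ in peaks]
    for tissue in sorted(per_tissue):
        hits = count_overlaps(peaks, per_tissue[tissue])
        for i, c in enumerate(hits):
            if c > 0:
                provenance[i].add(tissue)
    return PeakAtlas(peaks, [frozenset(s) for s in provenance])


def annotate_atlas(
    atlas: PeakAtlas,
    tss: TSSAnnotation,
    proximal_cutoff: int = 2000,
) -> PeakAtlas:
    """Fill per-peak TSS distance, nearest gene, and region class.

    A peak is promoter-proximal iff its unsigned TSS distance is
    <= proximal_cutoff. Peaks on chromosomes with no TSS get an undefined
    distance (None) and are classed distal; they are tallied separately as
    unassigned by :func:`atacatlas.qc.region_proportions`.
    """
    nearest = distance_to_nearest_tss(atlas.peaks, tss)
    distances = [d for d, _ in nearest]
    genes = [g for _, g in nearest]
    classes = [
        PROMOTER_PROXIMAL if (d is not None and d <= proximal_cutoff) else DISTAL
        for d in distances
    ]
    return replace(
        atlas,
        tss_distance=distances,
        nearest_gene=genes,
        region_class=classes,
        proximal_cutoff=proximal_cutoff,
    )
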