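"""Genomic interval primitives: the data model, BED/FASTA/TSS I/O, and the
merge / overlap-count / nearest-TSS operations every pipeline stage builds on.

All coordinates are 0-based half-open (BED convention). Two intervals overlap
iff they share at least one base pair; intervals that merely touch
(``end`` of one equals ``start`` of the next) do not overlap and are not
merged, matching the default semantics of BedTools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO


class BedParseError(ValueError):
    """A malformed line in a BED-like file; message names the line number."""


class BoundsError(ValueError):
    """An interval extends beyond the end of its chromosome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on one chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    start : 0-based inclusive start, bp.
    end : 0-based exclusive end, bp; must exceed ``start``.
    name : optional label (BED column 4).
    score : optional numeric score (BED column 5).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp shared; boundary-touching intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSS:
    """One transcription start site: a 0-based point with gene and strand."""

    chrom: str
    position: int
    gene: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class TSSAnnotation:
    """A set of TSS points, unique on (chrom, position, gene), kept sorted."""

    def __init__(self, entries: Iterable[TSS]):
        entries = sorted(entries, key=lambda t: (t.chrom, t.position, t.gene))
        seen: set[tuple[str, int, str]] = set()
        for t in entries:
            key = (t.chrom, t.position, t.gene)
            if key in seen:
                raise ValueError(f"duplicate TSS entry {key}")
            seen.add(key)
        self.entries: list[TSS] = entries
        grouped: dict[str, list[TSS]] = {}
        for t in entries:
            grouped.setdefault(t.chrom, []).append(t)
        self._by_chrom: dict[str, tuple[np.ndarray, list[TSS]]] = {
            c: (np.asarray([t.position for t in ts], dtype=np.int64), ts)
            for c, ts in grouped.items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def chrom_positions(self, chrom: str) -> tuple[np.ndarray, list[TSS]]:
        """Sorted positions and parallel entries for one chromosome."""
        if chrom not in self._by_chrom:
            return np.empty(0, dtype=np.int64), []
        return self._by_chrom[chrom]

    @classmethod
    def from_bed(cls, path: str | Path) -> "TSSAnnotation":
        """Read TSS points from a BED6 of 1-bp intervals (start = TSS)."""
        entries = []
        for i, line in enumerate(_bed_lines(path), start=1):
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path} line {i}: TSS BED needs >= 4 columns"
                )
            chrom, start, end = fields[0], fields[1], fields[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {i}: non-integer coordinates"
                ) from exc
            if end_i != start_i + 1:
                raise BedParseError(
                    f"{path} line {i}: TSS interval must be 1 bp wide"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            entries.append(TSS(chrom, start_i, fields[3], strand))
        return cls(entries)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.entries:
                fh.write(
                    f"{t.chrom}\t{t.position}\t{t.position + 1}"
                    f"\t{t.gene}\t0\t{t.strand}\n"
                )


class GenomeSequence:
    """Per-chromosome nucleotide strings over {A, C, G, T, N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {c: str(s).upper() for c, s in sequences.items()}
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        records = SeqIO.parse(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def extract(self, interval: GenomicInterval) -> str:
        """Plus-strand sequence of ``interval``; bounds-checked."""
        if interval.chrom not in self.sequences:
            raise BoundsError(f"unknown chromosome {interval.chrom!r}")
        length = self.lengths[interval.chrom]
        if interval.end > length:
            raise BoundsError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {length}"
            )
        return self.sequences[interval.chrom][interval.start : interval.end]


def _bed_lines(path: str | Path):
    """Yield data lines of a BED file; skips blank, '#' and 'track'/'browser'."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/4/5/6 file into intervals, preserving file order.

    Coordinates are taken verbatim as 0-based half-open. A malformed line
    (fewer than 3 columns, non-integer coordinates, or end <= start) raises
    :class:`BedParseError` naming the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path} line {i}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {i}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start < 0 or end <= start:
                raise BedParseError(
                    f"{path} line {i}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path} line {i}: non-numeric score {fields[4]!r}"
                    ) from exc
            intervals.append(GenomicInterval(fields[0], start, end, name, score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0, strand '.' when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = iv.score if iv.score is not None else 0
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of overlapping intervals, sorted by (chrom, start).

    Output intervals on one chromosome are pairwise non-overlapping and
    cover exactly the same base set as the input. Boundary-touching
    intervals are kept separate. Names and scores are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict: touching does not merge
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def count_overlaps(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-query count of subject intervals sharing >= 1 bp.

    O((n+m) log m) per chromosome via sorted-endpoint counting: the number
    of subjects overlapping [s, e) equals #(subject.start < e) minus
    #(subject.end <= s), because any subject ending at or before s also
    starts before e.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        starts[chrom] = np.sort(np.asarray([iv.start for iv in ivs], dtype=np.int64))
        ends[chrom] = np.sort(np.asarray([iv.end for iv in ivs], dtype=np.int64))
    counts = np.zeros(len(query), dtype=np.int64)
    for i, q in enumerate(query):
        if q.chrom not in starts:
            continue
        n_start_before = np.searchsorted(starts[q.chrom], q.end, side="left")
        n_end_before = np.searchsorted(ends[q.chrom], q.start, side="right")
        counts[i] = n_start_before - n_end_before
    return counts


def distance_to_nearest_tss(
    peaks: Sequence[GenomicInterval],
    tss: TSSAnnotation,
) -> list[tuple[int | None, str | None]]:
    """Unsigned distance from each peak to its nearest TSS, with the gene.

    Distance is 0 when a TSS lies within [start, end); otherwise the gap in
    bp between the TSS point and the nearest peak boundary (start − pos on
    the left, pos − end on the right). Ties are broken by the first TSS in
    (chrom, position, gene) sorted order. A peak on a chromosome with no
    TSS gets ``(None, None)``.
    """
    results: list[tuple[int | None, str | None]] = []
    for peak in peaks:
        positions, entries = tss.chrom_positions(peak.chrom)
        if len(positions) == 0:
            results.append((None, None))
            continue
        i = int(np.searchsorted(positions, peak.start, side="left"))
        if i < len(positions) and positions[i] < peak.end:
            # contained: first entry in sorted order within the peak
            results.append((0, entries[i].gene))
            continue
        candidates: list[tuple[int, int]] = []  # (distance, position)
        if i > 0:
            left_pos = int(positions[i - 1])
            candidates.append((peak.start - left_pos, left_pos))
        if i < len(positions):
            right_pos = int(positions[i])
            candidates.append((right_pos - peak.end, right_pos))
        dist, pos = min(candidates)  # tie -> smaller position, i.e. first sorted
        j = int(np.searchsorted(positions, pos, side="left"))
        results.append((dist, entries[j].gene))
    return results


def extract_sequence(genome: GenomeSequence, interval: GenomicInterval) -> str:
    """Plus-strand sequence under ``interval``; raises on out-of-bounds."""
    return genome.extract(interval)
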