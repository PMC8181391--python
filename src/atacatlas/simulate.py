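"""Synthetic tissue ATAC-seq data with known ground truth.

The generator emulates the design of a multi-tissue bulk ATAC-seq atlas:
several tissues, two biological replicates each, a set of "housekeeping"
peaks shared by every tissue and placed at TSSs, and per-tissue distal
specific peaks whose accessibility in their home tissue exceeds the other
tissues by a stated fold. Per-sample fragment counts are one multinomial
draw over (background + peaks), so depth normalization by reads-per-million
is the exactly right correction. Replicate peak calls are the true peaks
with boundary jitter plus replicate-private noise peaks — the reason the
present-in-both-replicates filter exists. Sequences under a tissue's
specific peaks carry one planted instance of that tissue's motif at a
configurable rate; background sequence is i.i.d. uniform A/C/G/T.

Two generation routes share one distribution:

* ``simulate_atlas(config)`` draws per-peak fragment *counts* only (fast;
  used by statistical tests at full depth), and
* ``simulate_atlas(config, outdir=...)`` additionally materializes fragment
  coordinates and writes FASTA/BED files. Fragments are placed entirely
  inside their source peak and background fragments entirely inside
  inter-peak gaps, so counting fragments against the true peaks reproduces
  the multinomial draw exactly.

Everything is deterministic given ``config.seed``: independent named
substreams (layout, genome, peak calls, counts, fragments) are spawned from
one SeedSequence, so skipping genome synthesis never perturbs the counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomeSequence, GenomicInterval, TSS, TSSAnnotation, write_bed

SHARED = "shared"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """The requested design does not fit the requested genome."""


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Defaults describe a desk-scale body-organ design: 10 tissues x 2
    replicates, 200 shared TSS-proximal peaks, 200 specific distal peaks
    per tissue at 8-fold home-tissue accessibility, 1M fragments per
    sample with 40% background.
    """

    n_tissues: int = 10
    n_replicates: int = 2
    n_shared_peaks: int = 200
    n_specific_peaks_per_tissue: int = 200
    peak_width: int = 500
    genome_size: int = 2_000_000
    n_chromosomes: int = 5
    fragments_per_sample: int = 1_000_000
    specific_fold: float = 8.0
    background_fraction: float = 0.4
    replicate_jitter: float = 20.0
    noise_peak_rate: float = 0.1
    fragment_length: int = 50
    peak_spacing: int = 2000
    motif_length: int = 8
    motif_planting_rate: float = 0.8
    motif_consensus_prob: float = 0.97
    planted_motifs: list[tuple[str, np.ndarray, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_tissues,
            self.n_replicates,
            self.n_shared_peaks,
            self.n_specific_peaks_per_tissue,
            self.peak_width,
            self.genome_size,
            self.n_chromosomes,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all design counts must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise ConfigurationError("background_fraction must be in [0, 1)")
        if self.specific_fold < 1:
            raise ConfigurationError("specific_fold must be >= 1")
        if self.fragments_per_sample < 0:
            raise ConfigurationError("fragments_per_sample must be >= 0")
        if self.fragment_length > self.peak_width:
            raise ConfigurationError("fragment_length must fit inside a peak")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{t}_rep{r}"
            for t in self.tissues
            for r in range(1, self.n_replicates + 1)
        ]

    @property
    def n_true_peaks(self) -> int:
        return self.n_shared_peaks + self.n_tissues * self.n_specific_peaks_per_tissue

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d.pop("planted_motifs")  # PWMs are written to their own file
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass(frozen=True)
class TruePeak:
    peak_id: str
    chrom: str
    start: int
    end: int
    label: str  # SHARED or the home-tissue name

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.peak_id)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: peak labels, weights, motif plants."""

    peaks: list[TruePeak]
    weights: pd.DataFrame  # true peaks x tissues accessibility weights
    motif_placements: list[dict]  # peak_id, motif_id, offset (within peak)
    motif_consensi: dict[str, str]  # motif id -> consensus string
    motif_targets: dict[str, str]  # motif id -> home tissue

    def label_of(self, peak_id: str) -> str:
        return self._by_id()[peak_id].label

    def _by_id(self) -> dict[str, TruePeak]:
        if not hasattr(self, "_index"):
            self._index = {p.peak_id: p for p in self.peaks}
        return self._index

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peaks": [dataclasses.asdict(p) for p in self.peaks],
            "weights": {
                t: self.weights[t].tolist() for t in self.weights.columns
            },
            "peak_ids": list(self.weights.index),
            "motif_placements": self.motif_placements,
            "motif_consensi": self.motif_consensi,
            "motif_targets": self.motif_targets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: SyntheticTruth
    counts: pd.DataFrame  # true peaks x samples fragment counts
    background_counts: pd.Series  # per-sample fragments outside peaks
    replicate_peaks: dict[tuple[str, int], list[GenomicInterval]]
    tss: TSSAnnotation
    genome: GenomeSequence | None = None
    sample_sheet: pd.DataFrame | None = None

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.background_counts


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _layout(config: SimulationConfig, rng: np.random.Generator):
    """Place true peaks on a regular grid of slots and shuffle labels."""
    slot = config.peak_width + config.peak_spacing
    per_chrom = max(0, (config.genome_size - config.peak_spacing) // slot)
    total_slots = per_chrom * config.n_chromosomes
    if total_slots < config.n_true_peaks:
        raise ConfigurationError(
            f"genome fits {total_slots} peaks but {config.n_true_peaks} requested"
        )
    labels = [SHARED] * config.n_shared_peaks + [
        t for t in config.tissues
        for _ in range(config.n_specific_peaks_per_tissue)
    ]
    rng.shuffle(labels)
    chroms = _chrom_names(config)
    peaks: list[TruePeak] = []
    for k, label in enumerate(labels):
        chrom = chroms[k // per_chrom]
        start = config.peak_spacing + (k % per_chrom) * slot
        peaks.append(
            TruePeak(f"true_{k:06d}", chrom, start, start + config.peak_width, label)
        )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    peaks = [
        TruePeak(f"true_{i:06d}", p.chrom, p.start, p.end, p.label)
        for i, p in enumerate(peaks)
    ]
    return peaks


def _weights(config: SimulationConfig, peaks: list[TruePeak]) -> pd.DataFrame:
    w = np.ones((len(peaks), config.n_tissues))
    tissue_idx = {t: j for j, t in enumerate(config.tissues)}
    for i, p in enumerate(peaks):
        if p.label != SHARED:
            w[i, tissue_idx[p.label]] = config.specific_fold
    return pd.DataFrame(w, index=[p.peak_id for p in peaks], columns=config.tissues)


def _tss_for(peaks: list[TruePeak]) -> TSSAnnotation:
    entries = []
    g = 0
    for p in peaks:
        if p.label == SHARED:
            center = (p.start + p.end) // 2
            strand = "+" if g % 2 == 0 else "-"
            entries.append(TSS(p.chrom, center, f"gene{g:05d}", strand))
            g += 1
    return TSSAnnotation(entries)


def _default_motifs(config: SimulationConfig, rng: np.random.Generator):
    """One near-point-mass PWM per tissue with distinct random consensi."""
    consensi: dict[str, str] = {}
    targets: dict[str, str] = {}
    pwms: list[tuple[str, np.ndarray, str]] = []
    seen: set[str] = set()
    for t in config.tissues:
        while True:
            idx = rng.integers(0, 4, config.motif_length)
            cons = "".join("ACGT"[b] for b in idx)
            if cons not in seen and cons != cons[::-1]:
                seen.add(cons)
                break
        p_on = config.motif_consensus_prob
        p_off = (1.0 - p_on) / 3.0
        probs = np.full((config.motif_length, 4), p_off)
        probs[np.arange(config.motif_length), idx] = p_on
        motif_id = f"MOTIF_{t}"
        consensi[motif_id] = cons
        targets[motif_id] = t
        pwms.append((motif_id, probs, t))
    return pwms, consensi, targets


def _replicate_calls(
    config: SimulationConfig,
    peaks: list[TruePeak],
    rng: np.random.Generator,
) -> dict[tuple[str, int], list[GenomicInterval]]:
    """True peaks with boundary jitter plus replicate-private noise peaks.

    Jitter offsets are clipped so each jittered peak still contains the
    true peak center, guaranteeing both replicates overlap.
    """
    chroms = _chrom_names(config)
    half = config.peak_width // 2 - 1
    clip = max(1, min(half, config.peak_spacing // 2 - 1))
    gaps = _gap_table(config, peaks)
    calls: dict[tuple[str, int], list[GenomicInterval]] = {}
    for tissue in config.tissues:
        own = [p for p in peaks if p.label in (SHARED, tissue)]
        for rep in range(1, config.n_replicates + 1):
            out: list[GenomicInterval] = []
            deltas = rng.normal(0.0, config.replicate_jitter, size=(len(own), 2))
            deltas = np.clip(np.rint(deltas), -clip, clip).astype(int)
            for p, (ds, de) in zip(own, deltas):
                start = max(0, p.start + int(ds))
                end = min(config.genome_size, p.end + int(de))
                out.append(GenomicInterval(p.chrom, start, max(end, start + 1)))
            n_noise = int(round(config.noise_peak_rate * len(own)))
            noise_w = min(config.peak_width, config.peak_spacing - 2)
            for _ in range(n_noise):
                chrom, g0, g1 = gaps[rng.integers(0, len(gaps))]
                if g1 - g0 <= noise_w:
                    continue
                s = int(rng.integers(g0, g1 - noise_w))
                out.append(GenomicInterval(chrom, s, s + noise_w, "noise"))
            out.sort(key=lambda iv: (iv.chrom, iv.start))
            calls[(tissue, rep)] = out
    return calls


def _gap_table(config: SimulationConfig, peaks: list[TruePeak]):
    """Inter-peak gaps (chrom, start, end) covering all non-peak sequence."""
    gaps = []
    by_chrom: dict[str, list[TruePeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in _chrom_names(config):
        pos = 0
        for p in sorted(by_chrom.get(chrom, []), key=lambda x: x.start):
            if p.start > pos:
                gaps.append((chrom, pos, p.start))
            pos = p.end
        if pos < config.genome_size:
            gaps.append((chrom, pos, config.genome_size))
    return gaps


def _draw_counts(
    config: SimulationConfig,
    weights: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """One multinomial draw per sample over (background, peaks...)."""
    n_peaks = weights.shape[0]
    counts = np.zeros((n_peaks, len(config.sample_ids)), dtype=np.int64)
    background = np.zeros(len(config.sample_ids), dtype=np.int64)
    bg = config.background_fraction
    for j, sample in enumerate(config.sample_ids):
        tissue = sample.rsplit("_rep", 1)[0]
        w = weights[tissue].to_numpy()
        probs = np.concatenate(([bg], (1.0 - bg) * w / w.sum()))
        draw = rng.multinomial(config.fragments_per_sample, probs)
        background[j] = draw[0]
        counts[:, j] = draw[1:]
    return (
        pd.DataFrame(counts, index=weights.index, columns=config.sample_ids),
        pd.Series(background, index=config.sample_ids, name="background"),
    )


def _synthesize_genome(
    config: SimulationConfig,
    peaks: list[TruePeak],
    pwms: list[tuple[str, np.ndarray, str]],
    rng: np.random.Generator,
) -> tuple[GenomeSequence, list[dict]]:
    seqs = {
        c: rng.integers(0, 4, config.genome_size).astype(np.uint8)
        for c in _chrom_names(config)
    }
    placements: list[dict] = []
    by_tissue = {t: (mid, probs) for mid, probs, t in pwms}
    L = config.motif_length
    margin = L + 4
    for p in peaks:
        if p.label == SHARED or p.label not in by_tissue:
            continue
        if rng.random() >= config.motif_planting_rate:
            continue
        motif_id, probs = by_tissue[p.label]
        center = (p.start + p.end) // 2
        span = max(1, (p.end - p.start) // 2 - margin)
        offset = center - L // 2 + int(rng.integers(-span, span + 1))
        offset = min(max(offset, p.start), p.end - L)
        instance = np.array(
            [rng.choice(4, p=probs[i]) for i in range(L)], dtype=np.uint8
        )
        seqs[p.chrom][offset : offset + L] = instance
        placements.append(
            {"peak_id": p.peak_id, "motif_id": motif_id, "position": int(offset)}
        )
    genome = GenomeSequence(
        {c: _BASES[a].tobytes().decode("ascii") for c, a in seqs.items()}
    )
    return genome, placements


def _materialize_fragments(
    config: SimulationConfig,
    peaks: list[TruePeak],
    counts: pd.DataFrame,
    background: pd.Series,
    rng: np.random.Generator,
    outdir: Path,
) -> None:
    """Write per-sample fragment BEDs matching the drawn counts exactly."""
    gaps = _gap_table(config, peaks)
    fl = config.fragment_length
    usable = np.asarray([max(0, g1 - g0 - fl) for _, g0, g1 in gaps], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(usable)))
    total_usable = int(cum[-1])
    for sample in config.sample_ids:
        path = outdir / f"{sample}.fragments.bed"
        with open(path, "w") as fh:
            col = counts[sample]
            for p in peaks:
                c = int(col[p.peak_id])
                if c == 0:
                    continue
                starts = rng.integers(p.start, p.end - fl + 1, size=c)
                starts.sort()
                for s in starts:
                    fh.write(f"{p.chrom}\t{s}\t{s + fl}\n")
            n_bg = int(background[sample])
            if n_bg:
                if total_usable <= 0:
                    raise ConfigurationError("no gap space for background fragments")
                u = np.sort(rng.integers(0, total_usable, size=n_bg))
                gi = np.searchsorted(cum, u, side="right") - 1
                for k in range(n_bg):
                    chrom, g0, _ = gaps[gi[k]]
                    s = g0 + int(u[k] - cum[gi[k]])
                    fh.write(f"{chrom}\t{s}\t{s + fl}\n")


def simulate_atlas(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    include_genome: bool = True,
) -> SimulationResult:
    """Generate one synthetic atlas dataset.

    With ``outdir`` set, writes genome.fa, tss.bed, per-sample peak and
    fragment BEDs, a sample sheet, the config, the planted PWMs (JASPAR
    text), and a truth manifest. Without it, returns in-memory objects
    only (fragment coordinates are never materialized). Byte-identical
    outputs for identical config + seed.
    """
    root = np.random.SeedSequence(config.seed)
    s_layout, s_genome, s_calls, s_counts, s_frags = root.spawn(5)
    peaks = _layout(config, np.random.default_rng(s_layout))
    weights = _weights(config, peaks)
    tss = _tss_for(peaks)
    calls = _replicate_calls(config, peaks, np.random.default_rng(s_calls))
    counts, background = _draw_counts(config, weights, np.random.default_rng(s_counts))

    pwms = config.planted_motifs
    consensi: dict[str, str] = {}
    targets: dict[str, str] = {}
    if pwms is None:
        pwms, consensi, targets = _default_motifs(
            config, np.random.default_rng(s_genome)
        )
    else:
        for motif_id, probs, tissue in pwms:
            idx = np.argmax(probs, axis=1)
            consensi[motif_id] = "".join("ACGT"[b] for b in idx)
            targets[motif_id] = tissue

    genome = None
    placements: list[dict] = []
    if include_genome:
        genome, placements = _synthesize_genome(
            config, peaks, pwms, np.random.default_rng(s_genome.spawn(1)[0])
        )

    truth = SyntheticTruth(peaks, weights, placements, consensi, targets)
    sheet = pd.DataFrame(
        {
            "sample_id": config.sample_ids,
            "tissue": [s.rsplit("_rep", 1)[0] for s in config.sample_ids],
            "replicate": [int(s.rsplit("_rep", 1)[1]) for s in config.sample_ids],
            "sex": [
                "female" if int(s.rsplit("_rep", 1)[1]) % 2 else "male"
                for s in config.sample_ids
            ],
            "peaks": [f"{s}.peaks.bed" for s in config.sample_ids],
            "fragments": [f"{s}.fragments.bed" for s in config.sample_ids],
        }
    )
    result = SimulationResult(
        config=config,
        truth=truth,
        counts=counts,
        background_counts=background,
        replicate_peaks=calls,
        tss=tss,
        genome=genome,
        sample_sheet=sheet,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if genome is not None:
            genome.to_fasta(outdir / "genome.fa")
        tss.to_bed(outdir / "tss.bed")
        for (tissue, rep), ivs in calls.items():
            write_bed(ivs, outdir / f"{tissue}_rep{rep}.peaks.bed")
        _materialize_fragments(
            config, peaks, counts, background,
            np.random.default_rng(s_frags), outdir,
        )
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
        write_jaspar_pwms(pwms, outdir / "motifs.jaspar")
        truth.to_json(outdir / "truth.json")
    return result


def write_jaspar_pwms(
    pwms: list[tuple[str, np.ndarray, str]],
    path: str | Path,
    scale: int = 10_000,
) -> None:
    """Write planted PWMs as JASPAR-style plain-text count matrices.

    The count scale is large so that re-reading with the default matrix
    pseudocount reproduces the planted probabilities to ~1e-4; at a
    coarse scale the pseudocount would soften a near-point-mass motif
    enough to change which windows reach the score threshold.
    """
    with open(path, "w") as fh:
        for motif_id, probs, _tissue in pwms:
            fh.write(f">{motif_id} {motif_id}\n")
            counts = np.rint(probs * scale).astype(int)
            for row, base in enumerate("ACGT"):
                vals = " ".join(str(v) for v in counts[:, row])
                fh.write(f"{base} [ {vals} ]\n")


def expected_count_profile(
    truth: SyntheticTruth,
    peak_id: str,
    config: SimulationConfig,
) -> pd.Series:
    """Closed-form per-tissue expected fragment count for one true peak.

    E[count in a sample of tissue t] =
    fragments_per_sample x (1 - background_fraction) x w(p,t) / sum_p w(p,t).
    The sampler's empirical means converge to these values.
    """
    if peak_id not in truth.weights.index:
        raise KeyError(f"unknown peak id {peak_id!r}")
    w = truth.weights.loc[peak_id]
    totals = truth.weights.sum(axis=0)
    return (
        config.fragments_per_sample
        * (1.0 - config.background_fraction)
        * w
        / totals
    )


def counts_on_atlas(
    result: SimulationResult,
    atlas_peaks: list[GenomicInterval],
) -> tuple[pd.DataFrame, pd.Series]:
    """Project true-peak counts onto atlas peaks without fragment files.

    Each atlas peak receives the summed counts of the true peaks it
    overlaps (atlas peaks derived from replicate-filtered merged calls
    overlap at most one true peak at default spacing); atlas peaks born
    from noise calls receive zero. Returns (counts, library_sizes) where
    library sizes include background fragments, mirroring the file route.
    """
    n = len(atlas_peaks)
    mat = np.zeros((n, result.counts.shape[1]), dtype=np.int64)
    true_ivs = [p.interval for p in result.truth.peaks]
    # map each true peak to the atlas peaks it overlaps
    starts: dict[str, np.ndarray] = {}
    order: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(atlas_peaks):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs = sorted(idxs, key=lambda i: atlas_peaks[i].start)
        starts[chrom] = np.asarray([atlas_peaks[i].start for i in idxs])
        order[chrom] = np.asarray(idxs)
    ends = {
        c: np.asarray([atlas_peaks[i].end for i in order[c]]) for c in order
    }
    raw = result.counts.to_numpy()
    for k, iv in enumerate(true_ivs):
        if iv.chrom not in starts:
            continue
        lo = np.searchsorted(ends[iv.chrom], iv.start, side="right")
        hi = np.searchsorted(starts[iv.chrom], iv.end, side="left")
        for j in order[iv.chrom][lo:hi]:
            mat[j] += raw[k]
    names = [iv.name or f"peak_{i:06d}" for i, iv in enumerate(atlas_peaks)]
    counts = pd.DataFrame(mat, index=names, columns=result.counts.columns)
    return counts, result.library_sizes
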