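"""Known-motif enrichment in tissue-specific peaks.

A transparent stand-in for a full motif-enrichment suite: position weight
matrices (JASPAR-style counts) are scanned over peak sequences with a
log-odds score against a background base composition, a sequence is
motif-positive when any window on either strand reaches the score
threshold, and per-(motif, tissue) enrichment of positives among a
tissue's specific peaks versus background peaks is tested with a
one-sided hypergeometric tail. This is NOT a re-implementation of HOMER:
there is no GC-matched background selection, ZOOPS scoring, or de novo
discovery — the statistic here is exact and fully specified so its
behavior is testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import hypergeom

UNIFORM_BACKGROUND = np.full(4, 0.25)

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = N / anything else
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position weight matrix over A, C, G, T.

    ``probs`` has shape (L, 4) with rows summing to 1. The hit threshold
    is a fraction of the maximum achievable log-odds score versus the
    background (default 60%).
    """

    motif_id: str
    probs: np.ndarray
    pseudocount: float = 0.0
    threshold_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        threshold_fraction: float = 0.6,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(motif_id, probs, pseudocount, threshold_fraction)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self, background: np.ndarray = UNIFORM_BACKGROUND) -> np.ndarray:
        """(L, 5) log2(p/bg) matrix; column 4 (N) is -inf so N windows never hit."""
        bg = np.asarray(background, dtype=float)
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / bg)
        return np.hstack([lo, np.full((len(self), 1), -np.inf)])

    def max_score(self, background: np.ndarray = UNIFORM_BACKGROUND) -> float:
        return float(self.log_odds(background)[:, :4].max(axis=1).sum())

    def threshold(self, background: np.ndarray = UNIFORM_BACKGROUND) -> float:
        return self.threshold_fraction * self.max_score(background)


def read_jaspar(
    path: str | Path,
    pseudocount: float = 0.5,
    threshold_fraction: float = 0.6,
) -> list[PWM]:
    """Read JASPAR-format plain-text count matrices into PWMs."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in records:
        counts = np.array(
            [[m.counts[b][i] for b in "ACGT"] for i in range(m.length)],
            dtype=float,
        )
        name = m.matrix_id or m.name
        pwms.append(
            PWM.from_counts(name, counts, pseudocount, threshold_fraction)
        )
    return pwms


def _window_scores(codes: np.ndarray, lo_matrix: np.ndarray) -> np.ndarray:
    """Score every window of ``codes`` (ints in 0..4) against (L, 5) log-odds."""
    L = lo_matrix.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo_matrix[np.arange(L), windows].sum(axis=1)


def scan_sequence(
    seq: str,
    pwm: PWM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    threshold: float | None = None,
) -> list[tuple[int, str]]:
    """All motif hits in one sequence, both strands, deduplicated by position.

    A window starting at 0-based position i on the plus strand (or whose
    reverse complement matches on the minus strand) is a hit when its
    summed log2(P(window|PWM)/P(window|background)) reaches the threshold
    (default: the PWM's threshold_fraction of its maximum score). Windows
    containing N never hit. Returns (position, strand) pairs sorted by
    position; a position hit on both strands is reported once, as '+'.
    """
    if threshold is None:
        threshold = pwm.threshold(background)
    lo = pwm.log_odds(background)
    L = len(pwm)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    plus = _window_scores(codes, lo)
    rc_codes = _CODE[
        np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)
    ]
    minus_rc = _window_scores(rc_codes, lo)
    hits: dict[int, str] = {}
    n = len(plus)
    for i in np.flatnonzero(minus_rc >= threshold):
        hits[n - 1 - int(i)] = "-"  # rc window i starts at len-L-i in seq
    for i in np.flatnonzero(plus >= threshold):
        hits[int(i)] = "+"
    return sorted(hits.items())


def sequence_has_hit(
    seq: str,
    pwm: PWM,
    background: np.ndarray = UNIFORM_BACKGROUND,
    threshold: float | None = None,
) -> bool:
    return len(scan_sequence(seq, pwm, background, threshold)) > 0


@dataclass
class MotifEnrichmentMatrix:
    """Motifs x tissues enrichment P-values with the underlying counts."""

    pvalues: pd.DataFrame  # motifs x tissues; NaN sentinel for empty columns
    fg_hits: pd.DataFrame
    fg_size: pd.Series  # per tissue
    bg_hits: pd.Series  # per motif
    bg_size: int

    @property
    def neg_log10(self) -> pd.DataFrame:
        return -np.log10(self.pvalues) + 0.0  # +0.0 normalizes -log10(1) to 0.0


def motif_enrichment(
    foreground: Mapping[str, Sequence[str]],
    background: Sequence[str],
    pwms: Sequence[PWM],
    background_freqs: np.ndarray = UNIFORM_BACKGROUND,
) -> MotifEnrichmentMatrix:
    """Hypergeometric motif enrichment of specific-peak sequences per tissue.

    A sequence is motif-positive when it carries >= 1 hit. For each
    (motif, tissue), the one-sided P is the hypergeometric upper tail of
    drawing as many or more positive sequences in the foreground, from the
    pooled foreground + shared background. Tissues with an empty
    foreground get a NaN column and a warning. P-values are reported raw
    (no multiple-testing correction); order of sequences never matters.
    """
    if not foreground or not len(background):
        raise ValueError("foreground and background must be non-empty")
    tissues = sorted(foreground)
    motif_ids = [p.motif_id for p in pwms]
    pvals = pd.DataFrame(np.nan, index=motif_ids, columns=tissues)
    fg_hits = pd.DataFrame(0, index=motif_ids, columns=tissues)
    fg_size = pd.Series({t: len(foreground[t]) for t in tissues})
    bg_hits = pd.Series(0, index=motif_ids, dtype=int)
    for t in tissues:
        if fg_size[t] == 0:
            warnings.warn(f"empty foreground for tissue {t!r}", stacklevel=2)
    for pwm in pwms:
        thr = pwm.threshold(background_freqs)
        n_bg = sum(
            sequence_has_hit(s, pwm, background_freqs, thr) for s in background
        )
        bg_hits[pwm.motif_id] = n_bg
        for t in tissues:
            if fg_size[t] == 0:
                continue
            k = sum(
                sequence_has_hit(s, pwm, background_freqs, thr)
                for s in foreground[t]
            )
            fg_hits.loc[pwm.motif_id, t] = k
            M = int(fg_size[t]) + len(background)  # pool size
            K = k + n_bg  # positives in pool
            pvals.loc[pwm.motif_id, t] = float(
                hypergeom.sf(k - 1, M, K, int(fg_size[t]))
            )
    return MotifEnrichmentMatrix(
        pvals, fg_hits, fg_size, bg_hits, len(background)
    )


def top_motifs(
    matrix: MotifEnrichmentMatrix,
    k: int = 15,
) -> dict[str, list[str]]:
    """Per-tissue motifs ranked by ascending P (ties by motif id), first k."""
    if k <= 0:
        raise ValueError("k must be positive")
    out: dict[str, list[str]] = {}
    for t in matrix.pvalues.columns:
        col = matrix.pvalues[t].dropna()
        ranked = sorted(col.items(), key=lambda kv: (kv[1], kv[0]))
        out[t] = [m for m, _ in ranked[:k]]
    return out


def select_background(
    candidates: Sequence[str],
    foreground_size: int,
    multiple: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Subsample background sequences to ``multiple`` x foreground size."""
    target = int(round(multiple * foreground_size))
    if target >= len(candidates):
        return list(candidates)
    rng = rng or np.random.default_rng(0)
    idx = rng.choice(len(candidates), size=target, replace=False)
    return [candidates[i] for i in sorted(idx)]
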