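"""Shannon-entropy tissue-specificity index for chromatin accessibility.

For each standard peak, let E_i be its RPM in tissue i (replicate mean by
default) and R_i = E_i / sum(E) its relative accessibility. The entropy
score

    H = - sum_i R_i * log2(R_i)        (0 * log2 0 := 0)

ranges over [0, log2 N] for N tissues: H = 0 for a peak open in exactly one
tissue, H = log2 N for a uniformly accessible peak. Peaks with H strictly
below a threshold (3 bits for body organs, 2 bits for brain regions in the
reference design) are called tissue-specific and assigned to the tissue of
maximal R_i. Peaks with sum(E) = 0 cannot be scored and are excluded from
calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_AGGREGATORS = {"mean", "sum", "max"}


def tissue_profile(
    rpm: pd.DataFrame,
    sample_to_tissue: Mapping[str, str],
    agg: str = "mean",
) -> pd.DataFrame:
    """Collapse a peak x sample RPM matrix to peak x tissue E_i values.

    Every sample column must map to exactly one tissue; replicates of a
    tissue are combined by ``agg`` (mean by default; sum and max are the
    alternatives). Tissue columns come out in sorted name order.
    """
    if agg not in _AGGREGATORS:
        raise ValueError(f"agg must be one of {sorted(_AGGREGATORS)}")
    unmapped = [s for s in rpm.columns if s not in sample_to_tissue]
    if unmapped:
        raise ValueError(f"samples without a tissue mapping: {unmapped}")
    groups = pd.Series({s: sample_to_tissue[s] for s in rpm.columns})
    mapped_tissues = set(groups)
    orphan = [t for t in set(sample_to_tissue.values()) - mapped_tissues]
    if orphan:
        raise ValueError(f"tissue(s) with zero samples: {sorted(orphan)}")
    ei = rpm.T.groupby(groups).agg(agg).T
    return ei[sorted(ei.columns)]


def entropy_score(ei: Sequence[float] | np.ndarray) -> tuple[np.ndarray, float]:
    """R_i vector and entropy H (bits) for one peak's per-tissue profile.

    Requires E_i >= 0; returns (R_i, nan) when sum(E) = 0.
    """
    e = np.asarray(ei, dtype=float)
    if (e < 0).any():
        raise ValueError("E_i values must be non-negative")
    total = e.sum()
    if total == 0:
        return np.full_like(e, np.nan), float("nan")
    r = e / total
    nz = r[r > 0]
    return r, float(-(nz * np.log2(nz)).sum())


def entropy_scores(ei: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Vectorized :func:`entropy_score` over a peak x tissue matrix."""
    e = ei.to_numpy(dtype=float)
    if (e < 0).any():
        raise ValueError("E_i values must be non-negative")
    totals = e.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = e / totals[:, None]
        plogp = np.where(r > 0, r * np.log2(np.where(r > 0, r, 1.0)), 0.0)
    h = -plogp.sum(axis=1)
    h[totals == 0] = np.nan
    ri = pd.DataFrame(r, index=ei.index, columns=ei.columns)
    return ri, pd.Series(h, index=ei.index, name="H")


@dataclass
class SpecificityResult:
    """Per-peak entropy scores and specificity calls for one tissue set."""

    ri: pd.DataFrame  # peaks x tissues relative accessibility
    h: pd.Series  # entropy, bits; NaN where sum(E) = 0
    is_specific: pd.Series  # strict H < threshold; False where H is NaN
    assigned_tissue: pd.Series  # argmax R_i for specific peaks, else None
    n_tissues: int
    threshold: float

    @property
    def undefined(self) -> pd.Series:
        """Peaks excluded from calling because sum(E) = 0."""
        return self.h.isna()

    def specific_peaks(self, tissue: str) -> list[str]:
        mask = self.is_specific & (self.assigned_tissue == tissue)
        return list(self.h.index[mask])

    def table(self) -> pd.DataFrame:
        out = self.ri.copy()
        out.columns = [f"Ri_{t}" for t in out.columns]
        out["H"] = self.h
        out["is_specific"] = self.is_specific
        out["assigned_tissue"] = self.assigned_tissue
        out.index.name = "peak_id"
        return out


def call_specific_peaks(
    ei: pd.DataFrame,
    threshold: float,
) -> SpecificityResult:
    """Call tissue-specific peaks at a strict entropy threshold (bits).

    ``is_specific`` iff H < threshold (a peak exactly at the threshold is
    not specific). Specific peaks are assigned to the tissue of maximal
    R_i; ties resolve to the first tissue in sorted name order. Peaks with
    sum(E) = 0 are flagged undefined and never called.
    """
    n = ei.shape[1]
    if not 0 < threshold < np.log2(n):
        raise ValueError(
            f"threshold must lie in (0, log2 N) = (0, {np.log2(n):.3f})"
        )
    ei = ei[sorted(ei.columns)]
    ri, h = entropy_scores(ei)
    is_specific = (h < threshold).fillna(False)
    assigned = pd.Series([None] * len(h), index=h.index, dtype=object)
    if is_specific.any():
        # idxmax returns the first maximal column; columns are sorted
        assigned[is_specific] = ri.loc[is_specific].idxmax(axis=1)
    return SpecificityResult(ri, h, is_specific, assigned, n, threshold)


@dataclass
class EntropyReport:
    """Histogram of entropy scores with a bimodality (valley) summary."""

    counts: np.ndarray
    edges: np.ndarray
    n_peaks: int
    n_undefined: int
    valley: float | None  # bin-center of the deepest minimum between modes

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def entropy_distribution_report(
    h: pd.Series | np.ndarray,
    bins: int = 50,
) -> EntropyReport:
    """Summarize the entropy-score distribution to document a threshold.

    Reports the histogram and, when the distribution is bimodal, the bin
    center of the deepest valley between the two tallest local maxima.
    Never applies a threshold itself. Raises when no peak has a defined
    score.
    """
    h = np.asarray(pd.Series(h), dtype=float)
    n_undefined = int(np.isnan(h).sum())
    h = h[~np.isnan(h)]
    if len(h) == 0:
        raise ValueError("no peaks with a defined entropy score")
    counts, edges = np.histogram(h, bins=bins)
    valley = None
    maxima = [
        i
        for i in range(len(counts))
        if counts[i] > 0
        and (i == 0 or counts[i] >= counts[i - 1])
        and (i == len(counts) - 1 or counts[i] > counts[i + 1])
    ]
    if len(maxima) >= 2:
        top_two = sorted(
            sorted(maxima, key=lambda i: counts[i], reverse=True)[:2]
        )
        lo, hi = top_two
        if hi - lo > 1:
            between = np.arange(lo + 1, hi)
            vi = between[np.argmin(counts[lo + 1 : hi])]
            centers = (edges[:-1] + edges[1:]) / 2.0
            valley = float(centers[vi])
    return EntropyReport(counts, edges, int(len(h)), n_undefined, valley)
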