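"""Zinger motif peak analyses.

Zinger motif peaks are peaks that carry a high-scoring zinger motif
(relative score > 85) in the zinger's enrichment zone while lacking the
ChIPped TF's own motif. This module provides the pairwise zinger
co-occurrence test (2x2 Fisher with the signed 1-p heatmap encoding),
agreement of zinger motif peaks with ChIP-seq performed for the zinger TF
itself (peakMax within 100 bp), and the one-tailed rank-sum comparison of
peak scores between peak groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_P = 0.001
AGREEMENT_WINDOW_BP = 100


@dataclass
class CooccurrenceCell:
    """Fisher test of joint zinger presence among zinger motif peaks."""

    zinger_a: str
    zinger_b: str
    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    fisher_p: float
    log_odds: float
    heatmap_value: float
    degenerate: bool = False


def cooccurrence_test(
    presence_a,
    presence_b,
    zinger_a: str = "a",
    zinger_b: str = "b",
    alpha: float = SIGNIFICANCE_P,
) -> CooccurrenceCell:
    """Two-sided Fisher exact test of co-occurrence of two zinger motifs.

    ``presence_a``/``presence_b`` are boolean vectors over the zinger motif
    peaks of one dataset (presence = motif score >= 85 for that zinger). The
    heatmap encoding is 1-p for significant positive association, -(1-p) for
    significant negative association, 0 otherwise. Log odds use the Haldane
    0.5 correction when any cell is empty. A zinger absent from (or present
    in) every peak makes the table degenerate: value 0, flagged.
    """
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("presence vectors must be equal-length and non-empty")
    both = int(np.sum(a & b))
    a_only = int(np.sum(a & ~b))
    b_only = int(np.sum(~a & b))
    neither = int(np.sum(~a & ~b))
    table = np.array([[both, a_only], [b_only, neither]])
    degenerate = (a.all() or (~a).all()) or (b.all() or (~b).all())
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table + 0.5 if (table == 0).any() else table.astype(float)
    log_odds = math.log((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    if degenerate or p >= alpha or log_odds == 0:
        value = 0.0
    else:
        value = (1.0 - p) if log_odds > 0 else -(1.0 - p)
    return CooccurrenceCell(zinger_a, zinger_b, table, float(p), log_odds, value, degenerate)


def cooccurrence_matrix(flags: pd.DataFrame, alpha: float = SIGNIFICANCE_P) -> pd.DataFrame:
    """Pairwise heatmap values for the zinger flag columns of one dataset."""
    names = list(flags.columns)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            cell = cooccurrence_test(flags[na], flags[nb], na, nb, alpha)
            mat.loc[na, nb] = cell.heatmap_value
            mat.loc[nb, na] = cell.heatmap_value
    return mat


def _nearest_distances(query: pd.DataFrame, ref: pd.DataFrame) -> np.ndarray:
    """Distance from each query peakMax to the nearest reference peakMax."""
    out = np.full(len(query), np.inf)
    if len(ref) == 0:
        return out
    for chrom, sub in query.groupby("chrom", sort=False):
        r = np.sort(ref.loc[ref["chrom"] == chrom, "peakmax"].to_numpy(float))
        q = sub["peakmax"].to_numpy(float)
        here = np.full(len(q), np.inf)
        if r.size:
            j = np.searchsorted(r, q)
            left = np.where(j > 0, np.abs(q - r[np.clip(j - 1, 0, r.size - 1)]), np.inf)
            right = np.where(j < r.size, np.abs(r[np.clip(j, 0, r.size - 1)] - q), np.inf)
            here = np.minimum(left, right)
        out[query.index.get_indexer(sub.index)] = here
    return out


@dataclass
class OverlapResult:
    """Agreement of zinger motif peaks with the zinger TF's own ChIP-seq."""

    frac_zinger: float
    frac_distal: float
    n_zinger: int
    n_distal: int
    rank_sum_p: float  # zinger group nearer, one-tailed


def overlap_with_zinger_chip(
    zinger_peaks: pd.DataFrame,
    distal_zinger_peaks: pd.DataFrame,
    zinger_tf_peaks: pd.DataFrame,
    window_bp: int = AGREEMENT_WINDOW_BP,
) -> OverlapResult:
    """Fraction of peaks whose peakMax is within 100 bp of a zinger-TF peakMax.

    All frames need columns [chrom, peakmax]. The distal-zinger group (same
    motifs, outside the enrichment zone, matched on score range) serves as
    the control; the one-tailed rank-sum test asks whether the zinger motif
    peaks lie nearer to the zinger TF's peaks than the control does. With an
    empty zinger-TF set both fractions are 0 and the test undefined (NaN).
    """
    if len(zinger_tf_peaks) == 0:
        return OverlapResult(0.0, 0.0, len(zinger_peaks), len(distal_zinger_peaks), float("nan"))
    dz = _nearest_distances(zinger_peaks, zinger_tf_peaks)
    dd = _nearest_distances(distal_zinger_peaks, zinger_tf_peaks)
    frac_z = float(np.mean(dz <= window_bp)) if dz.size else float("nan")
    frac_d = float(np.mean(dd <= window_bp)) if dd.size else float("nan")
    p = compare_peak_scores(dz[np.isfinite(dz)], dd[np.isfinite(dd)]) if dz.size and dd.size else float("nan")
    return OverlapResult(frac_z, frac_d, len(zinger_peaks), len(distal_zinger_peaks), p)


def compare_peak_scores(group_a, group_b, exact_max_n: int = 8) -> float:
    """One-tailed rank-sum p that group_a values are smaller than group_b.

    Exact enumeration is used when both groups have at most ``exact_max_n``
    untied observations; otherwise the normal approximation with continuity
    correction. Inputs that are entirely tied return the conventional 0.5.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.5
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if max(a.size, b.size) <= exact_max_n and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return float(res.pvalue)
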