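"""TFBS landscapes and heuristic enrichment zones.

A *landscape* records, for each fixed-length peak region (1001 bp, peakMax at
the 501st bp = index 500), the single top-scoring motif window above a floor
score, positioned by its signed midpoint distance to the peakMax. Motif
density rises sharply near the peakMax for genuinely bound profiles while
staying flat in the distal flanks (roughly 175-500 bp out), which reflect the
background rate of motif prediction.

The *enrichment zone* is derived heuristically from the landscape: distance
boundaries where the 5 bp binned motif density (3-bin moving average) exceeds
the distal baseline, and the smallest integer score threshold at which the
per-bp motif frequency inside the boundaries is at least 20% above the
flanks. When the heuristics find nothing the reported study-wide averages are
used as defaults: boundaries of +/-90 bp and a relative-score threshold
of 82.

Composition estimates correct zone counts with an equal-width distal control
zone (half 5', half 3', at least 50 bp clear of the enrichment zone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import motifs as _motifs

REGION_LENGTH = 1001
CENTER_INDEX = (REGION_LENGTH - 1) // 2  # the 501st bp
DEFAULT_BOUNDARY_BP = 90
DEFAULT_SCORE_THRESHOLD = 82.0
DISTAL_RANGE = (175, 500)
BIN_BP = 5
N_BINS = (REGION_LENGTH - 1) // BIN_BP + 1  # 201 bins over [-500, +500]


@dataclass
class EnrichmentZone:
    """Distance boundaries plus motif-score threshold around the peakMax."""

    left_bp: int
    right_bp: int
    score_threshold: float
    boundaries_found: bool = True
    threshold_found: bool = True

    def __post_init__(self) -> None:
        if not (self.left_bp < 0 < self.right_bp):
            raise ValueError("zone must straddle the peakMax (left < 0 < right)")

    @property
    def width(self) -> int:
        return self.right_bp - self.left_bp

    def contains(self, signed_distance, rel_score) -> np.ndarray:
        d = np.asarray(signed_distance, dtype=float)
        s = np.asarray(rel_score, dtype=float)
        return (d >= self.left_bp) & (d <= self.right_bp) & (s >= self.score_threshold)

    def distal_segments(self, clearance_bp: int = 50, limit: int = 500):
        """Equal-total-width control segments flanking the zone.

        Half the zone width on the 5' side, half on the 3' side, each
        starting ``clearance_bp`` beyond the zone edge and clipped at the
        region edge.
        """
        half = self.width / 2.0
        left_seg = (max(-limit, self.left_bp - clearance_bp - half), self.left_bp - clearance_bp)
        right_seg = (self.right_bp + clearance_bp, min(limit, self.right_bp + clearance_bp + half))
        return left_seg, right_seg

    def in_distal(self, signed_distance, rel_score, clearance_bp: int = 50) -> np.ndarray:
        (l0, l1), (r0, r1) = self.distal_segments(clearance_bp)
        d = np.asarray(signed_distance, dtype=float)
        s = np.asarray(rel_score, dtype=float)
        in_seg = ((d >= l0) & (d < l1)) | ((d > r0) & (d <= r1))
        return in_seg & (s >= self.score_threshold)


@dataclass
class CompositionEstimate:
    """Raw and background-corrected dataset composition fractions."""

    n_peaks: int
    raw_chipped: float
    raw_zinger: float
    raw_unidentified: float
    corrected_chipped: float
    corrected_zinger: float
    per_zinger_corrected: dict

    def raw_fractions(self) -> tuple[float, float, float]:
        return (self.raw_chipped, self.raw_zinger, self.raw_unidentified)


# ---------------------------------------------------------------------------
# Landscape construction
# ---------------------------------------------------------------------------


def top_hits(pwm: _motifs.PWM, matrix: np.ndarray, floor_score: float = 70.0) -> pd.DataFrame:
    """Per-row top motif window of an encoded sequence matrix.

    The top hit maximizes the relative score; ties are broken by smaller
    absolute distance to the centre, then smaller start, then + strand.
    Rows without any window at or above ``floor_score`` get ``has_motif``
    False and NaN hit fields.
    """
    n_seqs, seq_len = matrix.shape
    center = (seq_len - 1) // 2
    rel = _motifs.batch_window_scores(pwm, matrix)
    out = {
        "has_motif": np.zeros(n_seqs, dtype=bool),
        "signed_distance": np.full(n_seqs, np.nan),
        "rel_score": np.full(n_seqs, np.nan),
        "strand": np.array([""] * n_seqs, dtype=object),
        "start_offset": np.full(n_seqs, np.nan),
    }
    if rel.shape[1] == 0:
        return pd.DataFrame(out)
    n_win = rel.shape[1]
    starts = np.arange(n_win)
    mid = starts + pwm.width // 2
    absdist = np.abs(mid - center)
    # tie-break key, exact for equal scores: |dist| then start then strand
    tie = absdist[:, None] * 4.0 + starts[:, None] * 2e-6 + np.array([0.0, 1.0])[None, :] * 1e-9
    for r in range(n_seqs):
        best = rel[r].max()
        if best < floor_score:
            continue
        cand = np.argwhere(rel[r] == best)
        k = np.argmin(tie[cand[:, 0], cand[:, 1]])
        w, s = cand[k]
        out["has_motif"][r] = True
        out["signed_distance"][r] = mid[w] - center
        out["rel_score"][r] = rel[r, w, s]
        out["strand"][r] = "+-"[s]
        out["start_offset"][r] = w
    return pd.DataFrame(out)


def build_landscape(
    sequences: dict[str, str] | tuple[list[str], np.ndarray],
    pwm: _motifs.PWM,
    floor_score: float = 70.0,
) -> pd.DataFrame:
    """Top motif hit per 1001 bp peak region, relative to the peakMax.

    ``sequences`` is either a mapping peak_id -> sequence string or a pair
    ``(peak_ids, encoded_matrix)``. All regions must be exactly 1001 bp.
    Returns a DataFrame indexed by peak_id with columns has_motif,
    signed_distance, rel_score, strand, start_offset.
    """
    if isinstance(sequences, dict):
        ids = list(sequences)
        if any(len(s) != REGION_LENGTH for s in sequences.values()):
            raise ValueError(f"all landscape regions must be {REGION_LENGTH} bp")
        matrix = np.stack([_motifs.encode_sequence(sequences[i]) for i in ids])
    else:
        ids, matrix = sequences
        if matrix.shape[1] != REGION_LENGTH:
            raise ValueError(f"all landscape regions must be {REGION_LENGTH} bp")
    df = top_hits(pwm, matrix, floor_score)
    df.index = pd.Index(ids, name="peak_id")
    return df


def positional_density(landscape: pd.DataFrame, bin_bp: int = BIN_BP) -> pd.Series:
    """Counts of top hits per distance bin over [-500, +500].

    Bin i covers signed distances [5i - 500, 5i - 495); the returned Series
    is indexed by bin centre (bp). The bin counts sum to the number of peaks
    with a motif.
    """
    d = landscape.loc[landscape["has_motif"], "signed_distance"].to_numpy(float)
    half = (REGION_LENGTH - 1) // 2
    n_bins = (REGION_LENGTH - 1) // bin_bp + 1
    idx = ((d + half) // bin_bp).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    centers = np.arange(n_bins) * bin_bp - half + (bin_bp - 1) / 2.0
    return pd.Series(counts, index=centers, name="count")


def find_distance_boundaries(
    density: pd.Series,
    distal_range: tuple[int, int] = DISTAL_RANGE,
    default_bp: int = DEFAULT_BOUNDARY_BP,
    bin_bp: int = BIN_BP,
    noise_k: float = 1.0,
) -> tuple[int, int, bool]:
    """Heuristic enrichment boundaries from the binned motif density.

    Per side, the baseline is the mean bin count over the distal range; a
    3-bin moving average is scanned outward from the peakMax bin and the
    boundary set at the outer edge of the maximal contiguous run whose
    average exceeds the baseline. To keep sampling noise from extending runs
    over background fluctuations, "exceeds" means by more than ``noise_k``
    times the distal bins' standard deviation. Returns
    (left_bp, right_bp, found); when no run exists on either side the
    defaults +/-``default_bp`` are returned with found=False.
    """
    counts = density.to_numpy(float)
    centers = density.index.to_numpy(float)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    center_bin = int(np.argmin(np.abs(centers)))
    lo, hi = distal_range

    def side_boundary(direction: int) -> int | None:
        mask = (np.abs(centers) >= lo) & (np.abs(centers) <= hi)
        mask &= (centers * direction) > 0
        base_mean = counts[mask].mean() if mask.any() else 0.0
        base_sd = counts[mask].std(ddof=1) if mask.sum() > 1 else 0.0
        baseline = base_mean + noise_k * base_sd
        if smooth[center_bin] <= baseline:
            return None
        i = center_bin
        while 0 <= i + direction < len(counts) and smooth[i + direction] > baseline:
            i += direction
        # outer edge of the outermost qualifying bin
        if direction > 0:
            return int((i + 1) * bin_bp - (REGION_LENGTH - 1) // 2)
        return int(i * bin_bp - (REGION_LENGTH - 1) // 2)

    right = side_boundary(+1)
    left = side_boundary(-1)
    if left is None and right is None:
        return -default_bp, default_bp, False
    if left is None or left >= 0:
        left = -default_bp
    if right is None or right <= 0:
        right = default_bp
    return left, right, True


def find_score_threshold(
    landscape: pd.DataFrame,
    boundaries: tuple[int, int],
    ratio: float = 1.2,
    floor: int = 70,
    flank_range: tuple[int, int] = DISTAL_RANGE,
) -> int | None:
    """Smallest integer score threshold with >= 20% proximal excess.

    Scans s = floor..100 and returns the first s at which the per-bp
    frequency of top hits with rel_score >= s inside the boundaries is at
    least ``ratio`` times the per-bp frequency within the flanks (175-500 bp
    on both sides). Returns None when no s qualifies.
    """
    left, right = boundaries
    d = landscape.loc[landscape["has_motif"], "signed_distance"].to_numpy(float)
    s = landscape.loc[landscape["has_motif"], "rel_score"].to_numpy(float)
    zone_width = right - left
    lo, hi = flank_range
    flank_width = 2 * (hi - lo + 1)
    in_zone = (d >= left) & (d <= right)
    in_flank = (np.abs(d) >= lo) & (np.abs(d) <= hi)
    for thr in range(int(floor), 101):
        zc = int(np.count_nonzero(in_zone & (s >= thr)))
        fc = int(np.count_nonzero(in_flank & (s >= thr)))
        if zc == 0:
            continue
        zone_freq = zc / zone_width
        flank_freq = fc / flank_width
        if flank_freq == 0 or zone_freq >= ratio * flank_freq:
            return thr
    return None


def derive_zone(
    landscape: pd.DataFrame,
    ratio: float = 1.2,
    floor: int = 70,
    default_bp: int = DEFAULT_BOUNDARY_BP,
    default_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> EnrichmentZone:
    """Boundaries + score threshold from one landscape, with fall-backs."""
    density = positional_density(landscape)
    left, right, found = find_distance_boundaries(density, default_bp=default_bp)
    thr = find_score_threshold(landscape, (left, right), ratio=ratio, floor=floor)
    return EnrichmentZone(
        left_bp=left,
        right_bp=right,
        score_threshold=float(thr) if thr is not None else default_threshold,
        boundaries_found=found,
        threshold_found=thr is not None,
    )


# ---------------------------------------------------------------------------
# Background-corrected composition
# ---------------------------------------------------------------------------


def plot_landscape(
    landscape: pd.DataFrame,
    zone: EnrichmentZone | None = None,
    ax=None,
    bin_bp: int = BIN_BP,
):
    """Scatter of top-hit score vs signed distance, with the binned density.

    The classic TFBS-landscape layout: one point per peak (x = signed
    distance to the peakMax, y = relative motif score), a per-bin hit
    fraction line on a twin axis, and the enrichment zone drawn as a box
    when given. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sub = landscape.loc[landscape["has_motif"]]
    ax.plot(sub["signed_distance"], sub["rel_score"], ".", ms=2, alpha=0.3, color="0.2")
    ax.set_xlabel("distance of top motif to peakMax (bp)")
    ax.set_ylabel("relative motif score")
    ax.set_xlim(-(REGION_LENGTH - 1) // 2, (REGION_LENGTH - 1) // 2)
    density = positional_density(landscape, bin_bp)
    twin = ax.twinx()
    twin.plot(density.index, density.to_numpy() / max(1, len(landscape)), color="tab:red", lw=1)
    twin.set_ylabel("fraction of motifs per bin", color="tab:red")
    if zone is not None:
        ax.axvline(zone.left_bp, color="tab:blue", ls="--", lw=1)
        ax.axvline(zone.right_bp, color="tab:blue", ls="--", lw=1)
        ax.axhline(zone.score_threshold, color="tab:blue", ls=":", lw=1)
    return ax


def corrected_fraction(zone_count: int, distal_count: int, n_peaks: int) -> float:
    """Background-corrected motif-peak fraction.

    The distal control zone count estimates the false-positive expectation;
    it is subtracted from the enrichment-zone count (floored at zero) and
    divided by the dataset size.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    return max(0, zone_count - distal_count) / n_peaks


def zone_counts(landscape: pd.DataFrame, zone: EnrichmentZone) -> tuple[int, int]:
    """(enrichment-zone count, distal-zone count) of motif-bearing peaks."""
    has = landscape["has_motif"].to_numpy(bool)
    d = landscape["signed_distance"].to_numpy(float)
    s = landscape["rel_score"].to_numpy(float)
    in_zone = np.zeros_like(has)
    in_dist = np.zeros_like(has)
    in_zone[has] = zone.contains(d[has], s[has])
    in_dist[has] = zone.in_distal(d[has], s[has])
    return int(in_zone.sum()), int(in_dist.sum())


def composition(
    chipped_landscape: pd.DataFrame,
    chipped_zone: EnrichmentZone,
    zinger_landscapes: dict[str, tuple[pd.DataFrame, EnrichmentZone]],
) -> CompositionEstimate:
    """Classify a dataset's peaks as ChIPped-TF / zinger / unidentified.

    A peak is *chipped* when the ChIPped TF's top motif lies in its
    enrichment zone; *zinger* when it is not chipped but carries at least
    one zinger motif in that zinger's zone (peaks with both count as
    chipped, by the zinger-motif-peak definition); *unidentified* otherwise.
    Corrected fractions subtract the distal control count per profile; the
    four per-zinger corrected counts are summed before dividing by the
    dataset size.
    """
    n = len(chipped_landscape)
    if n == 0:
        raise ValueError("empty dataset")
    chipped_flag = np.zeros(n, dtype=bool)
    has = chipped_landscape["has_motif"].to_numpy(bool)
    chipped_flag[has] = chipped_zone.contains(
        chipped_landscape["signed_distance"].to_numpy(float)[has],
        chipped_landscape["rel_score"].to_numpy(float)[has],
    )
    zinger_any = np.zeros(n, dtype=bool)
    per_zinger_corr: dict[str, float] = {}
    for name, (lsc, zone) in zinger_landscapes.items():
        if len(lsc) != n:
            raise ValueError("zinger landscape size mismatch")
        zhas = lsc["has_motif"].to_numpy(bool)
        flag = np.zeros(n, dtype=bool)
        flag[zhas] = zone.contains(
            lsc["signed_distance"].to_numpy(float)[zhas],
            lsc["rel_score"].to_numpy(float)[zhas],
        )
        zinger_any |= flag
        sub = lsc.loc[~chipped_flag]
        zc, dc = zone_counts(sub, zone)
        per_zinger_corr[name] = max(0, zc - dc) / n
    zinger_flag = zinger_any & ~chipped_flag
    unid = ~(chipped_flag | zinger_flag)
    czc, cdc = zone_counts(chipped_landscape, chipped_zone)
    return CompositionEstimate(
        n_peaks=n,
        raw_chipped=float(chipped_flag.mean()),
        raw_zinger=float(zinger_flag.mean()),
        raw_unidentified=float(unid.mean()),
        corrected_chipped=corrected_fraction(czc, cdc, n),
        corrected_zinger=float(sum(per_zinger_corr.values())),
        per_zinger_corrected=per_zinger_corr,
    )


def _split_mask(n: int) -> np.ndarray:
    return np.arange(n) % 2 == 0


def crossfit_zones(landscape: pd.DataFrame, **derive_kwargs) -> tuple[EnrichmentZone, EnrichmentZone]:
    """Zones derived independently on the two parity halves of a dataset.

    Because the zone heuristics select the boundaries and score threshold
    that maximize apparent enrichment, counting motifs with a zone derived
    from the same peaks overstates the zone counts. Deriving the zone on one
    half and counting on the other removes that selection bias; the returned
    pair is (zone from half A, zone from half B).
    """
    mask = _split_mask(len(landscape))
    return (
        derive_zone(landscape.loc[mask], **derive_kwargs),
        derive_zone(landscape.loc[~mask], **derive_kwargs),
    )


def _crossfit_in_zone(landscape: pd.DataFrame, zone_a: EnrichmentZone,
                      zone_b: EnrichmentZone, distal: bool = False) -> np.ndarray:
    """In-zone flags where each half is judged by the other half's zone."""
    n = len(landscape)
    mask = _split_mask(n)
    has = landscape["has_motif"].to_numpy(bool)
    d = landscape["signed_distance"].to_numpy(float)
    s = landscape["rel_score"].to_numpy(float)
    out = np.zeros(n, dtype=bool)
    for half, zone in ((mask, zone_b), (~mask, zone_a)):
        sel = half & has
        if distal:
            out[sel] = zone.in_distal(d[sel], s[sel])
        else:
            out[sel] = zone.contains(d[sel], s[sel])
    return out


def crossfit_composition(
    chipped_landscape: pd.DataFrame,
    zinger_landscapes: dict[str, pd.DataFrame],
    **derive_kwargs,
) -> tuple[CompositionEstimate, pd.DataFrame]:
    """Two-fold cross-fitted composition estimate plus per-peak flags.

    Same definitions as :func:`composition` but every peak's zone membership
    is judged by the enrichment zone derived from the *other* half of the
    dataset, so the background-corrected fractions are free of the
    zone-selection bias. Returns the estimate and a flag frame with the
    same columns as :func:`peak_flags`.
    """
    n = len(chipped_landscape)
    if n == 0:
        raise ValueError("empty dataset")
    chip_za, chip_zb = crossfit_zones(chipped_landscape, **derive_kwargs)
    chipped_flag = _crossfit_in_zone(chipped_landscape, chip_za, chip_zb)
    flags = pd.DataFrame(index=chipped_landscape.index)
    flags["chipped"] = chipped_flag
    flags["chipped_score"] = chipped_landscape["rel_score"]
    zinger_any = np.zeros(n, dtype=bool)
    strict_any = np.zeros(n, dtype=bool)
    best = np.full(n, np.nan)
    per_zinger_corr: dict[str, float] = {}
    for name, lsc in zinger_landscapes.items():
        za, zb = crossfit_zones(lsc, **derive_kwargs)
        in_zone = _crossfit_in_zone(lsc, za, zb)
        in_dist = _crossfit_in_zone(lsc, za, zb, distal=True)
        zc = int((in_zone & ~chipped_flag).sum())
        dc = int((in_dist & ~chipped_flag).sum())
        per_zinger_corr[name] = max(0, zc - dc) / n
        zinger_any |= in_zone & ~chipped_flag
        s = lsc["rel_score"].to_numpy(float)
        strict = in_zone & ~chipped_flag & (s > 85.0)
        flags[f"zinger_{name}"] = strict
        strict_any |= strict
        upd = strict & (np.isnan(best) | (s > best))
        best[upd] = s[upd]
    flags["zinger"] = strict_any
    flags["unidentified"] = ~(chipped_flag | strict_any)
    flags["best_zinger_score"] = best
    zinger_flag = zinger_any & ~chipped_flag
    czc = int(_crossfit_in_zone(chipped_landscape, chip_za, chip_zb).sum())
    cdc = int(_crossfit_in_zone(chipped_landscape, chip_za, chip_zb, distal=True).sum())
    est = CompositionEstimate(
        n_peaks=n,
        raw_chipped=float(chipped_flag.mean()),
        raw_zinger=float(zinger_flag.mean()),
        raw_unidentified=float((~(chipped_flag | zinger_flag)).mean()),
        corrected_chipped=corrected_fraction(czc, cdc, n),
        corrected_zinger=float(sum(per_zinger_corr.values())),
        per_zinger_corrected=per_zinger_corr,
    )
    return est, flags


def peak_flags(
    chipped_landscape: pd.DataFrame,
    chipped_zone: EnrichmentZone,
    zinger_landscapes: dict[str, tuple[pd.DataFrame, EnrichmentZone]],
    zinger_score_min: float = 85.0,
) -> pd.DataFrame:
    """Per-peak classification flags used downstream.

    The per-zinger flag additionally requires the zinger motif score to
    exceed ``zinger_score_min`` (the single-threshold convention used for
    pooled analyses). Columns: chipped, zinger (any), unidentified, one
    boolean column per zinger name, best_zinger_score, chipped_score.
    """
    n = len(chipped_landscape)
    has = chipped_landscape["has_motif"].to_numpy(bool)
    chipped_flag = np.zeros(n, dtype=bool)
    chipped_flag[has] = chipped_zone.contains(
        chipped_landscape["signed_distance"].to_numpy(float)[has],
        chipped_landscape["rel_score"].to_numpy(float)[has],
    )
    out = pd.DataFrame(index=chipped_landscape.index)
    out["chipped"] = chipped_flag
    out["chipped_score"] = chipped_landscape["rel_score"]
    best = np.full(n, np.nan)
    zany = np.zeros(n, dtype=bool)
    for name, (lsc, zone) in zinger_landscapes.items():
        zhas = lsc["has_motif"].to_numpy(bool)
        d = lsc["signed_distance"].to_numpy(float)
        s = lsc["rel_score"].to_numpy(float)
        flag = np.zeros(n, dtype=bool)
        flag[zhas] = zone.contains(d[zhas], s[zhas]) & (s[zhas] > zinger_score_min)
        flag &= ~chipped_flag
        out[f"zinger_{name}"] = flag
        zany |= flag
        upd = flag & (np.isnan(best) | (s > best))
        best[upd] = s[upd]
    out["zinger"] = zany
    out["unidentified"] = ~(chipped_flag | zany)
    out["best_zinger_score"] = best
    return out
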