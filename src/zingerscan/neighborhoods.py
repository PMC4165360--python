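"""Peak neighborhoods: recurrence of motif peak regions across datasets.

Classified peaks pooled across datasets are merged into *neighborhoods* by
single-linkage chaining of sorted peakMax positions: consecutive positions at
most 50 bp apart join the same neighborhood (so a chained neighborhood can be
much wider than 50 bp). Recurrence is quantified as the number of unique
ChIPped TFs and unique cell lines contributing members. ChIPped-TF
neighborhoods within 300 bp (centre to centre) of a zinger or unidentified
neighborhood are removed before between-class comparisons, and proximity of
neighborhood centres to cohesin/PRC tracks (within 500 bp of a track
reference point) is tested with one-tailed Fisher exact tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MERGE_BP = 50
DECLASS_BP = 300
PROXIMITY_BP = 500

MEMBER_COLUMNS = ["chrom", "peakmax", "tf", "cell_line"]


def merge_neighborhoods(
    members: pd.DataFrame, merge_bp: int = MERGE_BP
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-linkage merge of peakMax positions into neighborhoods.

    ``members`` needs columns chrom, peakmax, tf, cell_line (extra columns
    are carried through). Returns ``(neighborhoods, labelled_members)``:
    the neighborhood table has one row per chain with the peakMax envelope
    [start, end) in 0-based half-open coordinates, the centre (envelope
    midpoint), width, member count, and unique-TF / unique-cell-line
    recurrence counts; the member table gains a ``neighborhood_id`` column.
    Every input peak belongs to exactly one neighborhood.
    """
    missing = [c for c in MEMBER_COLUMNS if c not in members.columns]
    if missing:
        raise ValueError(f"members missing columns: {missing}")
    labelled = members.sort_values(["chrom", "peakmax"], kind="mergesort").copy()
    if len(labelled) == 0:
        nb = pd.DataFrame(
            columns=["chrom", "start", "end", "center", "width", "n_members",
                     "n_unique_tfs", "n_unique_cell_lines"]
        )
        labelled["neighborhood_id"] = pd.Series(dtype=int)
        return nb, labelled
    pos = labelled["peakmax"].to_numpy(float)
    new_chrom = labelled["chrom"].ne(labelled["chrom"].shift()).to_numpy()
    gap = np.empty(len(labelled), dtype=bool)
    gap[0] = True
    gap[1:] = new_chrom[1:] | (np.diff(pos) > merge_bp)
    labelled["neighborhood_id"] = np.cumsum(gap) - 1
    grp = labelled.groupby("neighborhood_id", sort=True)
    nb = grp.agg(
        chrom=("chrom", "first"),
        start=("peakmax", "min"),
        end=("peakmax", "max"),
        n_members=("peakmax", "size"),
        n_unique_tfs=("tf", "nunique"),
        n_unique_cell_lines=("cell_line", "nunique"),
    )
    nb["width"] = (nb["end"] - nb["start"]).astype(int)
    nb["center"] = (nb["start"] + nb["end"]) / 2.0
    nb["end"] = nb["end"].astype(int) + 1  # half-open envelope
    nb["start"] = nb["start"].astype(int)
    nb = nb[["chrom", "start", "end", "center", "width", "n_members",
             "n_unique_tfs", "n_unique_cell_lines"]].reset_index(drop=True)
    return nb, labelled


def recurrence_summary(neighborhoods: pd.DataFrame) -> pd.Series:
    """Recurrence statistics for one class of neighborhoods."""
    n = len(neighborhoods)
    multi = int((neighborhoods["n_unique_tfs"] >= 2).sum()) if n else 0
    return pd.Series(
        {
            "n_neighborhoods": n,
            "n_multi_tf": multi,
            "frac_multi_tf": multi / n if n else float("nan"),
            "mean_width": float(neighborhoods["width"].mean()) if n else float("nan"),
            "frac_multi_cell_line": float(
                (neighborhoods["n_unique_cell_lines"] >= 2).mean()
            ) if n else float("nan"),
            "total_bp": int((neighborhoods["end"] - neighborhoods["start"]).sum()) if n else 0,
        }
    )


def _center_near(
    query: pd.DataFrame, others: list[pd.DataFrame], window_bp: int
) -> np.ndarray:
    """Boolean: query centre within window of any centre in ``others``."""
    near = np.zeros(len(query), dtype=bool)
    for other in others:
        if len(other) == 0:
            continue
        for chrom, sub in query.groupby("chrom", sort=False):
            ref = np.sort(other.loc[other["chrom"] == chrom, "center"].to_numpy(float))
            if ref.size == 0:
                continue
            q = sub["center"].to_numpy(float)
            j = np.searchsorted(ref, q)
            left = np.where(j > 0, q - ref[np.clip(j - 1, 0, ref.size - 1)], np.inf)
            right = np.where(j < ref.size, ref[np.clip(j, 0, ref.size - 1)] - q, np.inf)
            hit = np.minimum(np.abs(left), np.abs(right)) <= window_bp
            near[query.index.get_indexer(sub.index)] |= hit
    return near


def declass_overlaps(
    chipped_nbhds: pd.DataFrame,
    zinger_nbhds: pd.DataFrame,
    unidentified_nbhds: pd.DataFrame,
    exclusion_bp: int = DECLASS_BP,
) -> pd.DataFrame:
    """Drop ChIPped-TF neighborhoods near zinger/unidentified neighborhoods.

    Removal is by centre-to-centre distance <= ``exclusion_bp``, ensuring the
    class comparisons are made between distinct neighborhood sets.
    """
    near = _center_near(chipped_nbhds, [zinger_nbhds, unidentified_nbhds], exclusion_bp)
    return chipped_nbhds.loc[~near].copy()


def proximity_test(
    nbhds_a: pd.DataFrame,
    nbhds_b: pd.DataFrame,
    track: pd.DataFrame,
    window_bp: int = PROXIMITY_BP,
) -> tuple[float, float, float]:
    """Compare proximity of two neighborhood sets to a region track.

    ``track`` needs columns chrom, peakmax (the reference points). Returns
    (frac_a, frac_b, p) where p is the one-tailed Fisher exact probability
    that set A is more proximal than set B.
    """
    if len(track) == 0:
        raise ValueError("track must be non-empty")
    tr = track.rename(columns={"peakmax": "center"})[["chrom", "center"]]
    near_a = _center_near(nbhds_a, [tr], window_bp)
    near_b = _center_near(nbhds_b, [tr], window_bp)
    frac_a = float(near_a.mean()) if len(nbhds_a) else float("nan")
    frac_b = float(near_b.mean()) if len(nbhds_b) else float("nan")
    table = [
        [int(near_a.sum()), int((~near_a).sum())],
        [int(near_b.sum()), int((~near_b).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return frac_a, frac_b, float(p)


def feature_proximity_screen(
    dataset_groups: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    tracks: dict[str, pd.DataFrame],
    windows: dict[str, int] | None = None,
    min_zinger_peaks: int = 200,
    direction_rule: float = 0.60,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen genomic features for consistent zinger-vs-chipped proximity.

    ``dataset_groups`` maps dataset_id to (zinger_peaks, chipped_peaks)
    DataFrames with chrom/peakmax columns. Datasets with fewer than
    ``min_zinger_peaks`` zinger motif peaks are excluded. Per feature, each
    eligible dataset contributes a two-sided Fisher test of proximal counts;
    the feature's verdict is "proximal" or "distal" when at least 60% of
    eligible datasets are significant in that direction, else "none".
    """
    windows = windows or {}
    rows = []
    for feature, track in tracks.items():
        window = windows.get(feature, PROXIMITY_BP)
        n_eligible = n_prox = n_dist = 0
        for ds, (zp, cp) in dataset_groups.items():
            if len(zp) < min_zinger_peaks:
                continue
            n_eligible += 1
            tr = track.rename(columns={"peakmax": "center"})[["chrom", "center"]]
            zq = zp.rename(columns={"peakmax": "center"})[["chrom", "center"]]
            cq = cp.rename(columns={"peakmax": "center"})[["chrom", "center"]]
            z_near = _center_near(zq, [tr], window)
            c_near = _center_near(cq, [tr], window)
            table = [
                [int(z_near.sum()), int((~z_near).sum())],
                [int(c_near.sum()), int((~c_near).sum())],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            if p < alpha:
                if odds > 1:
                    n_prox += 1
                elif odds < 1:
                    n_dist += 1
        if n_eligible == 0:
            verdict = "no-eligible-datasets"
        elif n_prox / n_eligible >= direction_rule:
            verdict = "proximal"
        elif n_dist / n_eligible >= direction_rule:
            verdict = "distal"
        else:
            verdict = "none"
        rows.append(
            {
                "feature": feature,
                "window_bp": window,
                "n_eligible": n_eligible,
                "n_significant_proximal": n_prox,
                "n_significant_distal": n_dist,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
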