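"""Per-dataset motif over-representation scoring and enrichment calls.

Two scores are computed for every (dataset, binding profile) pair, following
the oPOSSUM sequence-based analysis conventions:

* **Fisher-log score** — minus the natural log of a one-tailed Fisher exact
  p-value (hypergeometric) comparing the number of target vs background
  sequences that contain at least one motif hit. A score of 6.91 corresponds
  to p = 0.001.
* **KS centrality score** — minus the natural log of a two-sample
  Kolmogorov-Smirnov p-value comparing motif distances to the region centre
  between target and background sequences.

Scores that underflow to p = 0 are "infinite" and capped (Fisher-log: 100
past the largest finite score, or 500 when none exists; KS: 100). Scores are
averaged per ChIPped TF across that TF's datasets, binarized against
row-wise mean + k*SD thresholds, and the resulting per-profile dataset
counts corrected for motif families that recognize the same consensus.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

FISHER_ALL_INF_CAP = 500.0
FISHER_CAP_PAST_MAX = 100.0
KS_INF_CAP = 100.0

#: sentinel for scores that could not be computed (e.g. no motif distances)
UNDEFINED = float("nan")


def fisher_log_score(n_target_with, n_target, n_bg_with, n_bg):
    """One-tailed (enrichment direction) Fisher exact test, as -ln(p).

    Returns ``math.inf`` where the p-value underflows to zero; callers cap
    such scores with :func:`cap_infinite`. Accepts scalars or broadcastable
    arrays (returning an array for array input).
    """
    kt = np.asarray(n_target_with)
    nt = np.asarray(n_target)
    kb = np.asarray(n_bg_with)
    nb = np.asarray(n_bg)
    if (kt < 0).any() or (nt < 0).any() or (kb < 0).any() or (nb < 0).any():
        raise ValueError("counts must be non-negative")
    if (kt > nt).any() or (kb > nb).any():
        raise ValueError("with-motif counts cannot exceed totals")
    if (nt <= 0).any() or (nb <= 0).any():
        raise ValueError("set sizes must be positive")
    # P(X >= n_target_with), X ~ Hypergeom(total, n_with, n_target)
    logp = stats.hypergeom.logsf(kt - 1, nt + nb, kt + kb, nt)
    score = np.where(np.isfinite(logp), -logp, math.inf)
    if np.ndim(score) == 0:
        return float(score)
    return score


def ks_centrality_score(
    target_center_distances: Iterable[float],
    bg_center_distances: Iterable[float],
    exact_below: int = 10,
) -> float:
    """Two-sample KS test of motif centrality, as -ln(p).

    Distances are absolute bp offsets from the region centre. The exact
    two-sample method is used when either sample has fewer than
    ``exact_below`` observations, the asymptotic formula otherwise. Empty
    samples yield NaN (excluded from enrichment calls).
    """
    a = np.asarray(list(target_center_distances), dtype=float)
    b = np.asarray(list(bg_center_distances), dtype=float)
    if a.size == 0 or b.size == 0:
        return UNDEFINED
    method = "exact" if min(a.size, b.size) < exact_below else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if p <= 0.0:
        return math.inf
    return -math.log(p)


def cap_infinite(scores: Iterable[float], kind: str) -> np.ndarray:
    """Replace infinite scores according to the capping rules.

    ``kind="fisher"``: infinite entries become max(finite) + 100, or 500 when
    no finite score exists. ``kind="ks"``: infinite entries become 100.
    NaN (undefined) entries pass through unchanged.
    """
    arr = np.asarray(list(scores), dtype=float).copy()
    inf_mask = np.isinf(arr)
    if not inf_mask.any():
        return arr
    if kind == "fisher":
        finite = arr[np.isfinite(arr)]
        cap = FISHER_ALL_INF_CAP if finite.size == 0 else finite.max() + FISHER_CAP_PAST_MAX
    elif kind == "ks":
        cap = KS_INF_CAP
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    arr[inf_mask] = cap
    return arr


def dataset_scores(
    pwm,
    target_matrix: np.ndarray,
    bg_matrix: np.ndarray,
    score_threshold: float = 85.0,
    overlap_fraction: float = 0.2,
) -> tuple[float, float, dict]:
    """Fisher-log and KS centrality scores for one profile on one dataset.

    ``target_matrix`` / ``bg_matrix`` are encoded equal-length sequence
    matrices (see :func:`zingerscan.motifs.encode_sequence`). Sequences count
    as containing the motif when they retain at least one hit at or above the
    relative-score threshold; KS samples are the retained hits' absolute
    midpoint distances to the region centre.
    """
    from . import motifs as _m

    detail: dict = {}
    samples = []
    withs = []
    for mat in (target_matrix, bg_matrix):
        hits = _m.scan_batch(pwm, mat, score_threshold, overlap_fraction)
        center = (mat.shape[1] - 1) // 2
        dists = [abs(h.midpoint() - center) for row in hits for h in row]
        withs.append(sum(1 for row in hits if row))
        samples.append(dists)
    n_t, n_b = target_matrix.shape[0], bg_matrix.shape[0]
    fisher = fisher_log_score(withs[0], n_t, withs[1], n_b)
    ks = ks_centrality_score(samples[0], samples[1])
    detail.update(
        n_target_with=withs[0],
        n_target=n_t,
        n_bg_with=withs[1],
        n_bg=n_b,
        n_target_hits=len(samples[0]),
        n_bg_hits=len(samples[1]),
    )
    return fisher, ks, detail


def aggregate_by_tf(results: pd.DataFrame) -> pd.DataFrame:
    """Average dataset-level scores over datasets ChIPped for the same TF.

    ``results`` is tidy with columns [dataset_id, tf, profile_id, fisher_log,
    ks_log]; infinite scores should already be capped. Returns one row per
    (tf, profile_id) with the arithmetic means.
    """
    required = {"dataset_id", "tf", "profile_id", "fisher_log", "ks_log"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    out = (
        results.groupby(["tf", "profile_id"], sort=True)[["fisher_log", "ks_log"]]
        .mean()
        .reset_index()
    )
    return out


def _row_thresholds(values: np.ndarray, k: float) -> float:
    finite = values[np.isfinite(values)]
    if finite.size < 3:
        raise ValueError("need >= 3 finite profile scores per TF row")
    return float(finite.mean() + k * finite.std(ddof=1))


def row_thresholds(
    fisher: pd.DataFrame, ks: pd.DataFrame, k_fisher: float = 2.0, k_ks: float = 1.0
) -> pd.DataFrame:
    """Per-TF-row score thresholds (mean + k*SD across profile columns)."""
    rows = []
    for tf in fisher.index:
        rows.append(
            {
                "tf": tf,
                "fisher_threshold": _row_thresholds(fisher.loc[tf].to_numpy(float), k_fisher),
                "ks_threshold": _row_thresholds(ks.loc[tf].to_numpy(float), k_ks),
                "fisher_sd": float(np.nanstd(fisher.loc[tf].to_numpy(float), ddof=1)),
                "ks_sd": float(np.nanstd(ks.loc[tf].to_numpy(float), ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("tf")


def enrichment_calls(
    fisher: pd.DataFrame,
    ks: pd.DataFrame,
    k_fisher: float = 2.0,
    k_ks: float = 1.0,
) -> pd.DataFrame:
    """Binary enrichment calls per (TF row, profile column).

    ``fisher`` and ``ks`` are TF x profile matrices of dataset-averaged
    scores. A cell is called (1) when its Fisher-log score reaches the row
    mean + 2 SD **and** its KS score reaches the row mean + 1 SD; SDs are
    computed across the profile scores within the row. When a row's SD is
    zero only scores strictly above the common value are called; undefined
    (NaN) scores are never called.
    """
    if not fisher.index.equals(ks.index) or not fisher.columns.equals(ks.columns):
        raise ValueError("fisher and ks matrices must share index and columns")
    calls = pd.DataFrame(0, index=fisher.index, columns=fisher.columns, dtype=int)
    for tf in fisher.index:
        f = fisher.loc[tf].to_numpy(float)
        k = ks.loc[tf].to_numpy(float)
        f_fin, k_fin = f[np.isfinite(f)], k[np.isfinite(k)]
        if f_fin.size < 3 or k_fin.size < 3:
            raise ValueError(f"TF row {tf!r} needs >= 3 finite scores")
        f_sd, k_sd = f_fin.std(ddof=1), k_fin.std(ddof=1)
        f_thr = f_fin.mean() + k_fisher * f_sd
        k_thr = k_fin.mean() + k_ks * k_sd
        with np.errstate(invalid="ignore"):
            pass_f = (f > f_thr) if f_sd == 0 else (f >= f_thr)
            pass_k = (k > k_thr) if k_sd == 0 else (k >= k_thr)
        ok = pass_f & pass_k & np.isfinite(f) & np.isfinite(k)
        calls.loc[tf] = ok.astype(int)
    return calls


def family_correction(raw_count: int, n_family_datasets: int) -> int:
    """Subtract motif-family redundancy from an enriched-dataset count.

    The number of family members contributing datasets, minus one, is
    subtracted: a raw count of 20 with 9 family datasets yields 12. Floored
    at zero; a family of one changes nothing.
    """
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    if n_family_datasets < 1:
        raise ValueError("n_family_datasets must be >= 1")
    return max(0, raw_count - (n_family_datasets - 1))


def corrected_profile_counts(
    calls: pd.DataFrame, family_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Raw and family-corrected enriched-TF counts per profile.

    ``family_map`` maps TF/profile names to a family label; entries absent
    from the map are treated as singleton families. For each profile, the
    family datasets counted are the *enriched* TF rows whose TF shares the
    profile's family.
    """
    fam = dict(family_map or {})
    rows = []
    for profile in calls.columns:
        col = calls[profile]
        raw = int(col.sum())
        pfam = fam.get(str(profile))
        if pfam is None:
            n_family = 1
        else:
            enriched_tfs = [str(tf) for tf, v in col.items() if v]
            n_family = max(1, sum(1 for tf in enriched_tfs if fam.get(tf) == pfam))
        rows.append(
            {
                "profile_id": profile,
                "raw_count": raw,
                "n_family_datasets": n_family,
                "corrected_count": family_correction(raw, n_family),
            }
        )
    return pd.DataFrame(rows).set_index("profile_id")
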