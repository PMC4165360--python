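"""Shuffled-matrix null calibration of cross-dataset enrichment frequencies.

Short motifs occur by chance, so a profile can look enriched in some datasets
without any biology behind it. To calibrate how many enriched datasets are
expected by chance, the profile's PFM is column-shuffled (edges fixed) 100
times, each shuffled matrix is pushed through the same enrichment analysis
with the thresholds that were set for the original profile, and the number of
TF datasets each shuffled profile is enriched in is recorded. A
zero-adjusted logarithmic distribution (ZALG) is fitted to those counts:

    P(Y = 0) = p0
    P(Y = y) = (1 - p0) * (-1 / ln(1 - mu)) * mu^y / y,   y >= 1

The probability of the original profile's observed count is then evaluated
under the fit; by default this is the upper tail P(Y >= observed), since an
"as extreme as" statement needs a tail, with the point density available
behind ``mode="density"``. Goodness of fit is assessed by a chi-squared
comparison against the fitted pmf, calibrated by parametric bootstrap
(datasets regenerated from the fit, as with rZALG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import enrichment as _enr
from . import motifs as _motifs


@dataclass
class ZALGFit:
    """Maximum-likelihood zero-adjusted logarithmic fit.

    ``p0`` is the zero-class probability (its MLE is the observed zero
    fraction); ``mu`` is the logarithmic-series parameter fitted to the
    positive counts. ``mu`` is NaN when no positive counts exist.
    """

    p0: float
    mu: float
    n: int = 0
    loglik: float = field(default=float("nan"))

    @property
    def _log_norm(self) -> float:
        return -math.log1p(-self.mu)

    def pmf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        out = np.zeros(y.shape, dtype=float)
        out[y == 0] = self.p0
        pos = y > 0
        if pos.any():
            if math.isnan(self.mu):
                out[pos] = 0.0
            else:
                yy = y[pos].astype(float)
                out[pos] = (1 - self.p0) * np.exp(
                    yy * math.log(self.mu) - np.log(yy)
                ) / self._log_norm
        return out

    def tail(self, k: int) -> float:
        """Upper-tail probability P(Y >= k)."""
        if k <= 0:
            return 1.0
        if math.isnan(self.mu) or self.p0 >= 1.0:
            return 0.0
        # sum mu^y / y from y = k until the remainder is negligible
        total = 0.0
        term_log = k * math.log(self.mu)
        y = k
        while True:
            term = math.exp(term_log) / y
            total += term
            # geometric bound on the remainder
            if term * self.mu / (1 - self.mu) < 1e-16 * max(total, 1e-300):
                break
            y += 1
            term_log += math.log(self.mu)
            if y > 10_000_000:
                break
        return (1 - self.p0) * total / self._log_norm

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Random counts from the fitted distribution."""
        zero = rng.random(size) < self.p0
        out = np.zeros(size, dtype=int)
        n_pos = int((~zero).sum())
        if n_pos and not math.isnan(self.mu):
            out[~zero] = rng.logseries(self.mu, size=n_pos)
        return out

    def summary(self) -> str:
        return (
            f"ZALG fit (n={self.n}): p0={self.p0:.4f}, mu="
            + ("nan" if math.isnan(self.mu) else f"{self.mu:.4f}")
            + (f", loglik={self.loglik:.2f}" if not math.isnan(self.loglik) else "")
        )


def _logseries_mean(mu: float) -> float:
    return -mu / ((1 - mu) * math.log1p(-mu))


def fit_zalg(counts) -> ZALGFit:
    """Maximum-likelihood ZALG fit to non-negative integer counts.

    ``p0`` has the closed form (fraction of zeros); ``mu`` solves the
    logarithmic-series mean equation for the positive counts by root
    bracketing to 1e-10. All-zero input returns p0 = 1 with mu undefined.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    c = c.astype(int)
    n = c.size
    p0 = float((c == 0).mean())
    pos = c[c > 0]
    if pos.size == 0:
        return ZALGFit(p0=1.0, mu=float("nan"), n=n, loglik=0.0)
    m = float(pos.mean())
    lo, hi = 1e-9, 1 - 1e-9
    if m <= _logseries_mean(lo):
        mu = lo
    elif m >= _logseries_mean(hi):
        mu = hi
    else:
        mu = float(brentq(lambda x: _logseries_mean(x) - m, lo, hi, xtol=1e-10))
    fit = ZALGFit(p0=p0, mu=mu, n=n)
    with np.errstate(divide="ignore"):
        ll = np.log(fit.pmf(c))
    fit.loglik = float(ll[np.isfinite(ll)].sum()) if np.isfinite(ll).any() else float("-inf")
    return fit


def _pooled_edges(fit: ZALGFit, kmax: int, n: int, min_expected: float = 5.0):
    """Bin lower edges (count values) pooled so every expected bin >= 5.

    Bins are pooled from the right; the rightmost bin absorbs the analytic
    tail beyond ``kmax``. Returns (lower_edges, expected_per_bin).
    """
    expected = fit.pmf(np.arange(kmax + 1)) * n
    edges: list[int] = []
    exp_bins: list[float] = []
    acc_e = n * fit.tail(kmax + 1)
    for k in range(kmax, -1, -1):
        acc_e += expected[k]
        if acc_e >= min_expected or k == 0:
            edges.append(k)
            exp_bins.append(acc_e)
            acc_e = 0.0
    edges.reverse()
    exp_bins.reverse()
    if len(edges) >= 2 and exp_bins[0] < min_expected:
        exp_bins[1] += exp_bins[0]
        del edges[1], exp_bins[0]
        edges[0] = 0
    return np.array(edges), np.array(exp_bins)


def _bin_by_edges(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.bincount(np.clip(idx, 0, edges.size - 1), minlength=edges.size).astype(float)


def zalg_gof(
    fit: ZALGFit,
    counts,
    n_sim: int = 200,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Parametric-bootstrap chi-squared goodness-of-fit p-value.

    Observed counts are binned with expected-count pooling (every expected
    bin >= 5); the chi-squared statistic is referred to its distribution
    under ``n_sim`` datasets regenerated from the fit, mirroring the
    simulate-and-compare (rZALG) procedure. Returns NaN when pooling leaves
    fewer than two bins.
    """
    c = np.asarray(list(counts), dtype=int)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    edges, exp = _pooled_edges(fit, int(c.max()), c.size)
    if edges.size < 2:
        return float("nan")
    obs = _bin_by_edges(c, edges)
    stat = float(((obs - exp) ** 2 / exp).sum())
    exceed = 0
    for _ in range(n_sim):
        sim_obs = _bin_by_edges(fit.rvs(c.size, gen), edges)
        sim_stat = float(((sim_obs - exp) ** 2 / exp).sum())
        if sim_stat >= stat:
            exceed += 1
    return (1 + exceed) / (n_sim + 1)


def zalg_tail_probability(fit: ZALGFit, observed_count: int, mode: str = "tail") -> float:
    """Probability of a result as extreme as the observed dataset count.

    ``mode="tail"`` (default) returns P(Y >= observed); ``mode="density"``
    returns the point mass dZALG(observed).
    """
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    if mode == "tail":
        return fit.tail(int(observed_count))
    if mode == "density":
        return float(fit.pmf(np.array([observed_count]))[0])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Null ensembles from shuffled matrices
# ---------------------------------------------------------------------------


@dataclass
class NullEnsemble:
    """Family-corrected enriched-TF counts for shuffled versions of a PFM."""

    profile_id: str
    counts: np.ndarray
    n_shuffles: int
    seed: int | None


def profile_dataset_scores(
    pwm: _motifs.PWM,
    corpus: list[dict],
    score_threshold: float = 85.0,
) -> pd.DataFrame:
    """Capped, TF-averaged scores of one profile across a corpus.

    ``corpus`` entries are dicts with keys dataset_id, tf, target (encoded
    matrix) and background (encoded matrix). Returns columns
    [tf, fisher_log, ks_log] after capping and per-TF averaging.
    """
    rows = []
    for ds in corpus:
        f, k, _ = _enr.dataset_scores(
            pwm, ds["target"], ds["background"], score_threshold=score_threshold
        )
        rows.append(
            {"dataset_id": ds["dataset_id"], "tf": ds["tf"], "profile_id": pwm.id,
             "fisher_log": f, "ks_log": k}
        )
    df = pd.DataFrame(rows)
    df["fisher_log"] = _enr.cap_infinite(df["fisher_log"], "fisher")
    df["ks_log"] = _enr.cap_infinite(df["ks_log"], "ks")
    return _enr.aggregate_by_tf(df)[["tf", "fisher_log", "ks_log"]]


def count_enriched_tfs(
    per_tf: pd.DataFrame,
    thresholds: pd.DataFrame,
    tf_families: dict[str, str] | None = None,
    profile_family: str | None = None,
) -> int:
    """Enriched-TF count against per-row thresholds, family corrected.

    ``thresholds`` is indexed by tf with columns fisher_threshold and
    ks_threshold (as set for the original profiles). The family correction
    subtracts (members - 1) where members counts enriched TFs in the
    profile's motif family.
    """
    merged = per_tf.set_index("tf").join(thresholds, how="inner")
    enriched = merged[
        (merged["fisher_log"] >= merged["fisher_threshold"])
        & (merged["ks_log"] >= merged["ks_threshold"])
    ]
    raw = len(enriched)
    if raw == 0:
        return 0
    fam = tf_families or {}
    if profile_family is None:
        n_family = 1
    else:
        n_family = max(1, sum(1 for tf in enriched.index if fam.get(str(tf)) == profile_family))
    return _enr.family_correction(raw, n_family)


def null_counts(
    pfm: _motifs.PFM,
    corpus: list[dict],
    thresholds: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int | None = None,
    score_threshold: float = 85.0,
    tf_families: dict[str, str] | None = None,
    profile_family: str | None = None,
) -> NullEnsemble:
    """Enriched-TF counts for ``n_shuffles`` column-shuffled variants.

    Each shuffled matrix is converted to a PWM, scored on every corpus
    dataset, capped, averaged per TF, and compared against the *original*
    rows' enrichment thresholds; counts are family corrected. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        shuffled = _motifs.shuffle_pfm(pfm, rng=rng)
        spwm = _motifs.pfm_to_pwm(shuffled)
        spwm.id = f"{pfm.id}_shuf{i}"
        per_tf = profile_dataset_scores(spwm, corpus, score_threshold)
        counts[i] = count_enriched_tfs(per_tf, thresholds, tf_families, profile_family)
    return NullEnsemble(pfm.id, counts, n_shuffles, seed)
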