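"""Synthetic multi-dataset ChIP-seq corpora with known ground truth.

Real zinger analyses run on hundreds of ENCODE/GEO peak sets; this module
generates desk-scale corpora with the same statistical structure so every
pipeline stage can be exercised and validated against planted truth:

* fixed-length peak regions (1001 bp) with the peakMax at the centre and a
  uniform background rate of chance motif matches arising naturally from the
  random sequence;
* ChIPped-TF binding sites planted near the peakMax in a configurable
  fraction of peaks, and zinger sites (CTCF-like, ETS-like, JUN-like,
  THAP11-like synthetic profiles) planted in disjoint fractions;
* shared "zinger regions": genomic positions reused across datasets so that
  zinger motif peaks recur for many TFs and cell lines;
* cohesin / polycomb-like tracks placed within 500 bp of a configurable
  fraction of the shared regions and at background density elsewhere;
* peak scores drawn from location-shifted distributions so ChIPped-motif
  peaks score better than zinger motif peaks.

Everything is deterministic under the corpus seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import motifs as _motifs
from .landscape import REGION_LENGTH

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ZINGER_NAMES = ("CTCF_like", "ETS_like", "JUN_like", "THAP11_like")


def consensus_pfm(
    consensus: str,
    pfm_id: str,
    name: str = "",
    n_sites: int = 100,
    dominance: float = 0.85,
    edge_columns: int = 2,
    edge_dominance: float = 0.45,
) -> _motifs.PFM:
    """Deterministic PFM whose columns favour a consensus word.

    The consensus base receives ``dominance`` of the column counts and the
    other bases share the remainder; edge columns use ``edge_dominance`` to
    mimic the low-information flanks of real matrices.
    """
    L = len(consensus)
    counts = np.zeros((4, L))
    for j, base in enumerate(consensus.upper()):
        dom = edge_dominance if (j < edge_columns or j >= L - edge_columns) else dominance
        rest = (1.0 - dom) / 3.0
        for i in range(4):
            counts[i, j] = n_sites * (dom if _motifs.BASES[i] == base else rest)
    return _motifs.PFM(pfm_id, name, counts)


def zinger_pfms() -> dict[str, _motifs.PFM]:
    """Synthetic stand-in profiles for the four zinger motif classes.

    These are constructed consensus matrices, not the JASPAR models: a wide
    CTCF-like matrix (19 columns, so shuffling holds 3 edge columns), an
    ETS-like GGAA-core matrix, a 7 bp JUN-like TGACTCA matrix and a
    THAP11-like matrix.
    """
    return {
        "CTCF_like": consensus_pfm(
            "TGCCACCTGGTGGCCAGCA", "SYN_CTCF", "CTCF_like", dominance=0.9
        ),
        "ETS_like": consensus_pfm("ACCGGAAGTG", "SYN_ETS", "ETS_like", dominance=0.88),
        "JUN_like": consensus_pfm("TGACTCA", "SYN_JUN", "JUN_like", dominance=0.95,
                                  edge_columns=1),
        "THAP11_like": consensus_pfm(
            "GCTGGAGCCCAC", "SYN_THAP11", "THAP11_like", dominance=0.88
        ),
    }


def random_pfm(
    rng: np.random.Generator,
    pfm_id: str,
    width: int = 10,
    n_sites: int = 100,
    dominance: float = 0.88,
) -> _motifs.PFM:
    """A consensus PFM with a random consensus word (decoy/ChIPped profile)."""
    consensus = "".join(rng.choice(list(_motifs.BASES), size=width))
    return consensus_pfm(consensus, pfm_id, pfm_id, n_sites, dominance)


def sample_site(pfm: _motifs.PFM, rng: np.random.Generator) -> str:
    """Draw one binding-site word column-independently from PFM frequencies."""
    cum = np.cumsum(pfm.frequencies(), axis=0)
    codes = (rng.random(pfm.width)[None, :] > cum).sum(axis=0)
    return "".join(_motifs.BASES[c] for c in np.minimum(codes, 3))


def _sample_site_at_least(
    pfm: _motifs.PFM,
    pwm: _motifs.PWM,
    floor: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, float]:
    """Rejection-sample a site with relative score >= floor (best-of fallback)."""
    best, best_score = None, -1.0
    for _ in range(max_tries):
        w = sample_site(pfm, rng)
        s = _motifs.relative_score(pwm, w)
        if s >= floor:
            return w, s
        if s > best_score:
            best, best_score = w, s
    return best, best_score  # pragma: no cover - high-IC matrices rarely get here


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """One synthetic ChIP-seq dataset (a TF in a cell line)."""

    tf: str
    cell_line: str
    n_peaks: int = 5000
    chipped_fraction: float = 0.55
    zinger_fractions: dict = field(
        default_factory=lambda: {n: 0.03 for n in ZINGER_NAMES}
    )
    half_width_bp: int = 90       # planted motif midpoint within +/- this of peakMax
    score_floor: float = 85.0     # minimum relative score of planted sites
    gc: float = 0.41
    gc_sd: float = 0.05
    shared_rate: float = 0.8      # fraction of zinger peaks placed in shared regions

    def __post_init__(self) -> None:
        total = self.chipped_fraction + sum(self.zinger_fractions.values())
        if not 0 <= self.chipped_fraction <= 1 or any(
            not 0 <= v <= 1 for v in self.zinger_fractions.values()
        ):
            raise ValueError("fractions must lie in [0, 1]")
        if total > 1 + 1e-9:
            raise ValueError("chipped + zinger fractions must not exceed 1")

    @property
    def dataset_id(self) -> str:
        return f"{self.tf}_{self.cell_line}"


@dataclass
class CorpusConfig:
    """A collection of datasets sharing zinger regions on one genome."""

    datasets: list
    seed: int
    genome_length: int = 100_000_000
    n_shared_regions: int = 2000
    chrom: str = "chrS"


def default_corpus_config(
    seed: int,
    n_tfs: int = 10,
    n_cell_lines: int = 2,
    n_peaks: int = 5000,
    **dataset_kwargs,
) -> CorpusConfig:
    """The default study-structure corpus: n_tfs x n_cell_lines datasets."""
    datasets = [
        DatasetConfig(tf=f"TF{t:02d}", cell_line=f"CL{c}", n_peaks=n_peaks, **dataset_kwargs)
        for t in range(n_tfs)
        for c in range(n_cell_lines)
    ]
    return CorpusConfig(datasets=datasets, seed=seed)


# ---------------------------------------------------------------------------
# Sequence/peak generation
# ---------------------------------------------------------------------------


def _random_sequences(
    n: int, length: int, gc: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Encoded random sequences with per-sequence GC composition."""
    gc = np.clip(np.asarray(gc, float), 0.0, 1.0)
    at = (1.0 - gc) / 2.0
    c1 = at                # P(A)
    c2 = at + gc / 2.0     # P(A or C)
    c3 = at + gc           # P(A, C or G)
    u = rng.random((n, length))
    codes = (
        (u >= c1[:, None]).astype(np.uint8)
        + (u >= c2[:, None]).astype(np.uint8)
        + (u >= c3[:, None]).astype(np.uint8)
    )
    return codes


def _plant(
    matrix: np.ndarray,
    row: int,
    word: str,
    midpoint_offset: int,
    rng: np.random.Generator,
) -> tuple[int, str]:
    """Insert a site (random strand) with its midpoint at centre + offset."""
    L = len(word)
    center = (matrix.shape[1] - 1) // 2
    start = center + midpoint_offset - L // 2
    start = max(0, min(matrix.shape[1] - L, start))
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        word = word.translate(_COMPLEMENT)[::-1]
    matrix[row, start : start + L] = _motifs.encode_sequence(word)
    return start, strand


def generate_dataset(
    cfg: DatasetConfig,
    chipped_pfm: _motifs.PFM,
    zingers: dict[str, _motifs.PFM],
    shared_positions: np.ndarray,
    rng: np.random.Generator,
    chrom: str = "chrS",
    genome_length: int = 100_000_000,
    region_length: int = REGION_LENGTH,
) -> dict:
    """Generate one dataset: peaks, encoded sequences and planted truth.

    Peak classes are drawn disjointly (chipped / one zinger / background);
    planted motif midpoints are uniform within +/- ``half_width_bp`` of the
    peakMax and planted sites score at least ``score_floor``. Zinger peaks
    fall inside shared zinger regions at rate ``shared_rate``; peak scores
    are location-shifted so chipped peaks score higher than zinger peaks.
    """
    n = cfg.n_peaks
    names = list(cfg.zinger_fractions)
    probs = [cfg.chipped_fraction] + [cfg.zinger_fractions[z] for z in names]
    probs.append(max(0.0, 1.0 - sum(probs)))
    classes = rng.choice(len(probs), size=n, p=np.array(probs) / sum(probs))
    gc = rng.normal(cfg.gc, cfg.gc_sd, size=n)
    matrix = _random_sequences(n, region_length, gc, rng)

    pwms = {z: _motifs.pfm_to_pwm(p) for z, p in zingers.items()}
    chipped_pwm = _motifs.pfm_to_pwm(chipped_pfm)

    half = (region_length - 1) // 2
    peakmax = rng.integers(half, genome_length - half, size=n)
    truth_rows = []
    scores = rng.normal(7.0, 2.0, size=n)
    for i in range(n):
        cls = int(classes[i])
        if cls == 0:  # ChIPped-TF peak
            word, s = _sample_site_at_least(chipped_pfm, chipped_pwm, cfg.score_floor, rng)
            offset = int(rng.integers(-cfg.half_width_bp, cfg.half_width_bp + 1))
            _plant(matrix, i, word, offset, rng)
            scores[i] = rng.normal(10.0, 2.0)
            truth_rows.append(("chipped", offset, s, -1))
        elif 1 <= cls <= len(names):  # zinger peak
            z = names[cls - 1]
            word, s = _sample_site_at_least(zingers[z], pwms[z], cfg.score_floor, rng)
            offset = int(rng.integers(-cfg.half_width_bp, cfg.half_width_bp + 1))
            _plant(matrix, i, word, offset, rng)
            scores[i] = rng.normal(8.0, 2.0)
            region = -1
            if shared_positions.size and rng.random() < cfg.shared_rate:
                region = int(rng.integers(shared_positions.size))
                peakmax[i] = shared_positions[region] + int(rng.integers(-20, 21))
            truth_rows.append((z, offset, s, region))
        else:
            truth_rows.append(("background", np.nan, np.nan, -1))

    peak_ids = [f"{cfg.dataset_id}_p{i}" for i in range(n)]
    peaks = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "chrom": chrom,
            "start": peakmax - half,
            "end": peakmax + half + 1,
            "peakmax": peakmax,
            "score": scores,
            "dataset_id": cfg.dataset_id,
            "tf": cfg.tf,
            "cell_line": cfg.cell_line,
        }
    )
    truth = pd.DataFrame(
        truth_rows, columns=["true_class", "planted_offset", "planted_score", "shared_region"]
    )
    truth.insert(0, "peak_id", peak_ids)
    return {
        "dataset_id": cfg.dataset_id,
        "tf": cfg.tf,
        "cell_line": cfg.cell_line,
        "config": cfg,
        "peaks": peaks,
        "truth": truth,
        "matrix": matrix,
        "peak_ids": peak_ids,
    }


def generate_corpus(
    corpus_cfg: CorpusConfig,
    zingers: dict[str, _motifs.PFM] | None = None,
    chipped_pfms: dict[str, _motifs.PFM] | None = None,
) -> dict:
    """Generate every dataset of a corpus plus the shared zinger regions.

    ChIPped-TF profiles default to random consensus matrices (one per TF,
    reproducible from the corpus seed). Returns a dict with keys datasets
    (list of :func:`generate_dataset` results), shared_positions, zingers,
    chipped_pfms and config.
    """
    rng = np.random.default_rng(corpus_cfg.seed)
    zingers = zingers or zinger_pfms()
    half = (REGION_LENGTH - 1) // 2
    shared_positions = np.sort(
        rng.integers(half + 1000, corpus_cfg.genome_length - half - 1000,
                     size=corpus_cfg.n_shared_regions)
    )
    tfs = sorted({d.tf for d in corpus_cfg.datasets})
    if chipped_pfms is None:
        chipped_pfms = {tf: random_pfm(rng, f"SYN_{tf}") for tf in tfs}
    datasets = []
    for dcfg in corpus_cfg.datasets:
        ds_rng = np.random.default_rng(rng.integers(2**31))
        datasets.append(
            generate_dataset(
                dcfg,
                chipped_pfms[dcfg.tf],
                zingers,
                shared_positions,
                ds_rng,
                chrom=corpus_cfg.chrom,
                genome_length=corpus_cfg.genome_length,
            )
        )
    return {
        "datasets": datasets,
        "shared_positions": shared_positions,
        "zingers": zingers,
        "chipped_pfms": chipped_pfms,
        "config": corpus_cfg,
    }


# ---------------------------------------------------------------------------
# Tracks and backgrounds
# ---------------------------------------------------------------------------


def generate_tracks(
    shared_positions: np.ndarray,
    genome_length: int,
    rng: np.random.Generator,
    placement_fraction: float = 0.77,
    background_proximal_fraction: float = 0.13,
    proximity_bp: int = 500,
    prc_fraction: float = 0.3,
    chrom: str = "chrS",
) -> dict[str, pd.DataFrame]:
    """Cohesin/PRC-like reference-point tracks tied to shared zinger regions.

    A cohesin point is placed within ``proximity_bp`` of ``placement_fraction``
    of the shared regions; background points are laid down at the Poisson
    density that makes a random position proximal with probability
    ``background_proximal_fraction``. PRC points are placed preferentially
    near a subset of cohesin points plus their own background.
    """
    chosen = rng.random(shared_positions.size) < placement_fraction
    near = shared_positions[chosen] + rng.integers(
        -proximity_bp + 100, proximity_bp - 100, size=int(chosen.sum())
    )
    # P(no background point within +/- proximity_bp) = exp(-2*w*lambda)
    lam = -math.log(1.0 - background_proximal_fraction) / (2.0 * proximity_bp)
    n_bg = rng.poisson(lam * genome_length)
    bg = rng.integers(0, genome_length, size=n_bg)
    cohesin = np.sort(np.concatenate([near, bg]))
    prc_seed = cohesin[rng.random(cohesin.size) < prc_fraction]
    prc1 = np.sort(
        np.concatenate(
            [
                prc_seed + rng.integers(-300, 301, size=prc_seed.size),
                rng.integers(0, genome_length, size=max(1, n_bg // 4)),
            ]
        )
    )
    prc2 = np.sort(
        np.concatenate(
            [
                prc_seed + rng.integers(-300, 301, size=prc_seed.size),
                rng.integers(0, genome_length, size=max(1, n_bg // 4)),
            ]
        )
    )

    def frame(pos: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": chrom, "start": pos - 100, "end": pos + 101, "peakmax": pos}
        )

    return {"cohesin": frame(cohesin), "PRC1": frame(prc1), "PRC2": frame(prc2)}


def generate_background_set(
    target_matrix: np.ndarray, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Random sequences matching the target set's length and GC distribution.

    Per-sequence GC values are sampled with replacement from the target
    set's observed GC values; lengths are identical to the targets'.
    """
    if target_matrix.shape[0] == 0:
        raise ValueError("target set must be non-empty")
    gc_values = ((target_matrix == 1) | (target_matrix == 2)).mean(axis=1)
    n = target_matrix.shape[0] if n is None else n
    gc = rng.choice(gc_values, size=n, replace=True)
    return _random_sequences(n, target_matrix.shape[1], gc, rng)


# ---------------------------------------------------------------------------
# Direct landscape generation for zone-heuristic calibration
# ---------------------------------------------------------------------------


def calibration_landscape(
    n_peaks: int,
    half_width_bp: int,
    score_floor: float,
    rng: np.random.Generator,
    ratio: float = 1.2,
    margin: float = 0.05,
    bg_score_range: tuple[float, float] = (70.0, 98.0),
    region_length: int = REGION_LENGTH,
) -> tuple[pd.DataFrame, dict]:
    """Directly generated top-hit landscape for zone-recovery calibration.

    Background top hits are uniform in position over the region with scores
    uniform over ``bg_score_range``; planted hits are uniform within
    +/- ``half_width_bp`` of the peakMax with scores uniform on
    [score_floor, 100] (planted sites outscore the background's upper
    range, as real bound sites do). The planted fraction is derived from
    the cumulative threshold rule's geometry: the per-bp planted density is
    set to ``(ratio - 1) * (1 + margin)`` times the per-bp background
    density of hits scoring at least ``score_floor``, which makes the
    20%-above-flank criterion first hold within a few score units of the
    floor while leaving enough positional excess to detect the distance
    boundaries.
    """
    lo, hi = bg_score_range
    if not lo <= score_floor <= hi:
        raise ValueError("score_floor must lie within bg_score_range")
    tail = (hi - score_floor) / (hi - lo)
    # the recovered zone overruns the planted half-width by ~1 bin per side,
    # diluting the planted per-bp density; size the fraction for that width
    overshoot_bp = 10.0
    c = (
        (ratio - 1.0) * (1.0 + margin) * tail
        * (2.0 * half_width_bp + overshoot_bp) / region_length
    )
    f = c / (1.0 + c)
    planted = rng.random(n_peaks) < f
    n_p = int(planted.sum())
    half = (region_length - 1) // 2
    d = rng.integers(-half, half + 1, size=n_peaks).astype(float)
    s = rng.uniform(lo, hi, size=n_peaks)
    d[planted] = rng.integers(-half_width_bp, half_width_bp + 1, size=n_p)
    s[planted] = rng.uniform(score_floor, hi, size=n_p)
    landscape = pd.DataFrame(
        {
            "has_motif": True,
            "signed_distance": d,
            "rel_score": s,
            "strand": "+",
            "start_offset": np.nan,
            "planted": planted,
        }
    )
    landscape.index.name = "peak_id"
    info = {"planted_fraction": f, "n_planted": n_p}
    return landscape, info
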