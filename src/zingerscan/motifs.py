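"""Position frequency/weight matrix models and motif scanning.

A :class:`PFM` holds raw binding-site counts over the DNA alphabet; a
:class:`PWM` is its log-odds transform used to score sequence windows on a
0-100 relative scale (100 = the matrix's best possible word, 0 = its worst).
Scanning reports hits on both strands above a relative-score threshold and
resolves overlaps greedily: two retained hits may share at most one fifth of
the matrix width, so a 7 bp motif can overlap a neighbour by at most 1 bp.

Column-shuffled null matrices (edge columns held fixed, since matrix flanks
carry little information) support significance calibration of enrichment
frequencies.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# N is encoded as 4 and scores as the column-minimum contribution.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4

# reverse complement of encoded bases; N stays N
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class MotifFormatError(ValueError):
    """Raised for malformed PFM text."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string (case-insensitive) as uint8 codes 0-4."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@dataclass
class PFM:
    """Position frequency matrix: per-position base counts of aligned sites.

    ``counts`` has shape (4, L) with rows in A, C, G, T order.
    """

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise MotifFormatError("PFM counts must be a 4 x L matrix")
        if (self.counts < 0).any():
            raise MotifFormatError("PFM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise MotifFormatError("every PFM column must have positive total")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        c = self.counts + pseudocount
        return c / c.sum(axis=0, keepdims=True)


@dataclass
class PWM:
    """Log-odds weight matrix (bits) with relative-score bookkeeping."""

    id: str
    name: str
    weights: np.ndarray
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("PWM weights must be a 4 x L matrix")
        self.min_score = float(self.weights.min(axis=0).sum())
        self.max_score = float(self.weights.max(axis=0).sum())
        if not self.max_score > self.min_score:
            raise ValueError("degenerate PWM: max score equals min score")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def extended_weights(self) -> np.ndarray:
        """Weights with a 5th row for N = per-column minimum contribution."""
        return np.vstack([self.weights, self.weights.min(axis=0)])

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.name, self.weights[::-1, ::-1])


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence within a scanned region.

    ``start`` is the 0-based offset of the window; ``signed_distance`` (motif
    midpoint minus the region's peakMax position) is filled in by landscape
    code once a reference point is known.
    """

    start: int
    strand: str
    rel_score: float
    width: int
    peak_id: str | None = None
    signed_distance: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.width

    def midpoint(self) -> int:
        return self.start + self.width // 2


# ---------------------------------------------------------------------------
# JASPAR raw PFM text
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*(?:([ACGTacgt])\s*)?\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def parse_jaspar_pfm(text: str) -> PFM:
    """Parse one JASPAR raw-text PFM record.

    Accepts both the bare 4-row dialect and the ``A [ 1 2 3 ]`` decorated
    dialect. The header line is ``>ID name``; rows may appear in any labelled
    order and are returned in A, C, G, T order.
    """
    records = parse_jaspar_file(text)
    if len(records) != 1:
        raise MotifFormatError(f"expected one PFM record, found {len(records)}")
    return records[0]


def parse_jaspar_file(text: str) -> list[PFM]:
    """Parse a concatenation of JASPAR raw PFM records."""
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    records: list[PFM] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise MotifFormatError(f"expected '>' header, got: {header!r}")
        parts = header[1:].strip().split(None, 1)
        pfm_id = parts[0] if parts else ""
        name = parts[1] if len(parts) > 1 else ""
        i += 1
        rows: dict[str, list[float]] = {}
        order: list[str] = []
        while i < len(lines) and not lines[i].startswith(">") and len(order) < 4:
            m = _ROW_RE.match(lines[i])
            if m is None:
                raise MotifFormatError(f"unparseable PFM row: {lines[i]!r}")
            label = (m.group(1) or BASES[len(order)]).upper()
            try:
                values = [float(x) for x in m.group(2).split()]
            except ValueError as exc:
                raise MotifFormatError(f"bad number in row: {lines[i]!r}") from exc
            if label in rows:
                raise MotifFormatError(f"duplicate row for base {label}")
            rows[label] = values
            order.append(label)
            i += 1
        if set(rows) != set(BASES):
            raise MotifFormatError(
                f"PFM record {pfm_id!r} needs exactly rows A,C,G,T; got {sorted(rows)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise MotifFormatError(f"ragged PFM columns in record {pfm_id!r}")
        counts = np.array([rows[b] for b in BASES], dtype=float)
        if counts.shape[1] < 4:
            raise MotifFormatError("PFM must have at least 4 columns")
        records.append(PFM(pfm_id, name, counts))
    return records


def write_jaspar_pfm(pfm: PFM, decorated: bool = True) -> str:
    """Serialize a PFM in JASPAR raw text (round-trips with the parser)."""
    out = _io.StringIO()
    out.write(f">{pfm.id} {pfm.name}".rstrip() + "\n")
    for i, base in enumerate(BASES):
        vals = " ".join(f"{v:g}" for v in pfm.counts[i])
        out.write(f"{base} [ {vals} ]\n" if decorated else vals + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Information content and log-odds conversion
# ---------------------------------------------------------------------------


def information_content(pfm: PFM, pseudocount: float = 0.0) -> float:
    """Total information content in bits: sum over columns of 2 - H(column)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    freqs = pfm.frequencies(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=0)
    return float((2.0 - entropy).sum())


def pfm_to_pwm(
    pfm: PFM,
    background: np.ndarray | None = None,
    pseudocount: float | str = "sqrt_n",
) -> PWM:
    """Convert counts to a log-odds PWM in bits.

    The default pseudocount follows the TFBS-module convention: each base b
    receives ``p_b * sqrt(N)`` extra counts where N is the column total, i.e.

        w[b, j] = log2( (c[b, j] + p_b*sqrt(N_j)) / (N_j + sqrt(N_j)) / p_b )

    Passing a number instead uses that many total pseudo-counts per column,
    distributed by the background.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    bg = bg / bg.sum()
    n = pfm.column_totals()
    if (n <= 0).any():
        raise ValueError("zero-total PFM column")
    if pseudocount == "sqrt_n":
        k = np.sqrt(n)
    else:
        k = np.full_like(n, float(pseudocount))
    probs = (pfm.counts + bg[:, None] * k[None, :]) / (n + k)[None, :]
    weights = np.log2(probs / bg[:, None])
    return PWM(pfm.id, pfm.name, weights)


def relative_score(pwm: PWM, word: str) -> float:
    """Score a single word of length L on the 0-100 relative scale."""
    codes = encode_sequence(word)
    if codes.shape[0] != pwm.width:
        raise ValueError(f"word length {codes.shape[0]} != matrix width {pwm.width}")
    raw = float(pwm.extended_weights()[codes, np.arange(pwm.width)].sum())
    return 100.0 * (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Relative scores of every window on both strands.

    Returns an array of shape (n_windows, 2); column 0 is the + strand,
    column 1 the - strand (reverse-complement matrix on the same window).
    """
    return batch_window_scores(pwm, codes[None, :])[0]


def batch_window_scores(pwm: PWM, matrix: np.ndarray) -> np.ndarray:
    """Vectorized window scoring of many equal-length sequences.

    ``matrix`` is (n_seqs, seq_len) uint8-coded; result is
    (n_seqs, n_windows, 2) relative scores, empty when seq_len < L.
    """
    L = pwm.width
    n_seqs, seq_len = matrix.shape
    n_win = seq_len - L + 1
    if n_win <= 0:
        return np.empty((n_seqs, 0, 2), dtype=float)
    fwd = pwm.extended_weights()
    rev = pwm.reverse_complement().extended_weights()
    raw = np.zeros((n_seqs, n_win, 2), dtype=float)
    idx = np.asarray(matrix, dtype=np.intp)
    for k in range(L):
        col = idx[:, k : k + n_win]
        raw[:, :, 0] += fwd[col, k]
        raw[:, :, 1] += rev[col, k]
    return 100.0 * (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


def _greedy_filter(
    starts: np.ndarray,
    strands: np.ndarray,
    scores: np.ndarray,
    width: int,
    max_overlap: int,
) -> list[int]:
    """Greedy retention by descending score; ties leftmost then + strand.

    Returns indices into the candidate arrays, in retention order.
    """
    order = np.lexsort((strands, starts, -scores))
    kept: list[int] = []
    kept_starts: list[int] = []
    for idx in order:
        s = int(starts[idx])
        ok = True
        for ks in kept_starts:
            if width - abs(s - ks) > max_overlap:
                ok = False
                break
        if ok:
            kept.append(int(idx))
            kept_starts.append(s)
    return kept


def scan_sequence(
    pwm: PWM,
    sequence: str | np.ndarray,
    score_threshold: float,
    overlap_fraction: float = 0.2,
) -> list[MotifHit]:
    """Find non-redundant motif hits above a relative-score threshold.

    Hits are collected on both strands, then filtered greedily by descending
    score so that any two retained hits overlap by at most
    ``floor(L * overlap_fraction)`` bp. Windows containing N contribute the
    column-minimum weight at those positions and therefore rarely pass.
    A sequence shorter than the matrix yields an empty list.
    """
    if not 0 <= score_threshold <= 100:
        raise ValueError("score_threshold must lie in [0, 100]")
    codes = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    rel = window_scores(pwm, codes)
    if rel.size == 0:
        return []
    cand = np.argwhere(rel >= score_threshold)
    if cand.size == 0:
        return []
    starts = cand[:, 0]
    strands = cand[:, 1]
    scores = rel[starts, strands]
    max_overlap = int(pwm.width * overlap_fraction)
    kept = _greedy_filter(starts, strands, scores, pwm.width, max_overlap)
    hits = [
        MotifHit(
            start=int(starts[i]),
            strand="+-"[strands[i]],
            rel_score=float(scores[i]),
            width=pwm.width,
        )
        for i in kept
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_batch(
    pwm: PWM,
    matrix: np.ndarray,
    score_threshold: float,
    overlap_fraction: float = 0.2,
) -> list[list[MotifHit]]:
    """`scan_sequence` over the rows of an encoded sequence matrix."""
    rel = batch_window_scores(pwm, matrix)
    max_overlap = int(pwm.width * overlap_fraction)
    out: list[list[MotifHit]] = []
    for r in range(matrix.shape[0]):
        cand = np.argwhere(rel[r] >= score_threshold)
        if cand.size == 0:
            out.append([])
            continue
        starts, strands = cand[:, 0], cand[:, 1]
        scores = rel[r][starts, strands]
        kept = _greedy_filter(starts, strands, scores, pwm.width, max_overlap)
        hits = [
            MotifHit(int(starts[i]), "+-"[strands[i]], float(scores[i]), pwm.width)
            for i in kept
        ]
        hits.sort(key=lambda h: (h.start, h.strand))
        out.append(hits)
    return out


# ---------------------------------------------------------------------------
# Column shuffling
# ---------------------------------------------------------------------------


def default_fixed_edge_columns(width: int, wide_width: int = 18) -> int:
    """Edge columns held fixed when shuffling: 2, or 3 for wide matrices."""
    return 3 if width >= wide_width else 2


def shuffle_pfm(
    pfm: PFM,
    fixed_edge_columns: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> PFM:
    """Permute internal PFM columns, holding low-information edges fixed.

    The column multiset (and hence information content) is preserved exactly.
    """
    fe = (
        default_fixed_edge_columns(pfm.width)
        if fixed_edge_columns is None
        else int(fixed_edge_columns)
    )
    if fe < 0:
        raise ValueError("fixed_edge_columns must be >= 0")
    n_internal = pfm.width - 2 * fe
    if n_internal < 1:
        raise ValueError(
            f"matrix width {pfm.width} too small for {fe} fixed edge columns per side"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = gen.permutation(n_internal)
    counts = pfm.counts.copy()
    counts[:, fe : fe + n_internal] = counts[:, fe + perm]
    return PFM(pfm.id, f"{pfm.name}_shuffled" if pfm.name else "shuffled", counts)
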