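"""Peak-file and sequence I/O plus peak-length normalization.

Peaks are handled as pandas DataFrames with 0-based half-open coordinates
and a ``peakmax`` column: for narrowPeak the summit offset (column 10) gives
the peakMax, falling back to the interval midpoint when the offset is -1;
broadPeak and BED6 use the midpoint. The peak score prefers the q-value
column when assigned (> -1) and the p-value column otherwise. Analyses run
on regions trimmed/extended to a constant length centred on the peakMax
(401 bp for enrichment scoring, 1001 bp for landscapes).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import motifs as _motifs

logger = logging.getLogger("zingerscan")

PEAK_FORMATS = ("bed6", "narrowPeak", "broadPeak")
_N_FIELDS = {"bed6": 6, "narrowPeak": 10, "broadPeak": 9}


class PeakFormatError(ValueError):
    """Raised for malformed peak files, with the offending line number."""


def read_peaks(path, fmt: str, dataset_id: str | None = None,
               tf: str | None = None, cell_line: str | None = None) -> pd.DataFrame:
    """Read a BED6 / ENCODE narrowPeak / broadPeak file.

    Returns a DataFrame with columns chrom, start, end, name, score, strand,
    peakmax (plus dataset labels when given). ``score`` is the q-value field
    when assigned (> -1), else the p-value field (narrowPeak/broadPeak), or
    the BED score column (bed6).
    """
    if fmt not in PEAK_FORMATS:
        raise PeakFormatError(f"unknown peak format {fmt!r}; expected one of {PEAK_FORMATS}")
    want = _N_FIELDS[fmt]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < want:
                raise PeakFormatError(
                    f"{path}:{lineno}: expected >= {want} tab-separated fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                if fmt == "bed6":
                    score = float(fields[4])
                    peakmax = (start + end) // 2
                else:
                    pvalue, qvalue = float(fields[7]), float(fields[8])
                    score = qvalue if qvalue > -1 else pvalue
                    if fmt == "narrowPeak":
                        offset = int(fields[9])
                        peakmax = start + offset if offset >= 0 else (start + end) // 2
                    else:
                        peakmax = (start + end) // 2
            except (ValueError, IndexError) as exc:
                raise PeakFormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if not start <= peakmax < end:
                raise PeakFormatError(f"{path}:{lineno}: peakMax outside [start, end)")
            rows.append((chrom, start, end, name, score, strand, peakmax))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "peakmax"]
    )
    for col, val in (("dataset_id", dataset_id), ("tf", tf), ("cell_line", cell_line)):
        if val is not None:
            df[col] = val
    return df


def normalize_length(
    peaks: pd.DataFrame,
    length: int,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Trim/extend peaks to an odd constant length centred on the peakMax.

    The region becomes [peakmax - (length-1)/2, peakmax + (length-1)/2 + 1).
    Regions running off a contig edge are dropped with a logged warning.
    """
    if length % 2 != 1:
        raise ValueError("length must be odd so the peakMax can sit at the centre")
    half = (length - 1) // 2
    out = peaks.copy()
    out["start"] = out["peakmax"] - half
    out["end"] = out["peakmax"] + half + 1
    keep = out["start"] >= 0
    if contig_lengths is not None:
        limits = out["chrom"].map(contig_lengths)
        keep &= out["end"] <= limits.fillna(np.inf)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("normalize_length(%d): dropped %d peak(s) at contig edges", length, n_drop)
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str] | tuple[list[str], np.ndarray]) -> None:
    """Write sequences (mapping, or (ids, encoded matrix)) as FASTA."""
    if isinstance(sequences, dict):
        items = sequences.items()
    else:
        ids, matrix = sequences
        items = ((i, _motifs.decode_sequence(row)) for i, row in zip(ids, matrix))
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """Write peaks as ENCODE narrowPeak (summit offset from peakmax)."""
    with open(path, "w") as fh:
        for _, row in peaks.iterrows():
            offset = int(row["peakmax"] - row["start"])
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        str(int(row["start"])),
                        str(int(row["end"])),
                        str(row.get("peak_id", row.get("name", "."))),
                        "0",
                        ".",
                        f"{row['score']:.4f}",
                        "-1",
                        f"{row['score']:.4f}",
                        str(offset),
                    ]
                )
                + "\n"
            )


def hits_to_bed6(hits, chrom: str, region_start: int = 0) -> pd.DataFrame:
    """Motif hits as BED6 rows (score = relative score x 10, rounded)."""
    rows = [
        (
            chrom,
            region_start + h.start,
            region_start + h.end,
            h.peak_id or ".",
            int(round(h.rel_score * 10)),
            h.strand,
        )
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED-like frame (first columns chrom/start/end...) as TSV."""
    df.to_csv(path, sep="\t", header=False, index=False)
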