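"""Reading aligned reads from BED files and binning them genome-wide.

Reads are reduced to a single genomic position — the 5' alignment start
shifted ``shift`` bp in the direction of alignment, which moves both strands
toward the fragment center — and tallied into fixed-width bins.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GenomeTable, RunConfig

log = logging.getLogger(__name__)

FOREGROUND = "foreground"
CONTROL = "control"


@dataclass
class ReadSet:
    """Aligned reads of one experiment, grouped per chromosome.

    ``reads[chrom]`` is a tuple of arrays ``(starts, ends, is_fwd)`` with
    BED half-open coordinates; ``is_fwd`` is True for the + strand.
    """

    reads: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    t: int
    role: str
    total_reads: int
    dropped_unknown_chrom: int = 0

    def __post_init__(self) -> None:
        assert self.total_reads == sum(len(s) for s, _, _ in self.reads.values())


@dataclass
class BinnedTrack:
    """Per-chromosome vectors of shifted-read counts per bin."""

    counts: dict[str, np.ndarray]
    t: int
    role: str
    total_reads: int
    bin_size: int
    dropped_off_end: int = 0

    @property
    def total_binned(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))

    def mean_per_bin(self) -> float:
        """Genome-wide average number of reads per bin."""
        return self.total_binned / self.n_bins


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_aligned_reads(
    path, genome: GenomeTable, t: int, role: str = FOREGROUND, dedup: bool = False
) -> ReadSet:
    """Load a BED3/BED6 file (plain or gzip) of aligned reads.

    Reads on chromosomes absent from ``genome`` are dropped (counted and
    logged).  A missing strand column defaults to '+'.  Malformed
    coordinates raise with the offending line number; an empty file is an
    error because a time point with zero reads is unusable.
    """
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(
                fh,
                sep=r"\s+",
                header=None,
                comment="#",
                usecols=[0, 1, 2, 3, 4, 5],
                names=["chrom", "start", "end", "name", "score", "strand"],
                dtype={"chrom": str, "strand": str},
                engine="python",
            )
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty read file") from None
        except ValueError:
            # fewer than 6 columns: retry as BED3
            fh.seek(0)
            df = pd.read_csv(
                fh,
                sep=r"\s+",
                header=None,
                comment="#",
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
                dtype={"chrom": str},
                engine="python",
            )
            df["strand"] = "+"
    if len(df) == 0:
        raise ValueError(f"{path}: empty read file")

    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}:{lineno}: non-integer {col} field")
        df[col] = vals.astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}:{lineno}: start >= end")

    if "strand" not in df.columns:
        df["strand"] = "+"
    df["strand"] = df["strand"].fillna("+")

    known = df["chrom"].isin(genome.chroms)
    dropped = int((~known).sum())
    if dropped:
        log.info("%s: dropped %d reads on chromosomes absent from the genome table", path, dropped)
    df = df[known]

    if dedup:
        df = df.drop_duplicates(subset=["chrom", "start", "end", "strand"])

    reads: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    total = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        clen = genome.length(chrom)
        if starts.min(initial=0) < 0 or ends.max(initial=0) > clen:
            bad = (starts < 0) | (ends > clen)
            raise ValueError(f"{path}: {bad.sum()} reads outside chromosome {chrom} bounds")
        is_fwd = (sub["strand"] != "-").to_numpy(bool)
        reads[chrom] = (starts, ends, is_fwd)
        total += len(starts)
    return ReadSet(reads=reads, t=t, role=role, total_reads=total, dropped_unknown_chrom=dropped)


def bin_reads(reads: ReadSet, config: RunConfig, genome: GenomeTable) -> BinnedTrack:
    """Count shifted read positions per fixed-width bin.

    The counted position is ``start + shift`` for + reads and
    ``(end - 1) - shift`` for - reads (the 5' end shifted toward the
    fragment center).  Positions shifted outside ``[0, chrom_len)`` are
    dropped.
    """
    bin_size, shift = config.bin_size, config.shift
    counts: dict[str, np.ndarray] = {}
    dropped = 0
    for chrom in genome.chroms:
        n_bins = genome.n_bins(chrom, bin_size)
        if chrom not in reads.reads:
            counts[chrom] = np.zeros(n_bins, dtype=np.int64)
            continue
        starts, ends, is_fwd = reads.reads[chrom]
        pos = np.where(is_fwd, starts + shift, ends - 1 - shift)
        ok = (pos >= 0) & (pos < genome.length(chrom))
        dropped += int((~ok).sum())
        counts[chrom] = np.bincount(pos[ok] // bin_size, minlength=n_bins).astype(np.int64)
    return BinnedTrack(
        counts=counts,
        t=reads.t,
        role=reads.role,
        total_reads=reads.total_reads,
        bin_size=bin_size,
        dropped_off_end=dropped,
    )
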