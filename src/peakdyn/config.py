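"""Run configuration and genome table.

Three analysis modes bundle option presets for different assay types:
``punctate`` for accessibility assays (ATAC-seq, DNase-seq), ``narrow`` for
ChIP-seq of narrow histone marks, and ``broad`` for broad marks and Pol2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

MODES = ("punctate", "narrow", "broad")

#: default bin width in bp per mode
_BIN_SIZE = {"punctate": 200, "narrow": 200, "broad": 500}
#: default minimum dynamics prior per mode
_MIN_PRIOR = {"punctate": 0.05, "narrow": 0.0, "broad": 0.0}


@dataclass(frozen=True)
class RunConfig:
    """All tunable options of a run.

    Parameters
    ----------
    mode
        One of ``punctate``, ``narrow``, ``broad``.  Sets defaults for
        ``bin_size`` (200 bp narrow/punctate, 500 bp broad), ``min_prior``
        (0.05 punctate, 0 otherwise) and whether blocks are split at
        persistent internal gaps (never in broad mode).
    bin_size
        Width in bp of the non-overlapping genomic bins.
    shift
        Number of bp each read is shifted in the direction of alignment
        before being assigned to a bin (toward the fragment center).
    fdr
        Benjamini–Hochberg false discovery rate for the per-bin Poisson
        enrichment test and for the peak presence test.
    relaxed_p
        Weaker raw p-value threshold used to extend significant intervals.
    max_gap
        Maximum number of non-significant bins bridged when joining
        intervals, and the minimum internal gap length that triggers
        block splitting.
    block_extend
        Number of bins each block is extended on both sides (capped at the
        midpoint to the neighboring block).
    min_prior
        Lower clamp for each dynamics prior probability.
    background_windows
        Window widths in bp over which local control read rates are
        averaged for the expected background rate.
    dedup
        Drop duplicate read records (same chrom/start/end/strand).  Off by
        default: every alignment record counts once.
    """

    mode: str = "narrow"
    bin_size: int | None = None
    shift: int | None = None
    fdr: float = 0.05
    relaxed_p: float = 0.15
    max_gap: int = 3
    block_extend: int = 5
    min_prior: float | None = None
    background_windows: tuple[int, ...] = (1000, 5000, 20000)
    seed: int = 0
    n_threads: int = 1
    dedup: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.bin_size is None:
            object.__setattr__(self, "bin_size", _BIN_SIZE[self.mode])
        if self.shift is None:
            object.__setattr__(self, "shift", 100)
        if self.min_prior is None:
            object.__setattr__(self, "min_prior", _MIN_PRIOR[self.mode])
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if not 0.0 < self.relaxed_p < 1.0:
            raise ValueError("relaxed_p must be in (0, 1)")
        if self.max_gap < 0 or self.block_extend < 0:
            raise ValueError("max_gap and block_extend must be non-negative")
        if not 0.0 <= self.min_prior < 1 / 3:
            raise ValueError("min_prior must be in [0, 1/3)")
        if any(w <= 0 for w in self.background_windows):
            raise ValueError("background windows must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome names and lengths (bp)."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("duplicate chromosome names")
        if any(n <= 0 for n in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        object.__setattr__(self, "_index", dict(zip(self.chroms, self.lengths)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def __len__(self) -> int:
        return len(self.chroms)

    def length(self, chrom: str) -> int:
        return self._index[chrom]

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self._index[chrom] // bin_size)

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeTable":
        """Parse a two-column (name, length) chromosome sizes file."""
        chroms, lengths = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name length'")
                try:
                    n = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
                chroms.append(parts[0])
                lengths.append(n)
        if not chroms:
            raise ValueError(f"{path}: empty chromosome sizes file")
        return cls(tuple(chroms), tuple(lengths))
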