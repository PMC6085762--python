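"""Stage 1: find genomic blocks that may contain signal-enrichment peaks.

Per time point, each bin is tested for enrichment against a conservative
local Poisson background rate; significant bins are merged into intervals,
extended through weakly significant stretches, gap-joined, and finally
grouped across time points into blocks — the units over which the boundary
dynamics model is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import GenomeTable, RunConfig
from .genomic_io import BinnedTrack


@dataclass
class ExpectedRateTrack:
    """Expected background reads per bin (lambda), per chromosome.

    Rates are floored at the genome-wide mean foreground reads per bin and
    at one read, so lambda >= 1 always and log(lambda) >= 0.
    """

    rates: dict[str, np.ndarray]
    t: int


@dataclass(frozen=True)
class EnrichedInterval:
    """A maximal run of enriched bins at one time point (inclusive bins)."""

    chrom: str
    start_bin: int
    end_bin: int
    t: int

    def __post_init__(self) -> None:
        assert self.start_bin <= self.end_bin


@dataclass(eq=False)
class Block:
    """A contiguous bin range holding count/rate matrices for all T time points.

    ``counts`` and ``rates`` have shape (T, N) with N = end_bin - start_bin + 1.
    ``intervals[t]`` lists the member enriched intervals (genome bin coords).
    """

    chrom: str
    start_bin: int
    end_bin: int
    counts: np.ndarray
    rates: np.ndarray
    intervals: list[list[tuple[int, int]]]
    block_id: int = -1

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def n_times(self) -> int:
        return self.counts.shape[0]

    def __post_init__(self) -> None:
        assert self.counts.shape == self.rates.shape == (self.n_times, self.n_bins)
        assert (self.counts >= 0).all() and (self.rates > 0).all()


def expected_rate(
    fg: BinnedTrack, ctrl: BinnedTrack | None, config: RunConfig
) -> ExpectedRateTrack:
    """Conservative expected background rate per bin.

    With a control track, for each window width w the control reads in the
    w-bp window centered on the bin are scaled by (total_fg/total_ctrl) *
    (bin_size/w); the rate is the maximum over windows, then floored at the
    genome-wide mean foreground reads per bin and at one read.  Windows are
    truncated at chromosome ends without rescaling.
    """
    genome_mean = fg.mean_per_bin()
    floor = max(genome_mean, 1.0)
    rates: dict[str, np.ndarray] = {}
    if ctrl is not None:
        total_ctrl = ctrl.total_binned
        if total_ctrl == 0:
            raise ValueError("control track has zero reads")
        ratio = fg.total_binned / total_ctrl
    for chrom, fg_counts in fg.counts.items():
        n = len(fg_counts)
        lam = np.full(n, floor)
        if ctrl is not None:
            c = ctrl.counts[chrom]
            cum = np.concatenate([[0], np.cumsum(c)])
            for w in config.background_windows:
                nw = max(1, w // fg.bin_size)
                lo = np.clip(np.arange(n) - (nw - 1) // 2, 0, n)
                hi = np.clip(np.arange(n) + nw // 2 + 1, 0, n)
                window_total = cum[hi] - cum[lo]
                lam = np.maximum(lam, ratio * (fg.bin_size / w) * window_total)
        rates[chrom] = lam
    return ExpectedRateTrack(rates=rates, t=fg.t)


def poisson_upper_tail(o, lam):
    """P(X >= o) for X ~ Poisson(lam); vectorized, p = 1 for o = 0."""
    return stats.poisson.sf(np.asarray(o) - 1, lam)


def significant_bin_masks(
    fg: BinnedTrack, rates: ExpectedRateTrack, config: RunConfig
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Strict (BH at config.fdr, genome-wide) and relaxed (raw p <= relaxed_p)
    per-bin significance masks for one time point."""
    chroms = list(fg.counts)
    pvals = {c: poisson_upper_tail(fg.counts[c], rates.rates[c]) for c in chroms}
    flat = np.concatenate([pvals[c] for c in chroms])
    reject = multipletests(flat, alpha=config.fdr, method="fdr_bh")[0]
    strict, relaxed = {}, {}
    offset = 0
    for c in chroms:
        n = len(pvals[c])
        strict[c] = reject[offset : offset + n]
        relaxed[c] = pvals[c] <= config.relaxed_p
        offset += n
    return strict, relaxed


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def build_intervals(
    strict: dict[str, np.ndarray],
    relaxed: dict[str, np.ndarray],
    config: RunConfig,
    t: int,
) -> list[EnrichedInterval]:
    """Seed intervals from strict runs, extend through contiguous relaxed
    bins, then join intervals separated by <= max_gap non-relaxed bins."""
    out: list[EnrichedInterval] = []
    for chrom, smask in strict.items():
        if not smask.any():
            continue
        ext_mask = relaxed[chrom] | smask
        # extended interval = the relaxed run containing >= 1 strict bin
        extended = [(s, e) for s, e in _runs(ext_mask) if smask[s : e + 1].any()]
        merged = [extended[0]]
        for s, e in extended[1:]:
            if s - merged[-1][1] - 1 <= config.max_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        out.extend(EnrichedInterval(chrom, s, e, t) for s, e in merged)
    return out


def group_into_blocks(
    intervals: list[EnrichedInterval],
    fg_tracks: list[BinnedTrack],
    rate_tracks: list[ExpectedRateTrack],
    genome: GenomeTable,
    config: RunConfig,
) -> list[Block]:
    """Group bin-overlapping intervals across time points into blocks and
    extend each block by block_extend bins per side, stopping at the
    midpoint to the neighboring block and at chromosome ends."""
    T = len(fg_tracks)
    blocks: list[Block] = []
    by_chrom: dict[str, list[EnrichedInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in genome.chroms:
        ivs = sorted(by_chrom.get(chrom, []), key=lambda iv: (iv.start_bin, iv.end_bin))
        if not ivs:
            continue
        n_bins = genome.n_bins(chrom, config.bin_size)
        # connected components of the bin-overlap graph: chain-merge sorted spans
        comps: list[tuple[int, int, list[EnrichedInterval]]] = []
        for iv in ivs:
            if comps and iv.start_bin <= comps[-1][1]:
                s, e, members = comps[-1]
                comps[-1] = (s, max(e, iv.end_bin), members + [iv])
            else:
                comps.append((iv.start_bin, iv.end_bin, [iv]))
        for k, (s, e, members) in enumerate(comps):
            lo = max(0, s - config.block_extend)
            if k > 0:
                prev_end = comps[k - 1][1]
                lo = max(lo, (prev_end + s) // 2 + 1)
            hi = min(n_bins - 1, e + config.block_extend)
            if k + 1 < len(comps):
                next_start = comps[k + 1][0]
                hi = min(hi, (e + next_start) // 2)
            counts = np.stack([fg_tracks[t].counts[chrom][lo : hi + 1] for t in range(T)])
            rates = np.stack([rate_tracks[t].rates[chrom][lo : hi + 1] for t in range(T)])
            per_t: list[list[tuple[int, int]]] = [[] for _ in range(T)]
            for iv in members:
                per_t[iv.t].append((iv.start_bin, iv.end_bin))
            blocks.append(Block(chrom, lo, hi, counts, rates, per_t))
    return blocks


def split_block(block: Block, config: RunConfig) -> list[Block]:
    """Split a block at persistent internal gaps (narrow/punctate modes).

    For every time point with >= 2 member intervals separated by a gap
    longer than max_gap, the qualifying gap ranges are collected; the gap
    sets of all such time points are intersected, and the block is cut
    inside each nonempty intersection at the bin with the lowest mean
    foreground count across time points (ties -> leftmost).  The cut bin
    ends the left sub-block.  Broad mode: identity.
    """
    if config.mode == "broad":
        return [block]
    T, N = block.n_times, block.n_bins
    gap_masks = []
    for t in range(T):
        ivs = sorted(block.intervals[t])
        qual = np.zeros(N, dtype=bool)
        any_gap = False
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            gap_len = s2 - e1 - 1
            if gap_len > config.max_gap:
                any_gap = True
                lo = max(e1 + 1 - block.start_bin, 0)
                hi = min(s2 - 1 - block.start_bin, N - 1)
                if lo <= hi:
                    qual[lo : hi + 1] = True
        if any_gap:
            gap_masks.append(qual)
    if not gap_masks:
        return [block]
    inter = np.logical_and.reduce(gap_masks)
    if not inter.any():
        return [block]
    mean_counts = block.counts.mean(axis=0)
    cuts = []
    for s, e in _runs(inter):
        cuts.append(s + int(np.argmin(mean_counts[s : e + 1])))
    pieces = []
    lo = 0
    for cut in sorted(cuts):
        pieces.append((lo, cut))
        lo = cut + 1
    pieces.append((lo, N - 1))
    pieces = [(a, b) for a, b in pieces if a <= b]
    out = []
    for a, b in pieces:
        glo, ghi = block.start_bin + a, block.start_bin + b
        per_t = []
        for t in range(T):
            clipped = [
                (max(s, glo), min(e, ghi))
                for s, e in block.intervals[t]
                if s <= ghi and e >= glo
            ]
            per_t.append(clipped)
        out.append(
            Block(
                block.chrom,
                glo,
                ghi,
                block.counts[:, a : b + 1],
                block.rates[:, a : b + 1],
                per_t,
            )
        )
    return out


def find_blocks(
    fg_tracks: list[BinnedTrack],
    ctrl_tracks: list[BinnedTrack] | None,
    genome: GenomeTable,
    config: RunConfig,
) -> list[Block]:
    """Full stage-1 pipeline: rates, tests, intervals, blocks, splitting."""
    T = len(fg_tracks)
    rate_tracks = [
        expected_rate(fg_tracks[t], ctrl_tracks[t] if ctrl_tracks else None, config)
        for t in range(T)
    ]
    intervals: list[EnrichedInterval] = []
    for t in range(T):
        strict, relaxed = significant_bin_masks(fg_tracks[t], rate_tracks[t], config)
        intervals.extend(build_intervals(strict, relaxed, config, t))
    blocks = group_into_blocks(intervals, fg_tracks, rate_tracks, genome, config)
    out: list[Block] = []
    for b in blocks:
        out.extend(split_block(b, config))
    for i, b in enumerate(out):
        b.block_id = i
    return out
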