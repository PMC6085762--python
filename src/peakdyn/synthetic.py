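"""Synthetic data with known ground truth, drawn from the generative model.

Two levels are supported: block-level sampling (counts straight from the
emission model, for inference and EM recovery tests) and read-level
datasets (BED files of single-end reads with planted peaks over a Poisson
background, for end-to-end pipeline tests).  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .block_finder import Block
from .config import GenomeTable
from .dynamics_model import (
    CONTRACT,
    DYNAMICS,
    EXPAND,
    STEADY,
    ModelParameters,
    save_parameters,
)

READ_LENGTH = 36  # bp, single-end


@dataclass
class TruthRecord:
    """Ground truth for one planted block."""

    block_index: int
    start_bin: int
    n_bins: int
    l: np.ndarray  # (T,)
    r: np.ndarray  # (T,)
    dyn_left: np.ndarray  # (T-1,)
    dyn_right: np.ndarray  # (T-1,)
    truncated: bool = False
    param_set_id: str = "default"

    def __post_init__(self) -> None:
        assert (self.l <= self.r + 1).all()


@dataclass
class SimSpec:
    """Conditions of a read-level simulation."""

    params: ModelParameters
    n_blocks: int
    block_len_range: tuple[int, int] = (20, 60)  # bins
    genome_length: int = 10_000_000  # bp
    background_rate: float = 0.5  # expected background reads per bin
    bin_size: int = 200
    shift: int = 100  # 5' ends are offset so that this shift re-centers them
    min_gap_bins: int = 30
    max_gap_bins: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.block_len_range
        assert 1 <= lo <= hi
        assert self.n_blocks >= 0 and self.genome_length > 0
        assert self.background_rate > 0 and self.bin_size > 0


def _sample_nb(rng: np.random.Generator, mu, delta, size=None):
    return rng.negative_binomial(delta, delta / (delta + mu), size=size)


def sample_boundary_path(
    params: ModelParameters, N: int, rng: np.random.Generator, max_tries: int = 1000
):
    """Sample a valid boundary path and its dynamics from the model.

    The first pair is uniform over valid (l, r); each transition samples a
    dynamic from the prior and a jump from its distribution, rejecting
    moves that violate 1 <= l <= r + 1 <= N + 1 (after ``max_tries``
    rejections the move is truncated to the nearest valid configuration and
    the labels are recomputed from the realized jumps).
    """
    T = params.T
    while True:
        l0 = int(rng.integers(1, N + 2))
        r0 = int(rng.integers(0, N + 1))
        if l0 <= r0 + 1:
            break
    ls, rs = [l0], [r0]
    dl, dr = [], []
    truncated = False
    for t in range(T - 1):
        l_prev, r_prev = ls[-1], rs[-1]
        ok = False
        for _ in range(max_tries):
            d_left = int(rng.choice(3, p=params.pi[t]))
            d_right = int(rng.choice(3, p=params.pi[t]))
            jl = _sample_jump(params, t, d_left, rng)
            jr = _sample_jump(params, t, d_right, rng)
            l_new, r_new = l_prev - jl, r_prev + jr
            if 1 <= l_new <= r_new + 1 and 0 <= r_new <= N and l_new <= N + 1:
                ok = True
                break
        if not ok:
            truncated = True
            l_new = int(np.clip(l_prev - jl, 1, N + 1))
            r_new = int(np.clip(r_prev + jr, 0, N))
            if l_new > r_new + 1:
                l_new = r_new + 1
            d_left = _label(l_prev - l_new)
            d_right = _label(r_new - r_prev)
        ls.append(l_new)
        rs.append(r_new)
        dl.append(d_left)
        dr.append(d_right)
    return (
        np.array(ls), np.array(rs),
        np.array(dl, dtype=int), np.array(dr, dtype=int),
        truncated,
    )


def _sample_jump(params: ModelParameters, t: int, d: int, rng: np.random.Generator) -> int:
    if d == STEADY:
        return 0
    if d == EXPAND:
        return 1 + int(_sample_nb(rng, params.jump_mu[t, 0], params.jump_delta[t, 0]))
    return -1 - int(_sample_nb(rng, params.jump_mu[t, 1], params.jump_delta[t, 1]))


def _label(j: int) -> int:
    return STEADY if j == 0 else (EXPAND if j > 0 else CONTRACT)


def sample_block(
    params: ModelParameters,
    N: int,
    rng: np.random.Generator,
    rates: np.ndarray | None = None,
    chrom: str = "chrS",
    start_bin: int = 0,
    block_index: int = 0,
) -> tuple[Block, TruthRecord]:
    """Sample one block: a boundary path, then per-bin NB counts.

    ``rates`` (T, N) defaults to 1 everywhere (no control track), matching
    the floor applied by the block finder.
    """
    T = params.T
    if rates is None:
        rates = np.ones((T, N))
    ls, rs, dl, dr, truncated = sample_boundary_path(params, N, rng)
    loglam = np.log(rates)
    counts = np.empty((T, N), dtype=np.int64)
    for t in range(T):
        mu_pk = np.exp(params.alpha[t] + params.gamma[t] * loglam[t])
        mu_bg = np.exp(params.beta[t] + params.gamma[t] * loglam[t])
        p = np.arange(1, N + 1)
        in_peak = (p >= ls[t]) & (p <= rs[t])
        mu = np.where(in_peak, mu_pk, mu_bg)
        counts[t] = _sample_nb(rng, mu, params.delta[t], size=N)
    block = Block(
        chrom=chrom,
        start_bin=start_bin,
        end_bin=start_bin + N - 1,
        counts=counts,
        rates=rates,
        intervals=[[] for _ in range(T)],
        block_id=block_index,
    )
    truth = TruthRecord(
        block_index=block_index,
        start_bin=start_bin,
        n_bins=N,
        l=ls,
        r=rs,
        dyn_left=dl,
        dyn_right=dr,
        truncated=truncated,
    )
    return block, truth


def sample_blocks(
    params: ModelParameters,
    n_blocks: int,
    block_len_range: tuple[int, int],
    seed: int,
) -> tuple[list[Block], list[TruthRecord]]:
    """Sample a training set of blocks with known truth (lambda = 1)."""
    rng = np.random.default_rng(seed)
    blocks, truths = [], []
    start = 0
    lo, hi = block_len_range
    for i in range(n_blocks):
        N = int(rng.integers(lo, hi + 1))
        b, tr = sample_block(params, N, rng, start_bin=start, block_index=i)
        blocks.append(b)
        truths.append(tr)
        start += N + 50
    return blocks, truths


def generate_read_dataset(spec: SimSpec, out_dir: str | Path) -> dict:
    """Write per-time-point foreground BED read files plus truth tables.

    Background reads are Poisson-scattered per bin at ``background_rate``;
    planted blocks replace the background with counts emitted by the model
    along a sampled boundary path.  Bin counts are realized as fixed-length
    reads with Bernoulli(0.5) strands whose 5' ends are placed so that
    shifting by ``spec.shift`` in the direction of alignment recovers a
    position uniform within the bin.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    T = params.T
    n_bins = spec.genome_length // spec.bin_size
    chrom = "chrS"

    # place blocks left to right with random gaps
    placements = []
    cursor = spec.max_gap_bins
    for i in range(spec.n_blocks):
        N = int(rng.integers(spec.block_len_range[0], spec.block_len_range[1] + 1))
        gap = int(rng.integers(spec.min_gap_bins, spec.max_gap_bins + 1))
        start = cursor + gap
        if start + N >= n_bins - spec.max_gap_bins:
            raise ValueError("genome too short for the requested number of blocks")
        placements.append((start, N))
        cursor = start + N

    truths = []
    block_counts = []
    for i, (start, N) in enumerate(placements):
        b, tr = sample_block(params, N, rng, start_bin=start, block_index=i)
        block_counts.append(b.counts)
        truths.append(tr)

    genome = GenomeTable((chrom,), (spec.genome_length,))
    paths = {"reads": [], "truth": str(out_dir / "truth.tsv"),
             "params": str(out_dir / "params.tsv"),
             "chrom_sizes": str(out_dir / "chrom.sizes")}
    in_block = np.zeros(n_bins, dtype=bool)
    for start, N in placements:
        in_block[start : start + N] = True
    for t in range(T):
        counts = rng.poisson(spec.background_rate, size=n_bins)
        counts[in_block] = 0
        for (start, N), bc in zip(placements, block_counts):
            counts[start : start + N] = bc[t]
        path = out_dir / f"reads_t{t + 1}.bed"
        _write_reads_bed(path, counts, spec, rng)
        paths["reads"].append(str(path))

    with open(paths["truth"], "w") as fh:
        cols = ["block_index", "start_bin", "n_bins", "truncated",
                "l", "r", "dyn_left", "dyn_right"]
        fh.write("\t".join(cols) + "\n")
        for tr in truths:
            fh.write(
                f"{tr.block_index}\t{tr.start_bin}\t{tr.n_bins}\t{int(tr.truncated)}\t"
                f"{','.join(map(str, tr.l))}\t{','.join(map(str, tr.r))}\t"
                f"{','.join(DYNAMICS[d] for d in tr.dyn_left)}\t"
                f"{','.join(DYNAMICS[d] for d in tr.dyn_right)}\n"
            )
    save_parameters(params, paths["params"])
    with open(paths["chrom_sizes"], "w") as fh:
        fh.write(f"{chrom}\t{spec.genome_length}\n")
    return {"paths": paths, "truths": truths, "genome": genome, "placements": placements}


def _write_reads_bed(path: Path, counts: np.ndarray, spec: SimSpec,
                     rng: np.random.Generator) -> None:
    bins = np.repeat(np.arange(len(counts)), counts)
    q = bins * spec.bin_size + rng.integers(0, spec.bin_size, size=len(bins))
    fwd = rng.random(len(bins)) < 0.5
    # 5' end such that shifting by spec.shift lands back on q
    starts = np.where(fwd, q - spec.shift, q + spec.shift - (READ_LENGTH - 1))
    ends = starts + READ_LENGTH
    ok = (starts >= 0) & (ends <= spec.genome_length)
    order = np.argsort(starts[ok], kind="stable")
    starts, ends, fwd = starts[ok][order], ends[ok][order], fwd[ok][order]
    with open(path, "w") as fh:
        for i, (s, e, f) in enumerate(zip(starts, ends, fwd)):
            fh.write(f"chrS\t{s}\t{e}\tread{i}\t0\t{'+' if f else '-'}\n")


def recovery_report(
    truths: list[TruthRecord],
    calls,
    true_params: ModelParameters | None = None,
    fit_params: ModelParameters | None = None,
) -> dict:
    """Summary metrics of a recovery run against ground truth.

    ``calls`` is a list of BlockCalls aligned with ``truths`` (same order).
    Reports a 3x3 dynamics confusion matrix (rows = planted, cols =
    called), boundary mean absolute error in bins over time points where
    both truth and call have a non-zero-length peak, and parameter errors
    when both parameter sets are given.
    """
    confusion = np.zeros((3, 3), dtype=np.int64)
    abs_err, n_bnd = 0.0, 0
    for tr, call in zip(truths, calls):
        for t in range(len(tr.dyn_left)):
            confusion[tr.dyn_left[t], call.left[t].label] += 1
            confusion[tr.dyn_right[t], call.right[t].label] += 1
        both = (tr.l <= tr.r) & (call.path.l <= call.path.r)
        abs_err += np.abs(tr.l[both] - call.path.l[both]).sum()
        abs_err += np.abs(tr.r[both] - call.path.r[both]).sum()
        n_bnd += 2 * int(both.sum())
    report = {
        "confusion": confusion,
        "accuracy": float(np.trace(confusion) / max(confusion.sum(), 1)),
        "boundary_mae": abs_err / max(n_bnd, 1),
    }
    if true_params is not None and fit_params is not None:
        report["pi_abs_err"] = np.abs(fit_params.pi - true_params.pi)
        report["peak_mean_rel_err"] = np.abs(
            np.exp(fit_params.alpha) / np.exp(true_params.alpha) - 1
        )
        report["bg_mean_rel_err"] = np.abs(
            np.exp(fit_params.beta) / np.exp(true_params.beta) - 1
        )
        report["jump_mean_rel_err"] = np.abs(fit_params.jump_mu / true_params.jump_mu - 1)
    return report
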