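"""Stage-2 prediction: peak presence, most likely boundaries and dynamics,
and browser-ready output tracks.

Prediction is two-step.  First, a peak presence test: the posterior
probability q of a zero-length peak is computed for every (block, time
point) pair and Benjamini-Hochberg control at the run FDR is applied to the
q values genome-wide; rejections are time points that carry a peak.
Second, conditioned on that mask (absent time points are constrained to
zero-length peaks), a max-product pass over the same DP lattice yields the
jointly most likely boundary path and dynamics labels, while a sum-product
pass under the same constraint yields exact per-side dynamics posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .block_finder import Block
from .config import GenomeTable, RunConfig
from .dynamics_model import (
    CONTRACT,
    DYNAMICS,
    EXPAND,
    STEADY,
    EmissionTable,
    ModelParameters,
    left_transition_matrix,
    valid_mask,
)
from .em_training import BlockPosteriors, e_step

log = logging.getLogger(__name__)

#: itemRgb values per color category
COLORS = {
    "FIRST": (100, 100, 100),  # dark gray: first peak of a block
    "STEADY": (180, 180, 180),  # light gray: steady on both sides
    "CONTRACT": (0, 0, 255),  # blue: >= 1 contracting side, none expanding
    "EXPAND": (255, 0, 0),  # red: >= 1 expanding side, none contracting
    "SINGLE": (255, 165, 0),  # orange: present at exactly one time point
    "OPPOSITE": (0, 0, 0),  # black: one side expands, the other contracts
}


@dataclass
class BoundaryPath:
    """Decoded per-time-point boundaries (1-based within the block).

    l[t] in [1, N+1], r[t] in [0, N], l <= r + 1; l = r + 1 marks a
    zero-length peak anchored at that boundary edge.
    """

    l: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        assert (self.l <= self.r + 1).all()

    def jumps(self) -> tuple[np.ndarray, np.ndarray]:
        """Signed left/right jumps (expansion positive) per transition."""
        return self.l[:-1] - self.l[1:], self.r[1:] - self.r[:-1]


@dataclass
class DynamicsCall:
    """MAP dynamic and posterior triple for one side of one transition."""

    side: str  # "L" or "R"
    t: int  # transition t -> t+1
    label: int  # STEADY / EXPAND / CONTRACT
    posterior: np.ndarray  # (3,) over DYNAMICS

    @property
    def label_name(self) -> str:
        return DYNAMICS[self.label]


@dataclass
class BlockCalls:
    """All stage-2 results for one block."""

    block: Block
    present: np.ndarray  # (T,) bool, from the presence test
    path: BoundaryPath
    left: list[DynamicsCall]
    right: list[DynamicsCall]
    colors: list[str | None]  # per t; None where no peak is emitted
    zero_len_posterior: np.ndarray  # (T,) q values


def peak_presence_masks(
    posteriors: list[BlockPosteriors], config: RunConfig
) -> np.ndarray:
    """BH-corrected presence decisions over all (block, t) pairs.

    q = posterior probability of a zero-length peak; small q -> confident
    peak.  Returns a (n_blocks, T) boolean array, True where a peak is
    called present.
    """
    q = np.stack([p.zero_len for p in posteriors])
    q = np.clip(q, 0.0, 1.0)
    reject = multipletests(q.ravel(), alpha=config.fdr, method="fdr_bh")[0]
    return reject.reshape(q.shape)


def _label_of_jump(j: int) -> int:
    return STEADY if j == 0 else (EXPAND if j > 0 else CONTRACT)


def decode_boundaries(
    block: Block,
    params: ModelParameters,
    present: np.ndarray,
    table: EmissionTable | None = None,
) -> tuple[BoundaryPath, list[DynamicsCall], list[DynamicsCall]]:
    """Most likely boundary path and dynamics, given the presence mask.

    Max-product over valid (l, r) states, jointly over boundary positions
    and dynamics labels (the three jump supports are disjoint, so each jump
    determines its dynamic).  Absent time points are constrained to
    zero-length states.  Ties are broken toward STEADY, then toward smaller
    total boundary movement, then toward the leftmost state.  Posteriors
    come from an exact sum-product pass under the same constraint.
    """
    if table is None:
        table = EmissionTable(block, params)
    N, T = table.N, table.T
    pairs_li, pairs_ri = np.nonzero(valid_mask(N))
    S = len(pairs_li)
    state_emis = [table.emission_matrix(t)[pairs_li, pairs_ri] for t in range(T)]
    diag = pairs_li == pairs_ri
    allowed_state = [np.ones(S, dtype=bool) if present[t] else diag for t in range(T)]

    score = state_emis[0] - 2.0 * np.log(N + 1)
    score = np.where(allowed_state[0], score, -np.inf)
    ptrs = []
    # tie-break key: fewer non-steady sides, then smaller |jL| + |jR|,
    # then smaller (leftmost) predecessor index
    jl = pairs_li[:, None] - pairs_li[None, :]
    jr = pairs_ri[None, :] - pairs_ri[:, None]
    ns = (jl != 0).astype(np.int64) + (jr != 0).astype(np.int64)
    mv = np.abs(jl) + np.abs(jr)
    # integer-exact composite key: (non-steady sides, movement, pred index)
    key = ((ns * (2 * N + 1) + mv) * S + np.arange(S)[:, None]).astype(float)
    for t in range(1, T):
        AL = left_transition_matrix(params, t - 1, N)
        TS = AL[pairs_li[:, None], pairs_li[None, :]] + AL[pairs_ri[None, :], pairs_ri[:, None]]
        tot = score[:, None] + TS
        best = tot.max(axis=0)
        with np.errstate(invalid="ignore"):
            tie = tot >= best[None, :]
        tie[:, ~np.isfinite(best)] = True  # all -inf: pointer irrelevant
        ptr = np.where(tie, key, np.inf).argmin(axis=0)
        ptrs.append(ptr)
        score = best + state_emis[t]
        score = np.where(allowed_state[t], score, -np.inf)
    end = int(np.argmax(score))  # first occurrence = leftmost state
    if not np.isfinite(score[end]):
        raise AssertionError("no feasible decoded path")
    states = [end]
    for ptr in reversed(ptrs):
        states.append(int(ptr[states[-1]]))
    states.reverse()
    l = np.array([pairs_li[s] + 1 for s in states])
    r = np.array([pairs_ri[s] for s in states])
    path = BoundaryPath(l=l, r=r)

    allowed = [None] * T
    for t in range(T):
        m = valid_mask(N).copy()
        if not present[t]:
            m &= np.eye(N + 1, dtype=bool)
        allowed[t] = m
    post = e_step(block, params, table=table, allowed=allowed)
    jl_path, jr_path = path.jumps()
    left, right = [], []
    for t in range(T - 1):
        for side, j, store in (("L", jl_path[t], left), ("R", jr_path[t], right)):
            lab = _label_of_jump(int(j))
            p3 = post.dyn_post[t, 0 if side == "L" else 1]
            s = p3.sum()
            p3 = p3 / s if s > 0 else np.full(3, 1 / 3)
            if p3[lab] < p3.max() - 1e-9:
                log.debug(
                    "block decode: joint-MAP label %s differs from marginal argmax at t=%d side=%s",
                    DYNAMICS[lab], t, side,
                )
            store.append(DynamicsCall(side=side, t=t, label=lab, posterior=p3))
    return path, left, right


def classify_peak_color(
    present_nonzero: np.ndarray, left: list[DynamicsCall], right: list[DynamicsCall]
) -> list[str | None]:
    """Color category per time point for the emitted (non-zero-length) peaks.

    The first peak of a block is dark gray; a peak present at exactly one
    time point is orange; later peaks are colored by the dynamics of the
    transition into them: light gray (steady both sides), blue (some
    contraction, no expansion), red (some expansion, no contraction), black
    (one side expands while the other contracts).
    """
    T = len(present_nonzero)
    colors: list[str | None] = [None] * T
    idx = np.flatnonzero(present_nonzero)
    if len(idx) == 0:
        return colors
    if len(idx) == 1:
        colors[idx[0]] = "SINGLE"
        return colors
    colors[idx[0]] = "FIRST"
    for t in idx[1:]:
        labs = {left[t - 1].label, right[t - 1].label}
        if labs == {STEADY}:
            colors[t] = "STEADY"
        elif EXPAND in labs and CONTRACT in labs:
            colors[t] = "OPPOSITE"
        elif CONTRACT in labs:
            colors[t] = "CONTRACT"
        else:
            colors[t] = "EXPAND"
    return colors


def call_dynamics(
    blocks: list[Block], params: ModelParameters, config: RunConfig
) -> list[BlockCalls]:
    """Run the full stage-2 prediction over all blocks."""
    posteriors = [e_step(b, params) for b in blocks]
    present = peak_presence_masks(posteriors, config)
    out = []
    for b, post, mask in zip(blocks, posteriors, present):
        path, left, right = decode_boundaries(b, params, mask)
        nonzero = path.l <= path.r
        colors = classify_peak_color(nonzero, left, right)
        out.append(
            BlockCalls(
                block=b,
                present=mask,
                path=path,
                left=left,
                right=right,
                colors=colors,
                zero_len_posterior=post.zero_len,
            )
        )
    return out


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _peak_bp(call: BlockCalls, t: int, bin_size: int, chrom_len: int) -> tuple[int, int]:
    b = call.block
    start = (b.start_bin + int(call.path.l[t]) - 1) * bin_size
    end = (b.start_bin + int(call.path.r[t])) * bin_size
    return min(start, chrom_len), min(max(end, start), chrom_len)


def write_outputs(
    calls: list[BlockCalls], genome: GenomeTable, config: RunConfig, out_prefix: str
) -> list[str]:
    """Write per-time-point BED9 tracks, the master dynamics table, and the
    blocks BED.  Returns the written paths.

    Zero-length peaks appear in the master table but emit no BED interval.
    """
    if not calls:
        raise ValueError("no calls to write")
    T = calls[0].block.n_times
    bin_size = config.bin_size
    written = []

    for t in range(T):
        path = f"{out_prefix}_peaks_t{t + 1}.bed"
        with open(path, "w") as fh:
            fh.write(
                f'track name="peaks_t{t + 1}" description="predicted peaks, '
                f'time point {t + 1}" itemRgb="On"\n'
            )
            for call in calls:
                if call.path.l[t] > call.path.r[t]:
                    continue
                chrom = call.block.chrom
                s, e = _peak_bp(call, t, bin_size, genome.length(chrom))
                rgb = ",".join(map(str, COLORS[call.colors[t]]))
                fh.write(
                    f"{chrom}\t{s}\t{e}\tblock{call.block.block_id}\t0\t.\t{s}\t{e}\t{rgb}\n"
                )
        written.append(path)

    table_path = f"{out_prefix}_dynamics.tsv"
    with open(table_path, "w") as fh:
        header = ["block_id", "chrom", "block_start", "block_end", "time", "peak_start",
                  "peak_end", "present", "color"]
        for side in ("left", "right"):
            header += [f"{side}_label"] + [f"{side}_post_{d.lower()}" for d in DYNAMICS]
        fh.write("\t".join(header) + "\n")
        for call in calls:
            b = call.block
            clen = genome.length(b.chrom)
            bs = b.start_bin * bin_size
            be = min((b.end_bin + 1) * bin_size, clen)
            for t in range(T):
                s, e = _peak_bp(call, t, bin_size, clen)
                row = [b.block_id, b.chrom, bs, be, t + 1, s, e,
                       int(call.path.l[t] <= call.path.r[t]), call.colors[t] or "NONE"]
                for calls_side in (call.left, call.right):
                    if t == 0:
                        row += ["NA", "NA", "NA", "NA"]
                    else:
                        dc = calls_side[t - 1]
                        row += [dc.label_name] + [repr(float(p)) for p in dc.posterior]
                fh.write("\t".join(map(str, row)) + "\n")
    written.append(table_path)

    blocks_path = f"{out_prefix}_blocks.bed"
    with open(blocks_path, "w") as fh:
        for call in calls:
            b = call.block
            clen = genome.length(b.chrom)
            fh.write(
                f"{b.chrom}\t{b.start_bin * bin_size}\t"
                f"{min((b.end_bin + 1) * bin_size, clen)}\tblock{b.block_id}\n"
            )
    written.append(blocks_path)
    return written
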