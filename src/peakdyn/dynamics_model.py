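"""Probabilistic mixture model for peak boundary dynamics within blocks.

Each block of N bins holds exactly one (possibly zero-length) peak per time
point, delimited by boundary variables l_t in [1, N+1] and r_t in [0, N]
with the validity constraint l_t <= r_t + 1 (l = r + 1 encodes a zero-length
peak: the whole block is background).  Bin counts are emitted from one of
two negative binomial components (PEAK / BACKGROUND) sharing the dispersion
delta_t and covariate coefficient gamma_t, with log-linear means driven by
the local expected background rate lambda.  Between consecutive time points
each boundary follows one of three dynamics: STEADY (no movement), EXPAND
(movement of j >= 1 bins outward, j - 1 ~ NB), or CONTRACT (movement inward,
-j - 1 ~ NB), with genome-wide priors pi shared between the two sides.

Inference over all valid boundary paths is exact: the joint distribution
factorizes over time and over the two sides given the per-time validity
coupling, so the likelihood is computed by a dynamic program over the
(l, r) grid with a separable two-pass transition sum — O(T N^3) instead of
O(T N^4).  A brute-force enumeration oracle over all boundary paths and all
3^(T-1) dynamics sequences per side backs every DP result in the tests.

Internally boundary pairs are indexed as (li, ri) = (l - 1, r), both in
0..N; validity becomes li <= ri and the zero-length states are the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy import stats

STEADY, EXPAND, CONTRACT = 0, 1, 2
DYNAMICS = ("STEADY", "EXPAND", "CONTRACT")

NEG_INF = -np.inf


@dataclass
class ModelParameters:
    """All learned quantities of the mixture model.

    Per time point t: emission intercepts ``alpha`` (peak) and ``beta``
    (background) on the log scale, covariate coefficient ``gamma`` and
    shared dispersion ``delta``.  Per transition t -> t+1: dynamics priors
    ``pi[t]`` (simplex over STEADY/EXPAND/CONTRACT) and the jump NB
    parameters for EXPAND and CONTRACT.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    pi: np.ndarray  # (T-1, 3)
    jump_mu: np.ndarray  # (T-1, 2): [:, 0] EXPAND, [:, 1] CONTRACT
    jump_delta: np.ndarray  # (T-1, 2)

    @property
    def T(self) -> int:
        return len(self.alpha)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta", "pi", "jump_mu", "jump_delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        T = self.T
        assert self.beta.shape == self.gamma.shape == self.delta.shape == (T,)
        assert self.pi.shape == (max(T - 1, 0), 3)
        assert self.jump_mu.shape == self.jump_delta.shape == (max(T - 1, 0), 2)

    def validate(self, min_prior: float = 0.0) -> None:
        if not (self.delta > 0).all():
            raise ValueError("emission dispersions must be positive")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("dynamics priors must sum to 1")
        if (self.pi < min_prior - 1e-12).any():
            raise ValueError("dynamics priors below MIN_PRIOR")
        if not ((self.jump_mu > 0).all() and (self.jump_delta > 0).all()):
            raise ValueError("jump parameters must be positive")

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.alpha.copy(), self.beta.copy(), self.gamma.copy(), self.delta.copy(),
            self.pi.copy(), self.jump_mu.copy(), self.jump_delta.copy(),
        )


def nb_log_pmf(k, mu, delta):
    """Log pmf of the negative binomial with mean ``mu`` and dispersion
    ``delta``; -inf for negative ``k`` (probability 0 by definition)."""
    k = np.asarray(k)
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (
            gammaln(k + delta)
            - gammaln(k + 1.0)
            - gammaln(delta)
            + delta * (np.log(delta) - np.log(mu + delta))
            + k * (np.log(mu) - np.log(mu + delta))
        )
    out = np.where(k < 0, NEG_INF, out)
    return out if out.ndim else float(out)


def jump_log_prob(j, d: int, t: int, params: ModelParameters):
    """Log P(J = j | D = d) for the transition t -> t+1.

    STEADY is a point mass at 0; EXPAND puts NB mass on j >= 1 (on j - 1),
    CONTRACT on j <= -1 (on -j - 1).
    """
    j = np.asarray(j)
    if d == STEADY:
        out = np.where(j == 0, 0.0, NEG_INF)
    elif d == EXPAND:
        out = nb_log_pmf(j - 1, params.jump_mu[t, 0], params.jump_delta[t, 0])
    elif d == CONTRACT:
        out = nb_log_pmf(-j - 1, params.jump_mu[t, 1], params.jump_delta[t, 1])
    else:
        raise ValueError(f"unknown dynamic {d}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


def jump_weight_table(params: ModelParameters, t: int, max_j: int) -> np.ndarray:
    """Per-dynamic transition terms log(pi_{t,d} P(j | d)) for
    j in [-max_j, max_j]; shape (3, 2*max_j + 1), row d, column j + max_j."""
    j = np.arange(-max_j, max_j + 1)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi[t])
    return np.stack([logpi[d] + jump_log_prob(j, d, t, params) for d in range(3)])


def transition_log_prob(b: int, b_next: int, side: str, t: int, params: ModelParameters) -> float:
    """log sum_d pi_{t,d} P(j | d) with the side's sign convention
    (left: j = b - b_next; right: j = b_next - b).  Because the three jump
    supports are disjoint, at most one dynamic contributes."""
    j = b - b_next if side == "L" else b_next - b
    W = jump_weight_table(params, t, abs(j) + 1)
    return float(logsumexp(W[:, j + abs(j) + 1]))


def valid_mask(N: int) -> np.ndarray:
    """Boolean (N+1, N+1) mask of valid (li, ri) pairs: li <= ri."""
    idx = np.arange(N + 1)
    return idx[:, None] <= idx[None, :]


class EmissionTable:
    """Prefix sums of per-bin log NB probabilities for one block.

    ``emission_matrix(t)[li, ri]`` is the log probability of the block's
    counts at time t when the peak occupies bins l..r (1-based, l = li + 1,
    r = ri), background elsewhere; -inf at invalid pairs.
    """

    def __init__(self, block, params: ModelParameters):
        counts = block.counts
        loglam = np.log(block.rates)
        T, N = counts.shape
        mu_pk = np.exp(params.alpha[:, None] + params.gamma[:, None] * loglam)
        mu_bg = np.exp(params.beta[:, None] + params.gamma[:, None] * loglam)
        self.lp_peak = nb_log_pmf(counts, mu_pk, params.delta[:, None])
        self.lp_bg = nb_log_pmf(counts, mu_bg, params.delta[:, None])
        zeros = np.zeros((T, 1))
        self.cum_peak = np.hstack([zeros, np.cumsum(self.lp_peak, axis=1)])
        self.cum_bg = np.hstack([zeros, np.cumsum(self.lp_bg, axis=1)])
        self.N = N
        self.T = T
        self._valid = valid_mask(N)
        self._cache: dict[int, np.ndarray] = {}

    def emission_matrix(self, t: int) -> np.ndarray:
        if t not in self._cache:
            N = self.N
            li = np.arange(N + 1)[:, None]
            ri = np.arange(N + 1)[None, :]
            cb, cp = self.cum_bg[t], self.cum_peak[t]
            mat = cb[li] + (cp[ri] - cp[li]) + (cb[N] - cb[ri])
            self._cache[t] = np.where(self._valid, mat, NEG_INF)
        return self._cache[t]

    def emission_log_prob(self, t: int, l: int, r: int) -> float:
        if not (1 <= l <= r + 1 <= self.N + 1):
            raise ValueError(f"invalid boundaries l={l}, r={r} for N={self.N}")
        return float(self.emission_matrix(t)[l - 1, r])


def emission_log_prob(block, t: int, l: int, r: int, params: ModelParameters,
                      table: EmissionTable | None = None) -> float:
    """Log emission probability of time point t with peak bins l..r."""
    if table is None:
        table = EmissionTable(block, params)
    return table.emission_log_prob(t, l, r)


def left_transition_matrix(params: ModelParameters, t: int, N: int) -> np.ndarray:
    """A_L[li, li'] = log sum_d pi P(l - l' | d); the right-side matrix is
    its transpose (j = r' - r)."""
    W = jump_weight_table(params, t, N)
    with np.errstate(divide="ignore"):
        w = logsumexp(W, axis=0)  # disjoint supports: effectively a select
    idx = np.arange(N + 1)
    return w[(idx[:, None] - idx[None, :]) + N]


def log_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """C[i, j] = logsumexp_k A[i, k] + B[k, j], computed through a BLAS
    matmul after shifting by row/column maxima (exact in log space)."""
    amax = A.max(axis=1, keepdims=True)
    bmax = B.max(axis=0, keepdims=True)
    a_s = np.where(np.isfinite(amax), amax, 0.0)
    b_s = np.where(np.isfinite(bmax), bmax, 0.0)
    with np.errstate(divide="ignore"):
        return np.log(np.exp(A - a_s) @ np.exp(B - b_s)) + a_s + b_s


def forward_messages(block, params: ModelParameters, table: EmissionTable | None = None,
                     allowed: list[np.ndarray] | None = None) -> list[np.ndarray]:
    """Forward DP messages a_t[li, ri] = log P(counts up to t, boundaries at t).

    ``allowed`` optionally restricts the state space per time point (used to
    force zero-length peaks at absent time points during decoding).
    """
    if table is None:
        table = EmissionTable(block, params)
    N, T = table.N, table.T
    mask = valid_mask(N)
    a = table.emission_matrix(0) - 2.0 * np.log(N + 1)
    a = np.where(mask, a, NEG_INF)
    if allowed is not None:
        a = np.where(allowed[0], a, NEG_INF)
    out = [a]
    for t in range(1, T):
        AL = left_transition_matrix(params, t - 1, N)
        # S[li, ri'] = LSE_ri a[li, ri] + A_R[ri, ri'],  A_R = AL.T
        S = log_matmul(a, AL.T)
        a = table.emission_matrix(t) + log_matmul(AL.T, S)
        a = np.where(mask, a, NEG_INF)
        if allowed is not None:
            a = np.where(allowed[t], a, NEG_INF)
        out.append(a)
    return out


def backward_messages(block, params: ModelParameters, table: EmissionTable | None = None,
                      allowed: list[np.ndarray] | None = None) -> list[np.ndarray]:
    """Backward DP messages b_t[li, ri] = log P(counts after t | boundaries at t)."""
    if table is None:
        table = EmissionTable(block, params)
    N, T = table.N, table.T
    mask = valid_mask(N)
    b = np.where(mask, 0.0, NEG_INF)
    if allowed is not None:
        b = np.where(allowed[T - 1], b, NEG_INF)
    out = [b]
    for t in range(T - 2, -1, -1):
        AL = left_transition_matrix(params, t, N)
        G = table.emission_matrix(t + 1) + out[-1]
        if allowed is not None:
            G = np.where(allowed[t + 1], G, NEG_INF)
        # b_t[li, ri] = LSE_{li', ri'} AL[li, li'] + G[li', ri'] + A_R[ri, ri']
        H = log_matmul(AL, G)
        b = log_matmul(H, AL)  # (A_R.T)[ri', ri] = AL[ri', ri]
        b = np.where(mask, b, NEG_INF)
        if allowed is not None:
            b = np.where(allowed[t], b, NEG_INF)
        out.append(b)
    out.reverse()
    return out


def block_log_likelihood(block, params: ModelParameters,
                         table: EmissionTable | None = None) -> float:
    """Exact log P(counts, all Z = 1 | covariates) for one block: the sum
    over all valid boundary paths and dynamics sequences."""
    if table is None:
        table = EmissionTable(block, params)
    alphas = forward_messages(block, params, table)
    ll = float(logsumexp(alphas[-1][valid_mask(table.N)]))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite block likelihood (degenerate parameters)")
    return ll


# ---------------------------------------------------------------------------
# brute-force enumeration oracle (independent route: scipy.stats pmfs)
# ---------------------------------------------------------------------------

def enumerate_valid_pairs(N: int) -> list[tuple[int, int]]:
    """All (l, r) with 1 <= l <= r + 1 <= N + 1; (N+1)(N+2)/2 pairs."""
    return [(l, r) for l in range(1, N + 2) for r in range(l - 1, N + 1)]


def enumerate_dynamics_sequences(T: int) -> list[tuple[int, ...]]:
    """All 3^(T-1) per-side dynamics label sequences."""
    return list(product(range(3), repeat=T - 1))


def _oracle_nb_logpmf(k, mu, delta):
    k = np.asarray(k)
    out = stats.nbinom.logpmf(np.maximum(k, 0), delta, delta / (delta + mu))
    return np.where(k < 0, NEG_INF, out)


def _oracle_emissions(block, params: ModelParameters) -> list[np.ndarray]:
    """Emission log-prob per valid pair per time point, by direct per-bin sums."""
    T, N = block.counts.shape
    loglam = np.log(block.rates)
    pairs = enumerate_valid_pairs(N)
    out = []
    for t in range(T):
        mu_pk = np.exp(params.alpha[t] + params.gamma[t] * loglam[t])
        mu_bg = np.exp(params.beta[t] + params.gamma[t] * loglam[t])
        lp_pk = _oracle_nb_logpmf(block.counts[t], mu_pk, params.delta[t])
        lp_bg = _oracle_nb_logpmf(block.counts[t], mu_bg, params.delta[t])
        vals = np.empty(len(pairs))
        for i, (l, r) in enumerate(pairs):
            tot = 0.0
            for p in range(1, N + 1):  # 1-based bins
                tot += lp_pk[p - 1] if l <= p <= r else lp_bg[p - 1]
            vals[i] = tot
        out.append(vals)
    return out


def _oracle_jump_tables(params: ModelParameters, N: int) -> list[np.ndarray]:
    """W[t][d, j + N] = log(pi_{t,d}) + log P(j | d), via scipy pmfs."""
    j = np.arange(-N, N + 1)
    out = []
    for t in range(params.T - 1):
        with np.errstate(divide="ignore"):
            logpi = np.log(params.pi[t])
        rows = [
            logpi[STEADY] + np.where(j == 0, 0.0, NEG_INF),
            logpi[EXPAND]
            + _oracle_nb_logpmf(j - 1, params.jump_mu[t, 0], params.jump_delta[t, 0]),
            logpi[CONTRACT]
            + _oracle_nb_logpmf(-j - 1, params.jump_mu[t, 1], params.jump_delta[t, 1]),
        ]
        out.append(np.stack(rows))
    return out


def _oracle_scan(block, params: ModelParameters):
    """Iterate over all valid boundary-pair sequences in chunks.

    Yields (pair_seq_indices (chunk, T), log p(seq) including priors,
    emissions and both sides' dynamics sums, per-side per-transition summed
    scores S_L, S_R of shape (chunk, n_dyn_seq)).
    """
    T, N = block.counts.shape
    pairs = enumerate_valid_pairs(N)
    P = len(pairs)
    if P**T > 50_000_000:
        raise ValueError(f"block too large to enumerate: {P}^{T} sequences")
    emis = _oracle_emissions(block, params)
    W = _oracle_jump_tables(params, N)
    dyn = np.array(enumerate_dynamics_sequences(T), dtype=int).reshape(3 ** (T - 1), T - 1)
    Larr = np.array([l for l, _ in pairs])
    Rarr = np.array([r for _, r in pairs])
    prior = -2.0 * np.log(N + 1)

    if T == 1:
        seq = np.arange(P)[:, None]
        tot = prior + emis[0]
        zero = np.zeros((P, 1))
        yield seq, tot, zero, zero
        return

    rest = np.stack(
        np.meshgrid(*([np.arange(P)] * (T - 1)), indexing="ij")
    ).reshape(T - 1, -1).T  # (P^(T-1), T-1)
    for first in range(P):
        seq = np.hstack([np.full((len(rest), 1), first), rest])  # (chunk, T)
        emis_sum = prior + sum(emis[t][seq[:, t]] for t in range(T))
        SL = np.zeros((len(rest), len(dyn)))
        SR = np.zeros((len(rest), len(dyn)))
        for t in range(T - 1):
            jl = Larr[seq[:, t]] - Larr[seq[:, t + 1]]
            jr = Rarr[seq[:, t + 1]] - Rarr[seq[:, t]]
            SL += W[t][dyn[:, t][None, :], (jl + N)[:, None]]
            SR += W[t][dyn[:, t][None, :], (jr + N)[:, None]]
        yield seq, emis_sum, SL, SR


def brute_force_log_likelihood(block, params: ModelParameters) -> float:
    """Explicit enumeration of the total block probability: all valid
    boundary paths x all 3^(T-1) dynamics sequences per side."""
    chunks = []
    for _, emis_sum, SL, SR in _oracle_scan(block, params):
        chunks.append(logsumexp(emis_sum + logsumexp(SL, axis=1) + logsumexp(SR, axis=1)))
    return float(logsumexp(chunks))


def brute_force_posteriors(block, params: ModelParameters) -> dict:
    """Posterior marginals by explicit enumeration (test oracle).

    Returns boundary-pair marginals per t on the (li, ri) grid, per-side
    dynamics posteriors, per-bin PEAK posteriors, zero-length posteriors,
    and the total log-likelihood.
    """
    T, N = block.counts.shape
    pairs = enumerate_valid_pairs(N)
    ll = brute_force_log_likelihood(block, params)
    marg = [np.zeros((N + 1, N + 1)) for _ in range(T)]
    dyn_post = np.zeros((T - 1, 2, 3))
    pair_joint = [np.zeros((N + 1, N + 1, N + 1, N + 1)) for _ in range(max(T - 1, 0))]
    dyn = np.array(enumerate_dynamics_sequences(T), dtype=int).reshape(3 ** (T - 1), T - 1)
    for seq, emis_sum, SL, SR in _oracle_scan(block, params):
        lseL = logsumexp(SL, axis=1)
        lseR = logsumexp(SR, axis=1)
        w = np.exp(emis_sum + lseL + lseR - ll)
        for t in range(T):
            li = np.array([pairs[i][0] - 1 for i in seq[:, t]])
            ri = np.array([pairs[i][1] for i in seq[:, t]])
            np.add.at(marg[t], (li, ri), w)
        wL = np.exp(emis_sum[:, None] + SL + lseR[:, None] - ll)  # (chunk, combos)
        wR = np.exp(emis_sum[:, None] + lseL[:, None] + SR - ll)
        for t in range(T - 1):
            for d in range(3):
                sel = dyn[:, t] == d
                dyn_post[t, 0, d] += wL[:, sel].sum()
                dyn_post[t, 1, d] += wR[:, sel].sum()
            li = np.array([pairs[i][0] - 1 for i in seq[:, t]])
            ri = np.array([pairs[i][1] for i in seq[:, t]])
            lj = np.array([pairs[i][0] - 1 for i in seq[:, t + 1]])
            rj = np.array([pairs[i][1] for i in seq[:, t + 1]])
            np.add.at(pair_joint[t], (li, ri, lj, rj), w)
    peak_post = np.zeros((T, N))
    for t in range(T):
        for p in range(1, N + 1):
            for l, r in pairs:
                if l <= p <= r:
                    peak_post[t, p - 1] += marg[t][l - 1, r]
    zero_len = np.array([np.trace(marg[t]) for t in range(T)])
    return {
        "marginals": marg,
        "dyn_post": dyn_post,
        "pair_joint": pair_joint,
        "peak_post": peak_post,
        "zero_len": zero_len,
        "loglik": ll,
    }


def brute_force_decode(block, params: ModelParameters,
                       present: np.ndarray | None = None):
    """Argmax over all (boundary path, dynamics labels) configurations,
    optionally restricted to zero-length peaks at absent time points.

    Exact ties are resolved by the same canonical rule as the decoder:
    smallest final state index, then — walking backward — the transition
    with fewer non-steady sides, then smaller total boundary movement, then
    the smaller predecessor state index.

    Returns (l array, r array, left labels, right labels, best score).
    """
    T, N = block.counts.shape
    pairs = enumerate_valid_pairs(N)
    dyn = np.array(enumerate_dynamics_sequences(T), dtype=int).reshape(3 ** (T - 1), T - 1)

    def tie_key(state_seq):
        key = [state_seq[T - 1]]
        for t in range(T - 2, -1, -1):
            l0, r0 = pairs[state_seq[t]]
            l1, r1 = pairs[state_seq[t + 1]]
            jl, jr = l0 - l1, r1 - r0
            key += [(jl != 0) + (jr != 0), abs(jl) + abs(jr), state_seq[t]]
        return tuple(key)

    best_score, best_key, best_cfg = NEG_INF, None, None
    for seq, emis_sum, SL, SR in _oracle_scan(block, params):
        ok = np.ones(len(seq), dtype=bool)
        if present is not None:
            for t in range(T):
                if not present[t]:
                    zero = np.array([pairs[i][0] == pairs[i][1] + 1 for i in seq[:, t]])
                    ok &= zero
        if not ok.any():
            continue
        tot = emis_sum[:, None, None] + SL[:, :, None] + SR[:, None, :]
        tot[~ok] = NEG_INF
        m = tot.max()
        if not np.isfinite(m) or m < best_score:
            continue
        if m > best_score:
            best_score, best_key, best_cfg = m, None, None
        for s, cL, cR in np.argwhere(tot == best_score):
            key = tie_key(seq[s])
            if best_key is None or key < best_key:
                ls = np.array([pairs[i][0] for i in seq[s]])
                rs = np.array([pairs[i][1] for i in seq[s]])
                best_key = key
                best_cfg = (ls, rs, dyn[cL].copy(), dyn[cR].copy())
    if best_cfg is None:
        raise AssertionError("no feasible configuration")
    ls, rs, dL, dR = best_cfg
    return ls, rs, dL, dR, float(best_score)


def brute_force_path_score(block, params: ModelParameters, l, r) -> float:
    """Joint log score of one boundary path with its best dynamics labels,
    via the oracle pmf route (test helper)."""
    T, N = block.counts.shape
    pairs = enumerate_valid_pairs(N)
    pair_index = {pair: k for k, pair in enumerate(pairs)}
    emis = _oracle_emissions(block, params)
    W = _oracle_jump_tables(params, N)
    score = -2.0 * np.log(N + 1)
    for t in range(T):
        score += emis[t][pair_index[(int(l[t]), int(r[t]))]]
    for t in range(T - 1):
        jl, jr = int(l[t] - l[t + 1]), int(r[t + 1] - r[t])
        score += max(W[t][d, jl + N] for d in range(3))
        score += max(W[t][d, jr + N] for d in range(3))
    return float(score)


# ---------------------------------------------------------------------------
# parameter serialization: flat key-value text
# ---------------------------------------------------------------------------

def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write one parameter per line: name, time index, (label,) value."""
    with open(path, "w") as fh:
        fh.write(f"T\t{params.T}\n")
        for t in range(params.T):
            for name in ("alpha", "beta", "gamma", "delta"):
                fh.write(f"{name}\t{t}\t{float(getattr(params, name)[t])!r}\n")
        for t in range(params.T - 1):
            for d in range(3):
                fh.write(f"pi\t{t}\t{DYNAMICS[d]}\t{float(params.pi[t, d])!r}\n")
            for k, d in ((0, "EXPAND"), (1, "CONTRACT")):
                fh.write(f"jump_mu\t{t}\t{d}\t{float(params.jump_mu[t, k])!r}\n")
                fh.write(f"jump_delta\t{t}\t{d}\t{float(params.jump_delta[t, k])!r}\n")


def load_parameters(path: str | Path) -> ModelParameters:
    rows = [line.split("\t") for line in Path(path).read_text().splitlines() if line]
    T = int(next(r[1] for r in rows if r[0] == "T"))
    p = ModelParameters(
        alpha=np.zeros(T), beta=np.zeros(T), gamma=np.zeros(T), delta=np.ones(T),
        pi=np.full((T - 1, 3), 1 / 3), jump_mu=np.ones((T - 1, 2)),
        jump_delta=np.ones((T - 1, 2)),
    )
    dyn_idx = {name: i for i, name in enumerate(DYNAMICS)}
    jump_idx = {"EXPAND": 0, "CONTRACT": 1}
    for r in rows:
        if r[0] in ("alpha", "beta", "gamma", "delta"):
            getattr(p, r[0])[int(r[1])] = float(r[2])
        elif r[0] == "pi":
            p.pi[int(r[1]), dyn_idx[r[2]]] = float(r[3])
        elif r[0] == "jump_mu":
            p.jump_mu[int(r[1]), jump_idx[r[2]]] = float(r[3])
        elif r[0] == "jump_delta":
            p.jump_delta[int(r[1]), jump_idx[r[2]]] = float(r[3])
    return p
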