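"""Expectation-Maximization fitting of the boundary-dynamics model.

The E-step is the exact forward-backward pass implied by the joint model
(no approximation); the M-step is generalized EM: the dynamics priors have
a closed-form update (with a MIN_PRIOR clamp), while the emission and jump
negative-binomial parameters are refined by bounded numerical ascent on the
expected complete-data log-likelihood, each sub-maximization guarded never
to decrease its surrogate.  Together this keeps the conditional
log-likelihood trace non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .block_finder import Block
from .config import RunConfig
from .dynamics_model import (
    CONTRACT,
    EXPAND,
    STEADY,
    EmissionTable,
    ModelParameters,
    backward_messages,
    forward_messages,
    left_transition_matrix,
    log_matmul,
    nb_log_pmf,
    valid_mask,
)

log = logging.getLogger(__name__)

_DELTA_BOUNDS = (1e-3, 1e6)  # dispersion kept off the Poisson/degenerate limits


@dataclass
class BlockPosteriors:
    """Posterior summaries of one block under fixed parameters.

    ``peak_post[t, p]`` is P(bin p+1 is in the peak at time t);
    ``zero_len[t]`` is P(l_t = r_t + 1) (no peak); ``dyn_post[t, side, d]``
    the per-side dynamics posteriors; ``jump_hist[t, side, j + N]`` the
    posterior mass of jump value j.  ``marginals`` (the full (l, r) grids)
    are only kept on request.
    """

    loglik: float
    peak_post: np.ndarray  # (T, N)
    zero_len: np.ndarray  # (T,)
    dyn_post: np.ndarray  # (T-1, 2, 3)
    jump_hist: np.ndarray  # (T-1, 2, 2N+1)
    marginals: list[np.ndarray] | None = None


@dataclass
class FitTrace:
    """Per-iteration conditional log-likelihood of the EM run."""

    loglik: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.loglik)


def e_step(
    block: Block,
    params: ModelParameters,
    table: EmissionTable | None = None,
    keep_marginals: bool = False,
    allowed: list[np.ndarray] | None = None,
) -> BlockPosteriors:
    """Exact forward-backward posteriors for one block.

    ``allowed`` optionally restricts the boundary states per time point
    (used by the decoder to condition on peak presence).
    """
    if table is None:
        table = EmissionTable(block, params)
    N, T = table.N, table.T
    alphas = forward_messages(block, params, table, allowed)
    betas = backward_messages(block, params, table, allowed)
    ll = float(logsumexp(alphas[-1][valid_mask(N)]))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite normalizer in E-step")
    idx = np.arange(N + 1)
    jl_grid = idx[:, None] - idx[None, :]  # left jump l - l' at [li, li']
    jr_grid = idx[None, :] - idx[:, None]  # right jump r' - r at [ri, ri']

    marginals = []
    peak_post = np.zeros((T, N))
    zero_len = np.zeros(T)
    for t in range(T):
        m = np.exp(alphas[t] + betas[t] - ll)
        if keep_marginals:
            marginals.append(m)
        zero_len[t] = np.trace(m)
        if N:
            c = np.cumsum(m, axis=0)  # over li
            tail = np.cumsum(c[:, ::-1], axis=1)[:, ::-1]  # over ri, descending
            peak_post[t] = tail[np.arange(N), np.arange(1, N + 1)]

    dyn_post = np.zeros((max(T - 1, 0), 2, 3))
    jump_hist = np.zeros((max(T - 1, 0), 2, 2 * N + 1))
    for t in range(T - 1):
        AL = left_transition_matrix(params, t, N)
        G = table.emission_matrix(t + 1) + betas[t + 1]
        if allowed is not None:
            G = np.where(allowed[t + 1], G, -np.inf)
        # left pairwise: LSE_ri a[li, ri] + A_R[ri, ri'] then LSE_ri' ... + G[li', ri']
        U = log_matmul(alphas[t], AL.T)  # U[li, ri']
        ML = log_matmul(U, G.T) + AL - ll  # [li, li']
        # right pairwise
        U2 = log_matmul(alphas[t].T, AL)  # U2[ri, li']
        MR = log_matmul(U2, G) + AL.T - ll  # [ri, ri']
        wL = np.exp(ML)
        wR = np.exp(MR)
        jump_hist[t, 0] = np.bincount(
            (jl_grid + N).ravel(), weights=wL.ravel(), minlength=2 * N + 1
        )
        jump_hist[t, 1] = np.bincount(
            (jr_grid + N).ravel(), weights=wR.ravel(), minlength=2 * N + 1
        )
        for side in (0, 1):
            h = jump_hist[t, side]
            dyn_post[t, side, STEADY] = h[N]
            dyn_post[t, side, EXPAND] = h[N + 1 :].sum()
            dyn_post[t, side, CONTRACT] = h[:N].sum()
    return BlockPosteriors(
        loglik=ll,
        peak_post=peak_post,
        zero_len=zero_len,
        dyn_post=dyn_post,
        jump_hist=jump_hist,
        marginals=marginals if keep_marginals else None,
    )


def initialize_parameters(
    blocks: list[Block], config: RunConfig, seed: int = 0
) -> ModelParameters:
    """Deterministic moment-based starting point.

    Background intercept from the mean of the lower half of per-bin counts,
    peak intercept from the upper decile (floored at beta + log 2); gamma is
    1 when the expected-rate covariate varies (a control was provided), else
    0; unit dispersions, uniform clamped priors, unit jump parameters.
    """
    if not blocks:
        raise ValueError("no blocks to initialize from")
    T = blocks[0].n_times
    alpha, beta = np.zeros(T), np.zeros(T)
    has_covariate = any(np.ptp(np.log(b.rates)) > 1e-12 for b in blocks)
    for t in range(T):
        allc = np.sort(np.concatenate([b.counts[t] for b in blocks]))
        if allc.sum() == 0:
            raise ValueError(f"all counts are zero at time point {t}")
        lower = allc[: max(1, len(allc) // 2)]
        upper = allc[-max(1, len(allc) // 10) :]
        beta[t] = np.log(max(lower.mean(), 0.05))
        alpha[t] = max(np.log(max(upper.mean(), 0.1)), beta[t] + np.log(2.0))
    pi = _clamp_simplex_rows(np.full((max(T - 1, 0), 3), 1 / 3), config.min_prior)
    return ModelParameters(
        alpha=alpha,
        beta=beta,
        gamma=np.full(T, 1.0 if has_covariate else 0.0),
        delta=np.ones(T),
        pi=pi,
        jump_mu=np.ones((max(T - 1, 0), 2)),
        jump_delta=np.ones((max(T - 1, 0), 2)),
    )


def _clamp_simplex(p: np.ndarray, floor: float) -> np.ndarray:
    """Project a probability vector so every entry >= floor, sum = 1."""
    p = np.maximum(np.asarray(p, dtype=float), 0.0)
    s = p.sum()
    p = p / s if s > 0 else np.full_like(p, 1.0 / len(p))
    if floor <= 0:
        return p
    fixed = np.zeros(len(p), dtype=bool)
    for _ in range(len(p)):
        low = (p < floor - 1e-15) & ~fixed
        if not low.any():
            break
        fixed |= low
        p[fixed] = floor
        free = ~fixed
        if free.any():
            budget = 1.0 - floor * fixed.sum()
            p[free] *= budget / p[free].sum()
    return p


def _clamp_simplex_rows(pi: np.ndarray, floor: float) -> np.ndarray:
    return np.array([_clamp_simplex(row, floor) for row in pi]) if len(pi) else pi


def _nb_mean_score(o, mu, delta):
    """d log NB / d(log mean):  o - mu (delta + o) / (mu + delta)."""
    return o - mu * (delta + o) / (mu + delta)


def _nb_delta_score(o, mu, delta):
    """d log NB / d delta."""
    return (
        digamma(o + delta)
        - digamma(delta)
        + np.log(delta)
        + 1.0
        - np.log(mu + delta)
        - (delta + o) / (mu + delta)
    )


def _fit_emission_time(o, x, w, theta0, free_gamma, free_alpha, free_beta, maxiter=60):
    """Maximize the posterior-weighted two-component NB regression for one
    time point.  theta = (alpha, beta, gamma, log delta).  Returns the new
    theta, guaranteed not to decrease the objective vs theta0."""

    def unpack(th):
        return th[0], th[1], th[2], np.exp(th[3])

    def negQ_grad(th):
        a, b, g, d = unpack(th)
        mu_a = np.exp(np.clip(a + g * x, -50, 50))
        mu_b = np.exp(np.clip(b + g * x, -50, 50))
        Q = np.sum(w * nb_log_pmf(o, mu_a, d) + (1 - w) * nb_log_pmf(o, mu_b, d))
        sa = w * _nb_mean_score(o, mu_a, d)
        sb = (1 - w) * _nb_mean_score(o, mu_b, d)
        grad = np.array(
            [
                sa.sum() if free_alpha else 0.0,
                sb.sum() if free_beta else 0.0,
                np.sum(x * (sa + sb)) if free_gamma else 0.0,
                d * np.sum(w * _nb_delta_score(o, mu_a, d) + (1 - w) * _nb_delta_score(o, mu_b, d)),
            ]
        )
        return -Q, -grad

    lo, hi = np.log(_DELTA_BOUNDS[0]), np.log(_DELTA_BOUNDS[1])
    bounds = [
        (theta0[0], theta0[0]) if not free_alpha else (-30, 30),
        (theta0[1], theta0[1]) if not free_beta else (-30, 30),
        (theta0[2], theta0[2]) if not free_gamma else (-10, 10),
        (lo, hi),
    ]
    res = minimize(
        negQ_grad, np.asarray(theta0, dtype=float), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": maxiter},
    )
    q0 = negQ_grad(np.asarray(theta0, dtype=float))[0]
    if not np.isfinite(res.fun) or res.fun > q0:
        return np.asarray(theta0, dtype=float), False
    return res.x, True


def _fit_jump_nb(weights, mu0, delta0, maxiter=60):
    """Weighted NB MLE over support k = 0, 1, ... with posterior weights.

    Returns (mu, delta), never decreasing the weighted log-likelihood
    relative to (mu0, delta0)."""
    k = np.arange(len(weights), dtype=float)
    W = weights.sum()
    if W <= 1e-10:
        return mu0, delta0, False
    wmean = float(np.sum(weights * k) / W)
    wvar = float(np.sum(weights * k**2) / W - wmean**2)
    mu_start = max(wmean, 1e-3)
    if wvar > mu_start * 1.0001:
        d_start = mu_start**2 / (wvar - mu_start)
    else:
        d_start = 100.0
    d_start = float(np.clip(d_start, *_DELTA_BOUNDS))

    def negQ_grad(th):
        mu, d = np.exp(th)
        Q = np.sum(weights * nb_log_pmf(k, mu, d))
        g_mu = np.sum(weights * _nb_mean_score(k, mu, d))
        g_d = d * np.sum(weights * _nb_delta_score(k, mu, d))
        return -Q, -np.array([g_mu, g_d])

    lo, hi = np.log(_DELTA_BOUNDS[0]), np.log(_DELTA_BOUNDS[1])
    bounds = [(np.log(1e-3), np.log(1e6)), (lo, hi)]
    starts = [np.log([mu_start, d_start]), np.log([max(mu0, 1e-3), delta0])]
    best = (negQ_grad(np.log([max(mu0, 1e-3), delta0]))[0], np.log([max(mu0, 1e-3), delta0]))
    for s in starts:
        res = minimize(negQ_grad, s, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < best[0]:
            best = (res.fun, res.x)
    mu, d = np.exp(best[1])
    return float(mu), float(d), True


def m_step(
    posteriors: list[BlockPosteriors],
    blocks: list[Block],
    params: ModelParameters,
    config: RunConfig,
) -> ModelParameters:
    """Generalized M-step: closed-form clamped prior update plus guarded
    numerical ascent for the emission and jump NB parameters."""
    T = params.T
    N_max = max(b.n_bins for b in blocks)
    new = params.copy()

    # (1) dynamics priors
    if T > 1:
        totals = np.zeros((T - 1, 3))
        for post in posteriors:
            totals += post.dyn_post.sum(axis=1)
        pi = totals / totals.sum(axis=1, keepdims=True)
        new.pi = _clamp_simplex_rows(pi, config.min_prior)

    # (2) emission NB regression per time point
    for t in range(T):
        o = np.concatenate([b.counts[t] for b in blocks]).astype(float)
        x = np.concatenate([np.log(b.rates[t]) for b in blocks])
        w = np.concatenate([p.peak_post[t] for p in posteriors])
        free_gamma = np.ptp(x) > 1e-12
        free_alpha = w.sum() > 1e-6
        free_beta = (1 - w).sum() > 1e-6
        if not free_alpha:
            log.warning("time %d: no peak-labeled mass; alpha held fixed", t)
        if not free_beta:
            log.warning("time %d: no background-labeled mass; beta held fixed", t)
        theta0 = (params.alpha[t], params.beta[t], params.gamma[t], np.log(params.delta[t]))
        theta, _ = _fit_emission_time(o, x, w, theta0, free_gamma, free_alpha, free_beta)
        new.alpha[t], new.beta[t], new.gamma[t] = theta[0], theta[1], theta[2]
        new.delta[t] = np.exp(theta[3])

    # (3) jump NB parameters per transition and dynamic
    for t in range(T - 1):
        # histograms come from blocks of different sizes: align on j = 0
        hist = np.zeros((2, 2 * N_max + 1))
        for p in posteriors:
            n_b = p.jump_hist.shape[2] // 2
            hist[:, N_max - n_b : N_max + n_b + 1] += p.jump_hist[t]
        n = N_max
        both = hist[0] + hist[1]  # sides share the jump distributions
        w_exp = both[n + 1 :]  # j = 1.. -> k = j - 1 = 0..
        w_con = both[:n][::-1]  # j = -1.. -> k = -j - 1 = 0..
        for kdx, wts in ((0, w_exp), (1, w_con)):
            mu, d, ok = _fit_jump_nb(
                np.asarray(wts, dtype=float), params.jump_mu[t, kdx], params.jump_delta[t, kdx]
            )
            if ok:
                new.jump_mu[t, kdx], new.jump_delta[t, kdx] = mu, d
    return new


def fit(
    blocks: list[Block],
    config: RunConfig,
    init: ModelParameters | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    subsample: int | None = None,
    seed: int | None = None,
    callback=None,
) -> tuple[ModelParameters, FitTrace]:
    """Run EM to convergence (relative log-likelihood improvement < tol).

    ``subsample`` fits on a seeded uniform random subset of blocks for
    speed; posteriors for all blocks can then be computed with the returned
    parameters.  A likelihood decrease beyond 1e-6 raises (it would indicate
    a broken E- or M-step).
    """
    if not blocks:
        raise ValueError("no blocks to fit")
    train = blocks
    if subsample is not None and subsample < len(blocks):
        rng = np.random.default_rng(config.seed if seed is None else seed)
        idx = rng.choice(len(blocks), size=subsample, replace=False)
        train = [blocks[i] for i in sorted(idx)]
    params = init.copy() if init is not None else initialize_parameters(train, config)
    trace = FitTrace()
    prev = -np.inf
    for it in range(max_iter):
        posts = [e_step(b, params) for b in train]
        ll = float(sum(p.loglik for p in posts))
        if ll < prev - 1e-6:
            raise FloatingPointError(
                f"EM log-likelihood decreased at iteration {it}: {prev} -> {ll}"
            )
        trace.loglik.append(ll)
        if callback is not None:
            callback(it, ll, params)
        if it > 0 and (ll - prev) < tol * abs(prev):
            trace.converged = True
            break
        params = m_step(posts, train, params, config)
        prev = ll
    return params, trace


def write_fit_trace(trace: FitTrace, path) -> None:
    """Tab-delimited (iteration, log-likelihood) log."""
    with open(path, "w") as fh:
        fh.write("iteration\tlog_likelihood\n")
        for i, ll in enumerate(trace.loglik):
            fh.write(f"{i}\t{ll!r}\n")
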