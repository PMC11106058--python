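"""Spike-and-slab latent-factor Gibbs sampler for network regression.

Model: ``y_i = mu + <A_i, B>_F + eps_i`` with ``eps_i ~ N(0, tau2)``.  The
vectorized coefficients carry a scale-mixture prior ``gamma_kl ~
N(u_k' Lambda u_l, tau2 * s_kl)`` with ``s_kl ~ Exp(theta/2)``, latent node
factors ``u_k`` under a spike-and-slab prior (``u_k ~ N(0, M)`` when the node
is influential, a point mass at zero otherwise), and signed inclusion
``Lambda = diag(lambda_1..lambda_R)`` with ``lambda_r in {-1, 0, 1}``.  The
flat prior ``pi(mu, tau2) ∝ 1/tau2`` completes the model.

Every full conditional is conjugate; one sweep updates, in order,
``tau2 -> (xi_k, u_k) for k=1..V -> gamma -> s -> theta -> Delta -> M -> mu ->
(lambda_r, pi_r) for r=1..R``.  The node-inclusion probabilities are the
posterior means of ``xi`` over retained draws.

Numerical conventions: all mixture weights are computed in log space;
Cholesky factorizations escalate a diagonal jitter from 1e-10 to 1e-6 before
giving up; the GIG conditional of the scales is drawn through the reciprocal
inverse-Gaussian identity (see :func:`sample_s`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .core import Hyperparameters, IndexMap, NetworkDataset, build_design_matrix, compute_W

__all__ = [
    "ChainState",
    "RunConfig",
    "ConvergenceReport",
    "PosteriorSamples",
    "init_state",
    "sample_mu",
    "sample_tau2",
    "sample_gamma",
    "compute_w_uk",
    "sample_u_xi_k",
    "sample_s",
    "sample_s_kl",
    "sample_theta",
    "sample_Delta",
    "sample_M",
    "sample_lambda_r",
    "sample_pi_tilde_r",
    "gibbs_step",
    "run_chains",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class DegeneratePosteriorError(RuntimeError):
    """A full conditional collapsed to a degenerate distribution."""


def _cholesky(A: np.ndarray, what: str) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter."""
    scale = np.mean(np.diag(A)) or 1.0
    eye = np.eye(A.shape[0])
    for jit in _JITTERS:
        try:
            return np.linalg.cholesky(A + jit * scale * eye)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"Cholesky factorization of {what} failed even with jitter {_JITTERS[-1]}"
    )


@dataclass
class ChainState:
    """One Gibbs state.  ``u_k`` is the zero vector exactly when ``xi_k = 0``."""

    mu: float
    tau2: float
    gamma: np.ndarray          # (q,)
    u: np.ndarray              # (V, R)
    lam: np.ndarray            # (R,) values in {-1, 0, 1}
    xi: np.ndarray             # (V,) values in {0, 1}
    s: np.ndarray              # (q,) positive scales
    theta: float
    Delta: float
    M: np.ndarray              # (R, R) SPD slab covariance
    pi_tilde: np.ndarray       # (R, 3) rows on the simplex, columns (0, +1, -1)

    def copy(self) -> "ChainState":
        return ChainState(
            mu=self.mu, tau2=self.tau2, gamma=self.gamma.copy(), u=self.u.copy(),
            lam=self.lam.copy(), xi=self.xi.copy(), s=self.s.copy(), theta=self.theta,
            Delta=self.Delta, M=self.M.copy(), pi_tilde=self.pi_tilde.copy(),
        )


@dataclass
class _ModelContext:
    """Precomputed design quantities shared by all sweeps of one chain."""

    X: np.ndarray
    y: np.ndarray
    imap: IndexMap
    XtX: np.ndarray = field(init=False)
    Xt1: np.ndarray = field(init=False)
    Xty: np.ndarray = field(init=False)
    incident: np.ndarray = field(init=False)   # (V, V-1) incident column indices
    others: np.ndarray = field(init=False)     # (V, V-1) the other endpoint per row

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.XtX = self.X.T @ self.X
        self.Xt1 = self.X.sum(axis=0)
        self.Xty = self.X.T @ self.y
        V = self.imap.V
        self.incident = np.stack([self.imap.incident_columns(k) for k in range(V)])
        self.others = np.stack([np.delete(np.arange(V), k) for k in range(V)])

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]


def init_state(X: np.ndarray, y: np.ndarray, imap: IndexMap, hyper: Hyperparameters,
               rng: np.random.Generator) -> ChainState:
    """Deterministic-moment initialization; only ``u`` is drawn (chain dispersion)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0 or X.shape[0] != y.size:
        raise ValueError("X and y must be nonempty with matching sample counts")
    R, V = hyper.R, imap.V
    u = rng.standard_normal((V, R))
    lam = np.ones(R)
    pi_rows = np.empty((R, 3))
    for r in range(R):
        conc = np.array([(r + 1) * hyper.eta, 1.0, 1.0])
        pi_rows[r] = conc / conc.sum()
    return ChainState(
        mu=float(np.mean(y)),
        tau2=float(np.var(y)) if y.size > 1 and np.var(y) > 0 else 1.0,
        gamma=compute_W(u, lam, imap),
        u=u,
        lam=lam,
        xi=np.ones(V, dtype=np.int8),
        s=np.ones(imap.q),
        theta=hyper.zeta / hyper.iota,
        Delta=hyper.a_delta / (hyper.a_delta + hyper.b_delta),
        M=np.eye(R),
        pi_tilde=pi_rows,
    )


# ---------------------------------------------------------------------------
# Full conditionals
# ---------------------------------------------------------------------------

def sample_mu(y, X, gamma, tau2, rng) -> float:
    """mu | ... ~ N(mean(y - X gamma), tau2 / n)."""
    n = y.size
    resid = y - X @ gamma
    return float(rng.normal(resid.mean(), np.sqrt(tau2 / n)))


def sample_tau2(y, X, mu, gamma, W, s, rng) -> float:
    """tau2 | ... ~ InverseGamma(n/2 + q/2, RSS/2 + (gamma-W)' D^-1 (gamma-W)/2)."""
    n, q = y.size, gamma.size
    r = y - mu - X @ gamma
    d = gamma - W
    scale = 0.5 * (r @ r + d @ (d / s))
    if scale <= 0:
        raise DegeneratePosteriorError(
            "tau2 conditional has zero scale (perfect fit with gamma == W)"
        )
    shape = 0.5 * n + 0.5 * q
    return float(scale / rng.gamma(shape))


def sample_gamma(y, X, s, W, mu, tau2, rng, XtX=None, Xt1=None, Xty=None) -> np.ndarray:
    """gamma | ... ~ N((X'X + D^-1)^-1 (X'(y - mu 1) + D^-1 W), tau2 (X'X + D^-1)^-1).

    Solved through a Cholesky factorization of the precision; no explicit
    inverse is ever formed.
    """
    if XtX is None:
        XtX = X.T @ X
    if Xt1 is None:
        Xt1 = X.sum(axis=0)
    if Xty is None:
        Xty = X.T @ y
    prec = XtX + np.diag(1.0 / s)
    L = _cholesky(prec, "gamma posterior precision")
    rhs = Xty - mu * Xt1 + W / s
    mean = linalg.cho_solve((L, True), rhs, check_finite=False)
    z = rng.standard_normal(mean.size)
    # cov = tau2 * prec^-1  =>  draw = mean + sqrt(tau2) * L^-T z
    return mean + np.sqrt(tau2) * linalg.solve_triangular(
        L, z, lower=True, trans="T", check_finite=False
    )


def _log_mvn_zero(x: np.ndarray, cov_chol: np.ndarray) -> float:
    """log N(x | 0, C) given the lower Cholesky factor of C."""
    z = linalg.solve_triangular(cov_chol, x, lower=True)
    return float(
        -0.5 * x.size * np.log(2 * np.pi)
        - np.sum(np.log(np.diag(cov_chol)))
        - 0.5 * z @ z
    )


def compute_w_uk(gamma_k, H_k_diag, U_star, M, Delta, tau2) -> float:
    """Spike probability of node ``k``.

    ``w = (1-Delta) N(g_k | 0, tau2 H_k) / [(1-Delta) N(g_k | 0, tau2 H_k)
    + Delta N(g_k | 0, tau2 H_k + U* M U*')]`` computed in log space.
    """
    if Delta <= 0.0:
        return 1.0
    if Delta >= 1.0:
        return 0.0
    spike_cov = tau2 * H_k_diag
    log_spike = float(
        -0.5 * gamma_k.size * np.log(2 * np.pi)
        - 0.5 * np.sum(np.log(spike_cov))
        - 0.5 * np.sum(gamma_k**2 / spike_cov)
    )
    slab_cov = np.diag(spike_cov) + U_star @ M @ U_star.T
    log_slab = _log_mvn_zero(gamma_k, _cholesky(slab_cov, "slab marginal covariance"))
    if not (np.isfinite(log_spike) and np.isfinite(log_slab)):
        raise FloatingPointError("non-finite log-density in spike probability")
    a = np.log1p(-Delta) + log_spike
    b = np.log(Delta) + log_slab
    m = max(a, b)
    return float(np.exp(a - m) / (np.exp(a - m) + np.exp(b - m)))


def sample_u_xi_k(gamma_k, H_k_diag, U_star, M, Delta, tau2, rng, M_chol=None):
    """Joint draw of ``(xi_k, u_k)`` for one node.

    ``xi_k ~ Bernoulli(1 - w_uk)``; on inclusion ``u_k`` is drawn from the
    Gaussian slab posterior ``N(m_uk, Sigma_uk)`` with
    ``Sigma_uk = (M^-1 + U*' H_k^-1 U* / tau2)^-1`` and
    ``m_uk = Sigma_uk U*' H_k^-1 gamma_k / tau2`` (standard conjugacy of the
    ``N(0, M)`` prior with the Gaussian likelihood of the incident
    coefficients).

    The spike probability and the slab posterior share their expensive
    pieces, so the slab marginal is evaluated through the Woodbury /
    determinant-lemma identities on the R x R posterior precision rather
    than the (V-1) x (V-1) covariance:
    ``logdet(tau2 H + U* M U*') = logdet(tau2 H) + logdet(M) +
    logdet(Sigma_uk^-1)`` and ``g' (tau2 H + U* M U*')^-1 g =
    g' (tau2 H)^-1 g - b' Sigma_uk b`` with ``b = U*' (tau2 H)^-1 g``.
    """
    R = M.shape[0]
    if Delta <= 0.0:
        return 0, np.zeros(R)
    if M_chol is None:
        M_chol = _cholesky(M, "slab covariance M")
    Hs = tau2 * H_k_diag
    g_over_H = gamma_k / Hs
    quad_spike = float(gamma_k @ g_over_H)
    b = U_star.T @ g_over_H
    prec = linalg.cho_solve((M_chol, True), np.eye(R), check_finite=False) \
        + U_star.T @ (U_star / Hs[:, None])
    Lc = _cholesky(prec, "slab posterior precision")
    if Delta >= 1.0:
        w = 0.0
    else:
        z = linalg.solve_triangular(Lc, b, lower=True, check_finite=False)
        logdet_H = float(np.sum(np.log(Hs)))
        logdet_slab = logdet_H + 2.0 * float(np.sum(np.log(np.diag(M_chol)))) \
            + 2.0 * float(np.sum(np.log(np.diag(Lc))))
        log_spike = -0.5 * (logdet_H + quad_spike)
        log_slab = -0.5 * (logdet_slab + quad_spike - float(z @ z))
        a = np.log1p(-Delta) + log_spike
        c = np.log(Delta) + log_slab
        m = max(a, c)
        if not np.isfinite(m):
            raise FloatingPointError("non-finite log-density in spike probability")
        w = np.exp(a - m) / (np.exp(a - m) + np.exp(c - m))
    if rng.random() < w:
        return 0, np.zeros(R)
    mean = linalg.cho_solve((Lc, True), b, check_finite=False)
    zr = rng.standard_normal(R)
    return 1, mean + linalg.solve_triangular(Lc, zr, lower=True, trans="T",
                                             check_finite=False)


def sample_s(gamma, W, tau2, theta, rng) -> np.ndarray:
    """Vector draw of all q scales from GIG(1/2, (gamma-W)^2/tau2, theta).

    Uses the identity ``X ~ GIG(1/2, chi, psi)  <=>  1/X ~
    InverseGaussian(mean=sqrt(psi/chi), shape=psi)``; the inverse-Gaussian is
    drawn with ``rng.wald``.  Where ``chi`` underflows (coefficient equal to
    its prior mean) the exact ``chi -> 0`` limit ``Gamma(1/2, rate=psi/2)``
    is used instead.
    """
    if theta <= 0 or tau2 <= 0:
        raise ValueError("theta and tau2 must be positive")
    chi = np.maximum((gamma - W) ** 2 / tau2, 1e-300)
    tiny = chi < 1e-200 * theta
    out = np.empty_like(chi)
    if np.any(~tiny):
        c = chi[~tiny]
        out[~tiny] = 1.0 / rng.wald(np.sqrt(theta / c), theta)
    if np.any(tiny):
        out[tiny] = rng.gamma(0.5, 2.0 / theta, size=int(tiny.sum()))
    return out


def sample_s_kl(gamma_kl, prior_mean_kl, tau2, theta, rng) -> float:
    """Single-scale version of :func:`sample_s` (GIG(1/2, (g-m)^2/tau2, theta))."""
    return float(
        sample_s(np.atleast_1d(gamma_kl), np.atleast_1d(prior_mean_kl), tau2, theta, rng)[0]
    )


def sample_theta(s, hyper, rng) -> float:
    """theta | s ~ Gamma(zeta + q, rate iota + sum(s)/2), summed over all q scales."""
    shape = hyper.zeta + s.size
    rate = hyper.iota + 0.5 * float(np.sum(s))
    return float(rng.gamma(shape, 1.0 / rate))


def sample_Delta(xi, hyper, rng) -> float:
    """Delta | xi ~ Beta(a + sum(xi), b + sum(1 - xi))."""
    k = int(np.sum(xi))
    return float(rng.beta(hyper.a_delta + k, hyper.b_delta + (xi.size - k)))


def sample_M(u, xi, hyper, rng) -> np.ndarray:
    """M | u ~ InvWishart(nu + #active, I_R + sum_active u_k u_k')."""
    R = u.shape[1]
    active = np.asarray(xi, dtype=bool)
    scale = np.eye(R) + u[active].T @ u[active]
    df = hyper.nu + int(active.sum())
    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    draw = np.atleast_2d(draw)
    return (draw + draw.T) / 2.0


def _lambda_log_weights(r, gamma, u, lam, s, tau2, pi_row, imap) -> np.ndarray:
    """Unnormalized log posterior of lambda_r over the support (0, +1, -1)."""
    outer = np.outer(u[:, r], u[:, r])
    P_r = outer[imap.rows, imap.cols]
    lam_rest = lam.copy()
    lam_rest[r] = 0.0
    W_rest = compute_W(u, lam_rest, imap)
    logw = np.empty(3)
    for idx, c in enumerate((0.0, 1.0, -1.0)):
        W_c = W_rest + c * P_r
        loglik = -0.5 * np.sum((gamma - W_c) ** 2 / (tau2 * s))
        with np.errstate(divide="ignore"):
            logw[idx] = np.log(pi_row[idx]) + loglik
    return logw


def sample_lambda_r(r, gamma, u, lam, s, tau2, pi_tilde, imap, rng) -> int:
    """Three-point draw of lambda_r given everything else.

    For each candidate value the prior mean ``W`` is recomputed and the
    Gaussian likelihood of ``gamma`` evaluated; the three log weights are
    normalized by log-sum-exp.  (The Gaussian normalization constants share
    the same ``tau2 s_kl`` across candidates and cancel.)
    """
    logw = _lambda_log_weights(r, gamma, u, lam, s, tau2, pi_tilde[r], imap)
    m = logw.max()
    if not np.isfinite(m):
        raise FloatingPointError("all candidate log-weights for lambda_r are -inf")
    p = np.exp(logw - m)
    p /= p.sum()
    x = rng.random()
    idx = 0 if x < p[0] else (1 if x < p[0] + p[1] else 2)
    return (0, 1, -1)[idx]


def sample_pi_tilde_r(r, lam_r, hyper, rng) -> np.ndarray:
    """pi_r | lambda_r ~ Dirichlet((r+1 based) r*eta + 1[lam=0], 1 + 1[lam=1], 1 + 1[lam=-1])."""
    conc = np.array([
        (r + 1) * hyper.eta + (lam_r == 0),
        1.0 + (lam_r == 1),
        1.0 + (lam_r == -1),
    ])
    return rng.dirichlet(conc)


# ---------------------------------------------------------------------------
# Sweep and runner
# ---------------------------------------------------------------------------

def _gibbs_sweep(state: ChainState, ctx: _ModelContext, hyper: Hyperparameters,
                 rng: np.random.Generator, update_mean_variance: bool = True) -> ChainState:
    st = state.copy()
    imap = ctx.imap
    V = imap.V

    W = compute_W(st.u, st.lam, imap)
    if update_mean_variance:
        st.tau2 = sample_tau2(ctx.y, ctx.X, st.mu, st.gamma, W, st.s, rng)

    # node inclusion and latent factors; Delta from the previous sweep
    Lm = _cholesky(st.M, "slab covariance M")
    for k in range(V):
        cols = ctx.incident[k]
        U_star = st.u[ctx.others[k]] * st.lam
        xi_k, u_k = sample_u_xi_k(
            st.gamma[cols], st.s[cols], U_star, st.M, st.Delta, st.tau2, rng, M_chol=Lm
        )
        st.xi[k] = xi_k
        st.u[k] = u_k

    W = compute_W(st.u, st.lam, imap)
    st.gamma = sample_gamma(
        ctx.y, ctx.X, st.s, W, st.mu, st.tau2, rng, XtX=ctx.XtX, Xt1=ctx.Xt1, Xty=ctx.Xty
    )
    st.s = sample_s(st.gamma, W, st.tau2, st.theta, rng)
    st.theta = sample_theta(st.s, hyper, rng)
    st.Delta = sample_Delta(st.xi, hyper, rng)
    st.M = sample_M(st.u, st.xi, hyper, rng)
    if update_mean_variance:
        st.mu = sample_mu(ctx.y, ctx.X, st.gamma, st.tau2, rng)

    for r in range(hyper.R):
        st.lam[r] = sample_lambda_r(
            r, st.gamma, st.u, st.lam, st.s, st.tau2, st.pi_tilde, imap, rng
        )
        st.pi_tilde[r] = sample_pi_tilde_r(r, st.lam[r], hyper, rng)
    return st


def gibbs_step(state: ChainState, X, y, imap: IndexMap, hyper: Hyperparameters,
               rng: np.random.Generator, update_mean_variance: bool = True) -> ChainState:
    """One full Gibbs sweep; a pure function of ``(state, rng)``.

    Convenience wrapper that rebuilds the design context each call; the
    multi-chain runner amortizes that work across sweeps.
    """
    ctx = _ModelContext(X=X, y=y, imap=imap)
    return _gibbs_sweep(state, ctx, hyper, rng, update_mean_variance)


@dataclass
class RunConfig:
    """Multi-chain run settings: chain count, generation budget, stopping rule."""

    n_chains: int = 3
    min_samples: int = 10_000
    max_samples: int = 800_000
    burn_in_fraction: float = 0.5
    rhat_strict: float = 1.01
    rhat_loose: float = 1.1
    seed: int = 0
    check_interval: int = 10_000

    def __post_init__(self):
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.min_samples > self.max_samples:
            raise ValueError("min_samples must not exceed max_samples")
        if self.rhat_strict > self.rhat_loose:
            raise ValueError("rhat_strict must not exceed rhat_loose")
        if self.n_chains < 1 or self.check_interval < 1:
            raise ValueError("n_chains and check_interval must be positive")


@dataclass
class ConvergenceReport:
    max_rhat_gamma: float
    max_rhat_xi: float
    generations: int
    converged_strict: bool
    converged_loose: bool
    rhat_gamma: np.ndarray | None = None
    rhat_xi: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "max_rhat_gamma": self.max_rhat_gamma,
            "max_rhat_xi": self.max_rhat_xi,
            "generations": self.generations,
            "converged_strict": self.converged_strict,
            "converged_loose": self.converged_loose,
        }


@dataclass
class PosteriorSamples:
    """Retained multi-chain draws (post burn-in) plus run metadata."""

    gamma: np.ndarray      # (chains, kept, q)
    xi: np.ndarray         # (chains, kept, V)
    mu: np.ndarray         # (chains, kept)
    tau2: np.ndarray       # (chains, kept)
    index_map: IndexMap
    hyper: Hyperparameters
    config: RunConfig
    report: ConvergenceReport

    @property
    def n_kept(self) -> int:
        return self.gamma.shape[1]


def _stack(blocks: list[np.ndarray]) -> np.ndarray:
    return np.concatenate(blocks, axis=0)


def run_chains(dataset: NetworkDataset | tuple, hyper: Hyperparameters,
               config: RunConfig, progress: bool = False) -> PosteriorSamples:
    """Run independent Gibbs chains with split-R-hat-based early stopping.

    Per-chain generators are spawned from ``SeedSequence(config.seed)`` so the
    run is reproducible and chains are independent.  Every ``check_interval``
    generations past ``min_samples``, rank-normalized split R-hat is computed
    on every ``gamma`` and ``xi`` coordinate using the second half of each
    chain; sampling stops once the maximum drops to ``rhat_strict`` or the
    generation cap is hit (then a warning is emitted, never an error).
    """
    from .diagnostics import split_rhat

    if isinstance(dataset, NetworkDataset):
        dm = build_design_matrix(dataset)
        X, y, imap = dm.X, dataset.response, dm.index_map
    else:
        X, y, imap = dataset
    ctx = _ModelContext(X=X, y=y, imap=imap)

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.n_chains)]
    states = [init_state(X, y, imap, hyper, rng) for rng in rngs]

    gamma_blocks: list[list[np.ndarray]] = [[] for _ in rngs]
    xi_blocks: list[list[np.ndarray]] = [[] for _ in rngs]
    mu_blocks: list[list[np.ndarray]] = [[] for _ in rngs]
    tau2_blocks: list[list[np.ndarray]] = [[] for _ in rngs]

    total = 0
    max_rg = max_rx = np.inf
    while True:
        chunk = min(config.check_interval, config.max_samples - total)
        if total < config.min_samples:
            chunk = min(chunk, config.min_samples - total)
        for c, rng in enumerate(rngs):
            g = np.empty((chunk, ctx.q))
            x = np.empty((chunk, imap.V), dtype=np.int8)
            m = np.empty(chunk)
            t = np.empty(chunk)
            st = states[c]
            for i in range(chunk):
                st = _gibbs_sweep(st, ctx, hyper, rng)
                g[i], x[i], m[i], t[i] = st.gamma, st.xi, st.mu, st.tau2
            states[c] = st
            gamma_blocks[c].append(g)
            xi_blocks[c].append(x)
            mu_blocks[c].append(m)
            tau2_blocks[c].append(t)
        total += chunk

        if total >= config.min_samples:
            half = total // 2
            if config.n_chains >= 2:
                g_all = np.stack([_stack(b)[half:] for b in gamma_blocks])
                x_all = np.stack([_stack(b)[half:] for b in xi_blocks])
                max_rg = float(np.max(split_rhat(g_all)))
                max_rx = float(np.max(split_rhat(x_all)))
            else:
                max_rg = max_rx = 1.0
            if progress:
                print(f"  generation {total}: max R-hat gamma={max_rg:.4f} xi={max_rx:.4f}")
            if max(max_rg, max_rx) <= config.rhat_strict or total >= config.max_samples:
                break

    converged_strict = max(max_rg, max_rx) <= config.rhat_strict
    converged_loose = max(max_rg, max_rx) <= config.rhat_loose
    if not converged_strict:
        warnings.warn(
            f"chains stopped at {total} generations with max R-hat "
            f"{max(max_rg, max_rx):.4f} > {config.rhat_strict}"
            + ("" if converged_loose else f" (loose bound {config.rhat_loose} also exceeded)"),
            RuntimeWarning,
        )

    burn = int(total * config.burn_in_fraction)
    report = ConvergenceReport(
        max_rhat_gamma=max_rg, max_rhat_xi=max_rx, generations=total,
        converged_strict=converged_strict, converged_loose=converged_loose,
    )
    return PosteriorSamples(
        gamma=np.stack([_stack(b)[burn:] for b in gamma_blocks]),
        xi=np.stack([_stack(b)[burn:] for b in xi_blocks]).astype(np.int8),
        mu=np.stack([_stack(b)[burn:] for b in mu_blocks]),
        tau2=np.stack([_stack(b)[burn:] for b in tau2_blocks]),
        index_map=imap, hyper=hyper, config=config, report=report,
    )
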