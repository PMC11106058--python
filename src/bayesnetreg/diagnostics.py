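"""Convergence diagnostics, posterior summaries, and recovery metrics.

Node influence is read off the posterior probability ``pp_k = mean(xi_k)``
over retained draws; edge (and node main-effect) influence is read off
equal-tailed credible intervals of the corresponding ``gamma`` coordinate
excluding zero.  Recovery against simulation truth is scored with coefficient
and response mean squared error, false positive/negative rates at a posterior
probability cutoff, and an ROC sweep over cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import B_to_gamma, IndexMap, gamma_to_B
from .gibbs import PosteriorSamples


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Rank-normalized split R-hat per coordinate.

    ``draws`` has shape ``(chains, draws)`` or ``(chains, draws, coords)``.
    Computed with arviz (each chain split in half, between/within variance
    ratio on rank-normal scores).  A coordinate that is constant across all
    chains is degenerate and reported as 1.0; chains that are individually
    constant but disagree get ``inf``.
    """
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
        squeeze = True
    elif draws.ndim == 3:
        squeeze = False
    else:
        raise ValueError(f"draws must be 2- or 3-dimensional, got shape {draws.shape}")
    if draws.shape[0] < 2:
        raise ValueError("split R-hat requires at least 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("split R-hat requires at least 4 draws per chain")

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = az.rhat(az.convert_to_dataset(draws), method="rank")
    r = np.asarray(res["x"].values, dtype=float)

    flat = draws.reshape(-1, draws.shape[2])
    all_const = np.ptp(flat, axis=0) == 0
    chain_const = np.all(np.ptp(draws, axis=1) == 0, axis=0)
    r[np.isnan(r) & all_const] = 1.0
    r[np.isnan(r) & chain_const & ~all_const] = np.inf
    # rank-normalization can leave residual NaN on near-degenerate binaries
    r[np.isnan(r)] = 1.0
    return float(r[0]) if squeeze else r


@dataclass
class PosteriorSummary:
    """Pooled posterior point estimates, credible intervals, and influence calls."""

    pp_node: np.ndarray                     # (V,) inclusion probabilities
    gamma_mean: np.ndarray                  # (q,)
    mu_mean: float
    B_hat: np.ndarray                       # (V, V) symmetric point estimate
    gamma_ci: dict[float, np.ndarray]       # level -> (q, 2) equal-tailed CI
    index_map: IndexMap
    levels: tuple[float, ...]

    @property
    def node_ci(self) -> dict[float, np.ndarray]:
        d = self.index_map.diagonal_columns
        return {lvl: ci[d] for lvl, ci in self.gamma_ci.items()}

    @property
    def edge_ci(self) -> dict[float, np.ndarray]:
        e = self.index_map.offdiagonal_columns
        return {lvl: ci[e] for lvl, ci in self.gamma_ci.items()}

    def influence_calls(self, level: float = 0.95) -> dict[str, np.ndarray]:
        """CI-excludes-zero calls per node main effect and per edge."""
        ci = self.gamma_ci[level]
        calls = (ci[:, 0] > 0) | (ci[:, 1] < 0)
        return {
            "node": calls[self.index_map.diagonal_columns],
            "edge": calls[self.index_map.offdiagonal_columns],
        }


def summarize(samples: PosteriorSamples, levels=(0.90, 0.95)) -> PosteriorSummary:
    """Pool retained draws across chains into a :class:`PosteriorSummary`.

    ``pp_node`` is the exact arithmetic mean of the stored ``xi`` draws;
    credible intervals are equal-tailed empirical quantiles (linear / type-7
    interpolation) of the pooled ``gamma`` draws.
    """
    if samples.n_kept == 0:
        raise ValueError("no retained draws to summarize")
    gamma = samples.gamma.reshape(-1, samples.gamma.shape[2])
    xi = samples.xi.reshape(-1, samples.xi.shape[2])
    gamma_mean = gamma.mean(axis=0)
    ci = {}
    for lvl in levels:
        alpha = (1.0 - lvl) / 2.0
        ci[lvl] = np.quantile(gamma, [alpha, 1.0 - alpha], axis=0).T
    return PosteriorSummary(
        pp_node=xi.mean(axis=0),
        gamma_mean=gamma_mean,
        mu_mean=float(samples.mu.mean()),
        B_hat=gamma_to_B(gamma_mean, samples.index_map),
        gamma_ci=ci,
        index_map=samples.index_map,
        levels=tuple(levels),
    )


def predict_response(X: np.ndarray, summary: PosteriorSummary) -> np.ndarray:
    """Posterior-mean prediction ``y_hat = mu_hat + X gamma_hat``."""
    return summary.mu_mean + X @ summary.gamma_mean


@dataclass
class EvaluationResult:
    mse_coefficients: float
    mse_response: float
    node_fpr: float
    node_fnr: float
    edge_fpr: float
    edge_fnr: float
    cutoff: float
    roc_points: list[tuple[float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mse_coefficients": self.mse_coefficients,
            "mse_response": self.mse_response,
            "node_fpr": self.node_fpr, "node_fnr": self.node_fnr,
            "edge_fpr": self.edge_fpr, "edge_fnr": self.edge_fnr,
            "cutoff": self.cutoff,
            "roc_points": [list(p) for p in self.roc_points],
        }


def _rate(calls: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(false positive rate, false negative rate); 0 when a class is empty."""
    truth = truth.astype(bool)
    neg, pos = (~truth).sum(), truth.sum()
    fpr = float((calls & ~truth).sum() / neg) if neg else 0.0
    fnr = float((~calls & truth).sum() / pos) if pos else 0.0
    return fpr, fnr


def evaluate(summary: PosteriorSummary, samples: PosteriorSamples, truth, X, y,
             cutoff: float = 0.5, roc_grid=None, ci_level: float = 0.95) -> EvaluationResult:
    """Score recovery of simulation truth.

    Coefficient MSE compares the posterior mean of ``gamma`` with the true
    vectorized coefficients; response MSE compares observed and predicted
    responses.  Node influence calls use ``pp >= cutoff`` against the true
    inclusion vector; edge calls use CI-excludes-zero against the true
    influential-edge mask; the ROC sweeps the node cutoff.
    """
    if truth is None:
        raise ValueError("evaluation requires simulation truth")
    imap = summary.index_map
    gamma_true = B_to_gamma(truth.B_true, imap)
    yhat = predict_response(X, summary)
    mse_coef = float(np.mean((summary.gamma_mean - gamma_true) ** 2))
    mse_resp = float(np.mean((np.asarray(y) - yhat) ** 2))

    xi_true = np.asarray(truth.xi_true, dtype=bool)
    node_calls = summary.pp_node >= cutoff
    node_fpr, node_fnr = _rate(node_calls, xi_true)

    off = imap.offdiagonal_columns
    edge_truth = truth.edge_influential[imap.rows[off], imap.cols[off]].astype(bool)
    edge_calls = summary.influence_calls(ci_level)["edge"]
    edge_fpr, edge_fnr = _rate(edge_calls, edge_truth)

    if roc_grid is None:
        roc_grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    roc = []
    for c in roc_grid:
        fpr, fnr = _rate(summary.pp_node >= c, xi_true)
        roc.append((float(c), 1.0 - fnr, fpr))

    return EvaluationResult(
        mse_coefficients=mse_coef, mse_response=mse_resp,
        node_fpr=node_fpr, node_fnr=node_fnr,
        edge_fpr=edge_fpr, edge_fnr=edge_fnr,
        cutoff=cutoff, roc_points=roc,
    )
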