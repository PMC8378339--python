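"""Likelihood core of the variable-rate Brownian-motion model.

The trait ``x`` diffuses along the tree with a node-specific instantaneous
variance ``sigma_i^2 = exp(s_i)``; the log-rates ``s`` themselves are
modelled as Brownian on the tree.  The objective maximized by the fitting
routines is the penalized log-likelihood

    L = log N(x | 1*x0, T)  -  lambda * [ -log N(s | 1*s0, C_ext) ]

where ``T`` is the rate-scaled tip covariance (path sums of edge length
times the edge-average rate) and the bracket is the roughness penalty: the
negative log-density of the log-rates under Brownian motion on the tree.
``lambda`` is chosen by the user — it cannot be estimated, because the joint
likelihood (also provided here, for pedagogy) diverges as the rate-of-rates
goes to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny, extended_cov_matrix, mrca_height_matrix, _mrca_table

logger = logging.getLogger(__name__)

__all__ = [
    "RateState",
    "edge_average_rate",
    "scaled_cov_matrix",
    "bm_loglik",
    "single_rate_mle",
    "penalty_term",
    "penalized_loglik",
    "joint_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)

# below this log-rate difference the logarithmic mean is evaluated by its
# midpoint limit to avoid 0/0 cancellation
_LOGMEAN_TOL = 1e-8


@dataclass
class RateState:
    """Log-rates at the non-root nodes plus the root log-rate.

    ``s`` has length ``n + m - 1`` and follows the ``C_ext`` row order (tips
    ``1..n`` then internal nodes ``n+2..n+m``); ``s0`` is the root log-rate.
    """

    s: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.all(np.isfinite(self.s)) or not np.isfinite(self.s0):
            raise ValueError("log-rates must be finite")

    @classmethod
    def constant(cls, tree: Phylogeny, log_rate: float) -> "RateState":
        return cls(np.full(tree.n + tree.m - 1, float(log_rate)), float(log_rate))

    def node_log_rates(self, tree: Phylogeny) -> np.ndarray:
        """Log-rate per node id (slot 0 unused); the root carries ``s0``."""
        out = np.empty(tree.n_nodes + 1)
        out[0] = np.nan
        for pos, v in enumerate(tree.ext_node_ids()):
            out[v] = self.s[pos]
        out[tree.root_id] = self.s0
        return out

    def sigma2(self, tree: Phylogeny) -> dict[int, float]:
        """Rates ``sigma_i^2 = exp(s_i)`` keyed by node id, root included."""
        snode = self.node_log_rates(tree)
        return {v: float(np.exp(snode[v])) for v in range(1, tree.n_nodes + 1)}


def edge_average_rate(s_parent: float, s_child: float) -> float:
    """Time-average rate along an edge whose log-rate interpolates linearly.

    Integrating ``exp(s(t))`` with ``s`` linear from ``s_parent`` to
    ``s_child`` over the edge gives the logarithmic mean of the endpoint
    rates, ``(sigma_p^2 - sigma_c^2) / (s_p - s_c)``.  Near-equal log-rates
    use the midpoint limit ``exp((s_p + s_c)/2)``.  Symmetric in its
    arguments and always between the endpoint rates.
    """
    if not (np.isfinite(s_parent) and np.isfinite(s_child)):
        raise ValueError("log-rates must be finite")
    b = s_parent - s_child
    if abs(b) < _LOGMEAN_TOL:
        return float(np.exp(0.5 * (s_parent + s_child)))
    return float((np.exp(s_parent) - np.exp(s_child)) / b)


def _edge_average_rates(snode: np.ndarray, tree: Phylogeny) -> np.ndarray:
    """Edge-average rate above every non-root node (indexed by child id)."""
    out = np.full(tree.n_nodes + 1, np.nan)
    sp = snode[tree.parent[1:]]  # parent log-rate per child id 1..n+m
    sc = snode[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        b = sp - sc
        lm = np.where(
            np.abs(b) < _LOGMEAN_TOL,
            np.exp(0.5 * (sp + sc)),
            (np.exp(sp) - np.exp(sc)) / np.where(b == 0.0, 1.0, b),
        )
    out[1:] = lm
    out[tree.root_id] = np.nan
    return out


def scaled_cov_matrix(tree: Phylogeny, rates: RateState) -> np.ndarray:
    """The rate-scaled tip covariance ``T``.

    ``T[i, j]`` accumulates, over every edge on the path from the root to
    MRCA(tip i, tip j), the edge length times the edge-average rate of that
    edge's endpoint log-rates.  With all rates equal to ``sigma^2`` this is
    exactly ``sigma^2 * C``.
    """
    snode = rates.node_log_rates(tree)
    avg = _edge_average_rates(snode, tree)
    accum = np.zeros(tree.n_nodes + 1)
    for v in tree.preorder():
        if v != tree.root_id:
            accum[v] = accum[tree.parent[v]] + tree.edge_length[v] * avg[v]
    tips = list(range(1, tree.n + 1))
    return accum[_mrca_table(tree, tips)]


def bm_loglik(x: np.ndarray, V: np.ndarray, x0: float) -> float:
    """Gaussian log-likelihood of tip data with mean ``1*x0`` and covariance V.

    Computed through a Cholesky factorization; if V is not positive definite
    the state is treated as rejected and ``-inf`` is returned.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    r = x - x0
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        logger.warning("covariance not positive definite; log-likelihood -> -inf")
        return -np.inf
    except ValueError:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    quad = float(r @ cho_solve((c, low), r, check_finite=False))
    return -0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG2PI


def single_rate_mle(tree: Phylogeny, x: np.ndarray) -> tuple[float, float, float]:
    """Closed-form ML fit of constant-rate Brownian motion.

    Returns ``(sigma2_hat, x0_hat, logL)`` with the GLS root state
    ``x0 = (1'C^-1 1)^-1 1'C^-1 x`` and the ML (divide-by-n, not REML) rate
    ``sigma2 = (x - 1 x0)' C^-1 (x - 1 x0) / n``.
    """
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance; the single-rate MLE is degenerate")
    C = mrca_height_matrix(tree)
    cf = cho_factor(C, lower=True)
    one = np.ones(tree.n)
    Ci1 = cho_solve(cf, one)
    x0 = float(Ci1 @ x) / float(Ci1 @ one)
    r = x - x0
    sigma2 = float(r @ cho_solve(cf, r)) / tree.n
    logL = bm_loglik(x, sigma2 * C, x0)
    return sigma2, x0, logL


def penalty_term(rates: RateState, Cext: np.ndarray, lam: float) -> float:
    """Roughness penalty: lambda times the negative log-density of the
    log-rates under Brownian motion on the tree.

    Includes the log-determinant and ``2*pi`` constants, so the value matches
    the printed objective, not only its argmax.  Zero when ``lambda = 0``.
    """
    if lam < 0:
        raise ValueError("the smoothing coefficient lambda must be >= 0")
    if lam == 0:
        return 0.0
    s = rates.s
    k = s.size
    try:
        cf = cho_factor(Cext, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError("C_ext is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    r = s - rates.s0
    quad = float(r @ cho_solve(cf, r, check_finite=False))
    return lam * (0.5 * quad + 0.5 * logdet + 0.5 * k * _LOG2PI)


def penalized_loglik(
    tree: Phylogeny,
    x: np.ndarray,
    rates: RateState,
    x0: float,
    lam: float,
    Cext: np.ndarray | None = None,
) -> float:
    """The penalized log-likelihood: trait log-likelihood under ``T`` minus
    the roughness penalty."""
    T = scaled_cov_matrix(tree, rates)
    ll = bm_loglik(x, T, x0)
    if not np.isfinite(ll):
        return -np.inf
    if Cext is None:
        Cext = extended_cov_matrix(tree)
    return ll - penalty_term(rates, Cext, lam)


def joint_loglik(
    tree: Phylogeny,
    x: np.ndarray,
    rates: RateState,
    x0: float,
    sigma2_BM: float,
) -> float:
    """Joint log-likelihood of the data and the log-rates, treating the
    rate-of-rates ``sigma2_BM`` as a free parameter.

    Provided for diagnostics only: this objective diverges to +inf as
    ``sigma2_BM -> 0`` with the log-rates held constant (the density of the
    unobserved log-rates becomes a spike), which is why the model is fitted
    by penalized likelihood with a user-chosen lambda instead.
    """
    if sigma2_BM <= 0:
        raise ValueError("sigma2_BM must be > 0")
    T = scaled_cov_matrix(tree, rates)
    ll_x = bm_loglik(x, T, x0)
    Cext = extended_cov_matrix(tree)
    ll_s = bm_loglik(rates.s, sigma2_BM * Cext, rates.s0)
    return ll_x + ll_s
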