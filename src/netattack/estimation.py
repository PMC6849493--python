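"""Regularized network estimation from raw data.

Continuous data: a Gaussian graphical model is fitted by graphical lasso
over a log-spaced penalty grid, and the penalty is selected by the extended
Bayesian information criterion

    EBIC = -2 L + k ln(n) + 2 gamma k ln(p),

where k counts free edge parameters; edge weights are the partial
correlations implied by the selected precision matrix.  Binary data: an
Ising model is fitted by nodewise L1-penalized logistic regression with a
per-node EBIC-selected penalty; directed coefficients are reconciled into an
undirected edge by the AND rule (both directions nonzero, weight = mean) by
default.

The EBIC hyperparameter defaults are gamma = 0.5 for continuous and 0.25
for binary data, the conventional choices of the corresponding estimation
literature; both are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .network import SymptomNetwork

__all__ = [
    "EstimationConfig",
    "EstimatedNetwork",
    "partial_correlations",
    "ebic_score",
    "estimate_ggm",
    "estimate_ising",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimationConfig:
    gamma: float | None = None  # default 0.5 (continuous) / 0.25 (binary)
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    rule: Literal["and", "or"] = "and"
    data_kind: Literal["continuous", "binary"] = "continuous"

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("need at least 2 penalty values")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be nonnegative")

    def resolved_gamma(self) -> float:
        if self.gamma is not None:
            return self.gamma
        return 0.25 if self.data_kind == "binary" else 0.5


@dataclass(frozen=True)
class EstimatedNetwork:
    """Selected network plus the model-selection path that produced it."""

    network: SymptomNetwork
    selected_lambda: float | np.ndarray
    ebic_path: list[dict] = field(repr=False)
    gamma: float = 0.5


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """rho_ij = -kappa_ij / sqrt(kappa_ii kappa_jj), zero diagonal."""
    K = np.asarray(precision, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    rho = -K / np.sqrt(np.outer(d, d))
    np.fill_diagonal(rho, 0.0)
    return rho


def ebic_score(loglik: float, k: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC; gamma = 0 reduces to the ordinary BIC."""
    if n < 1 or p < 1 or k < 0:
        raise ValueError("invalid EBIC arguments")
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p)


# --------------------------------------------------------------------------
# Gaussian graphical model
# --------------------------------------------------------------------------


def _gaussian_loglik(S: np.ndarray, precision: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return (n / 2.0) * (logdet - np.trace(S @ precision) - p * np.log(2 * np.pi))


def _constrained_mle(
    S: np.ndarray, support: np.ndarray, max_iter: int = 100, tol: float = 1e-7
) -> np.ndarray:
    """Gaussian MLE of the precision matrix under a fixed zero pattern.

    Iterative proportional scaling via nodewise regressions restricted to
    each node's neighborhood (the zero-penalty analogue of the graphical
    lasso block updates).  Scoring EBIC on this refit, rather than on the
    penalized estimate, separates support complexity from shrinkage bias.
    """
    p = S.shape[0]
    W = S.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            idx = np.array([i for i in range(p) if i != j])
            ne = idx[support[idx, j]]
            if len(ne):
                beta = np.linalg.solve(
                    W[np.ix_(ne, ne)] + 1e-10 * np.eye(len(ne)), S[ne, j]
                )
                w12 = W[np.ix_(idx, ne)] @ beta
            else:
                w12 = np.zeros(p - 1)
            delta = max(delta, np.abs(W[idx, j] - w12).max(initial=0.0))
            W[idx, j] = w12
            W[j, idx] = w12
        if delta < tol:
            break
    K = np.linalg.inv(W)
    K = (K + K.T) / 2
    mask = ~support & ~np.eye(p, dtype=bool)
    K[mask] = 0.0
    return K


def estimate_ggm(
    data: np.ndarray,
    config: EstimationConfig = EstimationConfig(),
    labels: tuple[str, ...] | None = None,
    edge_tol: float = 1e-6,
) -> EstimatedNetwork:
    """EBIC-selected graphical-lasso partial-correlation network.

    The penalty grid is log-spaced from lambda_max (the smallest penalty
    yielding the empty graph, i.e. the largest absolute off-diagonal sample
    correlation) down to ``lambda_max * lambda_min_ratio``.  Candidates that
    fail to converge are dropped with a warning.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an n x p data matrix with n >= 3")
    n, p = X.shape
    sds = X.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        name = labels[zero[0]] if labels else f"column {zero[0]}"
        raise ValueError(f"zero-variance column: {name}")
    S = np.corrcoef(X, rowvar=False)
    gamma = config.resolved_gamma()

    lam_max = np.abs(S - np.eye(p)).max()
    if lam_max == 0:
        lam_max = 1e-3
    grid = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)

    path: list[dict] = []
    best = None
    cache: dict[bytes, tuple[float, np.ndarray]] = {}
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                _, prec = graphical_lasso(S, alpha=float(lam), max_iter=500, tol=1e-4)
        except (FloatingPointError, ConvergenceWarning, np.linalg.LinAlgError) as exc:
            log.warning("graphical lasso dropped at lambda=%.4g: %s", lam, exc)
            continue
        off = (prec + prec.T) / 2
        np.fill_diagonal(off, 0.0)
        support = np.abs(off) >= edge_tol
        np.fill_diagonal(support, False)
        key = np.packbits(support[np.triu_indices(p, k=1)]).tobytes()
        if key in cache:
            ll, prec_fit = cache[key]
        else:
            prec_fit = _constrained_mle(S, support)
            ll = _gaussian_loglik(S, prec_fit, n)
            cache[key] = (ll, prec_fit)
        k = int(np.count_nonzero(np.triu(support)))
        score = ebic_score(ll, k, n, p, gamma)
        path.append({"lambda": float(lam), "k": k, "loglik": ll, "ebic": float(score)})
        if best is None or score < best[0]:
            best = (score, lam, prec_fit, support)
    if best is None:
        raise RuntimeError("graphical lasso failed at every penalty value")

    _, lam_sel, prec_sel, support = best
    rho = partial_correlations(prec_sel)
    rho[~support] = 0.0
    rho = np.clip(rho, -0.999999, 0.999999)
    labels = labels or tuple(f"V{i:02d}" for i in range(p))
    return EstimatedNetwork(
        network=SymptomNetwork(tuple(labels), (rho + rho.T) / 2),
        selected_lambda=float(lam_sel),
        ebic_path=path,
        gamma=gamma,
    )


# --------------------------------------------------------------------------
# Ising model
# --------------------------------------------------------------------------


def estimate_ising(
    data: np.ndarray,
    config: EstimationConfig = EstimationConfig(data_kind="binary"),
    labels: tuple[str, ...] | None = None,
) -> EstimatedNetwork:
    """Nodewise L1 logistic Ising fit with per-node EBIC penalty selection.

    Edge i-j is kept when both directed coefficients are nonzero (AND rule,
    default) or when either is (OR rule); the edge weight is the arithmetic
    mean of the two directed coefficients.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("need an n x p binary matrix")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("entries must be 0 or 1")
    n, p = X.shape
    for j in range(p):
        if X[:, j].min() == X[:, j].max():
            name = labels[j] if labels else f"column {j}"
            raise ValueError(f"constant column: {name}")
    gamma = config.resolved_gamma()

    B = np.zeros((p, p))  # B[j, i]: coefficient of node i predicting node j
    selected = np.empty(p)
    path: list[dict] = []
    for j in range(p):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        others = [i for i in range(p) if i != j]
        Zc = Z - Z.mean(axis=0)
        lam_max = np.abs(Zc.T @ (y - y.mean())).max() / n
        lam_max = max(lam_max, 1e-4)
        # start above the zero-solution boundary so the empty model is on the path
        grid = np.geomspace(1.1 * lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
        best = None
        for lam in grid:
            # large intercept_scaling: liblinear would otherwise penalize the
            # intercept, coupling the penalty to the node's base rate
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", tol=1e-6,
                intercept_scaling=100.0,
            )
            clf.fit(Z, y)
            coefs = clf.coef_[0].copy()
            if not np.isfinite(coefs).all():  # separation fallback
                log.warning("non-finite fit for node %d at lambda=%.4g", j, lam)
                continue
            coefs[np.abs(coefs) < 1e-5] = 0.0  # numerical dust from finite tol
            eta = clf.decision_function(Z)
            ll = float(-np.sum(np.logaddexp(0, -eta) * y + np.logaddexp(0, eta) * (1 - y)))
            k = int(np.count_nonzero(coefs))
            score = ebic_score(ll, k, n, max(p - 1, 2), gamma)
            if best is None or score < best[0]:
                best = (score, lam, coefs)
            path.append(
                {"node": j, "lambda": float(lam), "k": k, "ebic": float(score)}
            )
        if best is None:
            log.warning("node %d: all fits failed; using empty neighborhood", j)
            selected[j] = lam_max
            continue
        _, lam_sel, coefs = best
        selected[j] = lam_sel
        for idx, i in enumerate(others):
            B[j, i] = coefs[idx]

    nz = B != 0
    if config.rule == "and":
        keep = nz & nz.T
    elif config.rule == "or":
        keep = nz | nz.T
    else:
        raise ValueError(f"unknown rule {config.rule!r}")
    W = np.where(keep, (B + B.T) / 2.0, 0.0)
    np.fill_diagonal(W, 0.0)
    labels = labels or tuple(f"V{i:02d}" for i in range(p))
    return EstimatedNetwork(
        network=SymptomNetwork(tuple(labels), W),
        selected_lambda=selected,
        ebic_path=path,
        gamma=gamma,
    )
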