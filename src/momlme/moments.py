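"""OLS initialization and variance-component estimation.

Variance fractions are estimated by the method of moments: the empirical
products of OLS residuals for the pairs in a :class:`~momlme.model_core.PairIndex`,
scaled by the total residual variance, are regressed on the pair design L.
The one-shot matrix solve ``(L'L)^{-1} L'R`` handles all J outcomes at once;
outcomes whose unconstrained solution has a negative component are re-solved
exactly under the non-negativity constraint.  A per-outcome profile maximum
likelihood estimator is available as a slower alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.optimize as spo

from .model_core import OutcomeMatrix, PairIndex, RandomEffectsDesign

__all__ = [
    "OlsFit",
    "VarianceComponents",
    "fit_ols",
    "residual_products",
    "estimate_components_mom",
    "estimate_components_ml",
]

_ZERO_VAR_TOL = 1e-24  # relative to the outcome's mean square


@dataclass
class OlsFit:
    """Ordinary least squares fit shared by all outcome columns."""

    beta: np.ndarray        # p x J
    residuals: np.ndarray   # N x J
    sigma2_total: np.ndarray  # J, residual sum of squares / (N - p)
    valid: np.ndarray       # J bools, False where the residual variance is zero


@dataclass
class VarianceComponents:
    """Normalized variance fractions theta (modeled effects then E) per outcome.

    ``theta`` is scaled so that ``sum_e theta_e * mean(diag K_e) + theta_E = 1``,
    i.e. the normalized covariance V has average diagonal one; the original
    scale is recovered by multiplying with ``sigma2_total``.
    """

    theta: np.ndarray        # (n_effects + 1) x J
    sigma2_total: np.ndarray  # J
    labels: list[str]
    estimator_tag: str = "mom"
    diag_means: np.ndarray | None = None  # kernel diagonal means (error last)

    def norm_weights(self) -> np.ndarray:
        if self.diag_means is None:
            return np.ones(self.theta.shape[0])
        return self.diag_means


def fit_ols(X: np.ndarray, Y) -> OlsFit:
    """Fit OLS for every outcome column with one factorization of X."""
    if isinstance(Y, OutcomeMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than covariates (N={n}, p={p})")
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) <= n * np.finfo(float).eps * np.max(np.abs(np.diag(R))):
        raise ValueError("X is rank deficient")
    beta = sla.solve_triangular(R, Q.T @ Y)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y) / n, 1.0)
    valid = sigma2 > _ZERO_VAR_TOL * scale
    return OlsFit(beta=beta, residuals=resid, sigma2_total=sigma2, valid=valid)


def residual_products(ols: OlsFit, pair_index: PairIndex) -> np.ndarray:
    """Scaled residual products, one row per pair and one column per outcome.

    Entry (q, j) is ``r[i_q, j] * r[i'_q, j] / sigma2_j``.  Outcomes with
    zero residual variance produce NaN columns and a warning; they carry no
    information about variance fractions.
    """
    if not np.all(ols.valid):
        warnings.warn(
            f"{int((~ols.valid).sum())} outcome(s) have zero residual variance; "
            "their variance components are reported as missing",
            stacklevel=2,
        )
    sigma2 = np.where(ols.valid, ols.sigma2_total, np.nan)
    r = ols.residuals
    return r[pair_index.i] * r[pair_index.j] / sigma2


def _nnls_from_normal_eqs(G: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares given the normal equations G, c.

    Minimizing ||L t - r||^2 over t >= 0 is equivalent to minimizing
    ||U t - U^{-T} c||^2 where U is the Cholesky factor of G = L'L.
    """
    U = sla.cholesky(G, lower=False)
    b = sla.solve_triangular(U, c, trans="T")
    t, _ = spo.nnls(U, b)
    return t


def estimate_components_mom(
    pair_index: PairIndex,
    products: np.ndarray,
    sigma2_total: np.ndarray,
    negative_mode: str = "exact",
) -> VarianceComponents:
    """Method-of-moments variance fractions for all outcomes at once.

    Solves the unconstrained normal equations ``(L'L)^{-1} L'R`` in a single
    matrix expression.  Outcomes with a negative component are re-solved
    under theta >= 0: exactly (``negative_mode='exact'``, non-negative least
    squares) or by clamping at zero (``'clamp'``, faster but approximate).
    The result is rescaled so the normalized total residual variance is one.
    """
    if negative_mode not in ("exact", "clamp"):
        raise ValueError("negative_mode must be 'exact' or 'clamp'")
    L = pair_index.L
    n_comp = L.shape[1]
    G = L.T @ L
    # an effect with no informative off-diagonal pair makes G singular
    if np.linalg.cond(G) > 1e12:
        raise ValueError(
            "method-of-moments design is singular: some effect has no "
            "informative observation pairs"
        )
    valid = np.all(np.isfinite(products), axis=0)
    theta = np.full((n_comp, products.shape[1]), np.nan)
    if valid.any():
        c = L.T @ products[:, valid]
        t = sla.solve(G, c, assume_a="pos")
        neg = np.flatnonzero(np.any(t < 0, axis=0))
        if negative_mode == "clamp":
            t = np.maximum(t, 0.0)
        else:
            for k in neg:
                t[:, k] = _nnls_from_normal_eqs(G, c[:, k])
        theta[:, valid] = t

    # normalize: sum_e theta_e * mean(diag K_e) + theta_E = 1
    denom = pair_index.diag_means @ np.nan_to_num(theta)
    degenerate = valid & (denom <= 1e-12)
    safe = np.where(denom > 1e-12, denom, 1.0)
    theta = theta / safe
    if degenerate.any():
        theta[:, degenerate] = 0.0
        theta[-1, degenerate] = 1.0
    return VarianceComponents(
        theta=theta,
        sigma2_total=np.asarray(sigma2_total, dtype=np.float64),
        labels=list(pair_index.effect_labels),
        estimator_tag="mom",
        diag_means=pair_index.diag_means,
    )


def _neg_loglik(v: np.ndarray, blocks, X: np.ndarray, y: np.ndarray) -> float:
    """-2 log likelihood at raw component variances v, with beta profiled out."""
    n, p = X.shape
    logdet = 0.0
    xtvix = np.zeros((p, p))
    xtviy = np.zeros(p)
    ytviy = 0.0
    for idx2d, kernels in blocks:
        k, m = idx2d.shape
        V = v[-1] * np.eye(m)[None, :, :].repeat(k, axis=0)
        for e, Kb in enumerate(kernels):
            V += v[e] * Kb
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet += 2.0 * np.sum(np.log(np.einsum("kii->ki", C)))
        rhs = np.concatenate([X[idx2d], y[idx2d][:, :, None]], axis=2)
        sol = np.linalg.solve(V, rhs)
        Xb = X[idx2d]
        yb = y[idx2d]
        xtvix += np.einsum("kmp,kmq->pq", Xb, sol[:, :, :p])
        xtviy += np.einsum("kmp,km->p", Xb, sol[:, :, p])
        ytviy += np.einsum("km,km->", yb, sol[:, :, p])
    beta = np.linalg.solve(xtvix, xtviy)
    quad = ytviy - beta @ xtviy
    return logdet + quad + n * np.log(2.0 * np.pi)


def estimate_components_ml(
    design: RandomEffectsDesign,
    X: np.ndarray,
    Y,
    theta_init: VarianceComponents | None = None,
) -> VarianceComponents:
    """Per-outcome profile maximum likelihood over the component variances.

    Maximizes the Gaussian log likelihood over raw variances v >= 0 with the
    fixed effects profiled out by GLS at each candidate v.  Initialization
    defaults to the method-of-moments estimate.  Outcomes whose optimizer
    fails to converge fall back to the initial value with a warning.
    """
    from .gls import family_block_index  # local import to avoid a cycle

    if isinstance(Y, OutcomeMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if theta_init is None:
        from .model_core import build_pair_index

        ols = fit_ols(X, Y)
        pidx = build_pair_index(design)
        theta_init = estimate_components_mom(
            pidx, residual_products(ols, pidx), ols.sigma2_total
        )
    blocks = family_block_index(design)
    n_comp = design.n_effects + 1
    diag_means = design.diag_means
    theta = np.empty((n_comp, Y.shape[1]))
    sigma2 = np.empty(Y.shape[1])
    failed = []
    for jcol in range(Y.shape[1]):
        v0 = np.maximum(
            theta_init.theta[:, jcol] * theta_init.sigma2_total[jcol], 1e-4
        )
        if not np.all(np.isfinite(v0)):
            theta[:, jcol] = np.nan
            sigma2[jcol] = np.nan
            continue
        res = spo.minimize(
            _neg_loglik,
            v0,
            args=(blocks, X, Y[:, jcol]),
            method="L-BFGS-B",
            bounds=[(1e-10, None)] * n_comp,
        )
        v = res.x if res.success else v0
        if not res.success:
            failed.append(jcol)
        tot = float(diag_means @ v)
        theta[:, jcol] = v / tot
        sigma2[jcol] = tot
    if failed:
        warnings.warn(
            f"ML optimizer did not converge for outcomes {failed[:10]}; "
            "falling back to the initial estimate for those",
            stacklevel=2,
        )
    return VarianceComponents(
        theta=theta,
        sigma2_total=sigma2,
        labels=design.labels,
        estimator_tag="ml",
        diag_means=diag_means,
    )
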