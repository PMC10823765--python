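"""Binned generalized least squares, Wald inference, and wild bootstrap.

Fitting one GLS per outcome would require one covariance factorization per
outcome.  Instead, outcomes are grouped on a regular grid over their
estimated variance fractions (grid spacing 1/K for bin value K): all
outcomes in a grid cell share one normalized covariance V and hence one
factorization.  Because subjects are nested in families and kernels are
family-block-diagonal, V factors family by family; blocks are grouped by
family size and solved as stacked batches, which keeps the per-cell cost a
handful of vectorized LAPACK calls regardless of the number of families.

The GLS covariance ``Var(beta_j) = sigma_j^2 (X' V^{-1} X)^{-1}`` uses the
normalized V, so the per-outcome scalar ``sigma_j^2`` multiplies a single
shared matrix per cell.  Wald ratios are referred to the standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .model_core import (
    CategoricalEffect,
    ObservationFrame,
    OutcomeMatrix,
    PairIndex,
    RandomEffectsDesign,
    build_design,
    build_pair_index,
)
from .moments import (
    OlsFit,
    VarianceComponents,
    estimate_components_mom,
    fit_ols,
    residual_products,
)

__all__ = [
    "BinAssignment",
    "BlockCovariance",
    "FixedEffectsResult",
    "FitResult",
    "assign_bins",
    "compose_covariance",
    "fit_gls",
    "wald_inference",
    "contrast",
    "wild_bootstrap_ci",
    "fit",
    "binned_gls",
    "family_block_index",
]

#: lower bound on the error fraction when composing V, guaranteeing positive
#: definiteness; inert for realistic data where theta_E is well above it
THETA_E_FLOOR = 1e-4


def family_block_index(design: RandomEffectsDesign):
    """Per-family kernel blocks grouped by family size.

    Returns a list of ``(idx2d, kernels)`` entries, one per distinct family
    size m: ``idx2d`` is a (k, m) array of observation row indices for the k
    families of that size and ``kernels[e]`` a (k, m, m) stack of the e-th
    effect's kernel blocks.  Cached on the design.
    """
    if design._block_cache is not None:
        return design._block_cache
    codes = design.family_codes
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    ends = np.r_[starts[1:], codes.shape[0]]
    sizes = ends - starts
    groups = []
    for m in np.unique(sizes):
        sel = np.flatnonzero(sizes == m)
        idx2d = np.stack([order[starts[g] : ends[g]] for g in sel])
        kernels = []
        for eff in design.effects:
            if isinstance(eff, CategoricalEffect):
                c = eff.codes[idx2d]
                Kb = (c[:, :, None] == c[:, None, :]).astype(np.float64)
            else:
                Kd = eff.K
                Kb = np.stack([np.asarray(Kd[rows][:, rows].todense()) for rows in idx2d])
            kernels.append(Kb)
        groups.append((idx2d, kernels))
    design._block_cache = groups
    return groups


class BlockCovariance:
    """Normalized covariance V for one grid cell, factored family-by-family.

    ``V = sum_e theta_e K_e + theta_E I`` assembled per family block; blocks
    of equal size are stacked so that factorization and solves are batched.
    """

    def __init__(self, theta: np.ndarray, design: RandomEffectsDesign):
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (design.n_effects + 1,):
            raise ValueError("theta must have one entry per effect plus error")
        if np.any(theta < 0):
            raise ValueError("theta must be non-negative")
        if theta[-1] < THETA_E_FLOOR:
            theta = theta.copy()
            theta[-1] = THETA_E_FLOOR
        self.theta = theta
        self.design = design
        self._groups = []
        for idx2d, kernels in family_block_index(design):
            k, m = idx2d.shape
            V = np.broadcast_to(theta[-1] * np.eye(m), (k, m, m)).copy()
            for e, Kb in enumerate(kernels):
                V += theta[e] * Kb
            # Cholesky doubles as the positive-definiteness guard
            np.linalg.cholesky(V)
            self._groups.append((idx2d, V))

    def solve(self, M: np.ndarray) -> np.ndarray:
        """Return V^{-1} M for a dense N x r right-hand side."""
        single = M.ndim == 1
        if single:
            M = M[:, None]
        out = np.empty_like(M, dtype=np.float64)
        for idx2d, V in self._groups:
            out[idx2d.ravel()] = np.linalg.solve(V, M[idx2d]).reshape(
                -1, M.shape[1]
            )
        return out[:, 0] if single else out

    def dense(self) -> np.ndarray:
        """Materialize V (for small problems / testing)."""
        n = self.design.n_obs
        V = np.zeros((n, n))
        for idx2d, Vb in self._groups:
            for rows, block in zip(idx2d, Vb):
                V[np.ix_(rows, rows)] = block
        return V

    def diagonal(self) -> np.ndarray:
        n = self.design.n_obs
        d = np.empty(n)
        for idx2d, Vb in self._groups:
            d[idx2d.ravel()] = np.einsum("kii->ki", Vb).ravel()
        return d


def compose_covariance(theta: np.ndarray, design: RandomEffectsDesign) -> BlockCovariance:
    """Assemble the normalized covariance for one component vector."""
    return BlockCovariance(theta, design)


@dataclass
class BinAssignment:
    """Grid-cell membership of outcomes sharing one GLS covariance."""

    n_bins: int
    cell_index: np.ndarray       # J x n_effects integer grid coordinates (-1: excluded)
    cells: list                  # (key, member_indices, representative_theta)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def assign_bins(components: VarianceComponents, n_bins: int) -> BinAssignment:
    """Group outcomes whose variance fractions fall in the same grid cell.

    Each modeled-effect fraction maps to cell ``floor(theta * K)`` over
    half-open cells [k/K, (k+1)/K), with theta = 1 assigned to the top cell.
    A cell's representative component vector is the renormalized mean of its
    members' estimates, so it differs from any member by less than 1/K per
    coordinate.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    theta = components.theta
    n_eff = theta.shape[0] - 1
    J = theta.shape[1]
    valid = np.all(np.isfinite(theta), axis=0)
    cell_index = np.full((J, max(n_eff, 1)), -1, dtype=np.int64)
    modeled = theta[:-1, :]
    idx = np.clip(np.floor(modeled.T * n_bins).astype(np.int64), 0, n_bins - 1)
    cell_index[valid] = idx[valid] if n_eff else 0
    cells = []
    if valid.any():
        keys, inverse = np.unique(cell_index[valid], axis=0, return_inverse=True)
        vidx = np.flatnonzero(valid)
        for c in range(keys.shape[0]):
            members = vidx[inverse == c]
            rep = theta[:, members].mean(axis=1)
            rep = rep / _norm_denom(rep, components)
            cells.append((tuple(keys[c]), members, rep))
    return BinAssignment(n_bins=n_bins, cell_index=cell_index, cells=cells)


def _norm_denom(theta_vec: np.ndarray, components: VarianceComponents) -> float:
    # representative vectors are renormalized with the same kernel diagonal
    # weighting used for per-outcome estimates
    return float(components.norm_weights() @ theta_vec)


@dataclass
class FixedEffectsResult:
    """Per-outcome GLS fixed effects with Wald inference."""

    beta: np.ndarray      # p x J
    se: np.ndarray        # p x J
    z: np.ndarray         # p x J
    p_value: np.ndarray   # p x J
    sigma2_total: np.ndarray            # J
    cov_base: list = field(default_factory=list)   # per cell (X'V^{-1}X)^{-1}
    cell_of_outcome: np.ndarray | None = None      # J ints into cov_base
    covariate_names: list[str] = field(default_factory=list)
    outcome_names: list[str] = field(default_factory=list)

    def cov_beta(self, j: int) -> np.ndarray:
        """Var(beta_j) = sigma_j^2 (X' V^{-1} X)^{-1} for outcome j."""
        if self.cell_of_outcome is None or self.cell_of_outcome[j] < 0:
            raise ValueError(f"no covariance retained for outcome {j}")
        return self.sigma2_total[j] * self.cov_base[self.cell_of_outcome[j]]


def fit_gls(
    X: np.ndarray,
    Y_cell: np.ndarray,
    cov: BlockCovariance,
    sigma2_total: np.ndarray,
):
    """GLS fixed effects for the outcomes sharing one covariance cell.

    ``(X' V^{-1} X)^{-1}`` and ``X' V^{-1}`` are computed once and applied to
    every member outcome.  Returns (beta, se, cov_base) where ``cov_base`` is
    the shared unscaled covariance of beta.
    """
    Y_cell = np.atleast_2d(np.asarray(Y_cell, dtype=np.float64))
    if Y_cell.shape[0] != X.shape[0]:
        Y_cell = Y_cell.T
    rhs = np.concatenate([X, Y_cell], axis=1)
    sol = cov.solve(rhs)
    p = X.shape[1]
    A = X.T @ sol[:, :p]
    cov_base = np.linalg.inv(A)
    beta = cov_base @ (X.T @ sol[:, p:])
    se = np.sqrt(np.outer(np.diag(cov_base), sigma2_total))
    return beta, se, cov_base


def wald_inference(beta: np.ndarray, se: np.ndarray):
    """Wald ratios and two-tailed standard-normal p-values."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    # floor keeps p in (0, 1] when the survival function underflows (|z| > ~38)
    p = np.maximum(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny)
    p = np.where(np.isnan(z), np.nan, p)
    return z, p


def contrast(result: FixedEffectsResult, c: np.ndarray):
    """Estimate, SE, Wald ratio and p-value of c' beta for every outcome."""
    c = np.asarray(c, dtype=np.float64)
    if c.shape != (result.beta.shape[0],):
        raise ValueError(
            f"contrast length {c.shape} does not match {result.beta.shape[0]} covariates"
        )
    est = c @ result.beta
    var_unit = np.array([float(c @ B @ c) for B in result.cov_base])
    var = var_unit[result.cell_of_outcome] * result.sigma2_total
    se = np.sqrt(np.maximum(var, 0.0))
    z, p = wald_inference(est, se)
    return est, se, z, p


@dataclass
class FitResult:
    """Output bundle of the full pipeline."""

    fixed: FixedEffectsResult
    components: VarianceComponents
    bins: BinAssignment
    ols: OlsFit


def fit(
    frame: ObservationFrame,
    Y,
    effects=("F", "S"),
    kernels=None,
    n_bins: int = 20,
    estimator: str = "mom",
    iterations: int = 1,
    zero_tol: float = 0.0,
    negative_mode: str = "exact",
    design: RandomEffectsDesign | None = None,
) -> FitResult:
    """Full pipeline: OLS -> moment components -> binning -> GLS -> Wald.

    ``iterations`` > 1 repeats the component/GLS stage using residuals from
    the previous GLS fit; one pass is the default and is usually sufficient.
    """
    if isinstance(Y, OutcomeMatrix):
        names = Y.outcome_names
        Y = Y.Y
    else:
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim == 1:
            Y = Y[:, None]
        names = [f"y{k}" for k in range(Y.shape[1])]
    if design is None:
        design = build_design(frame, effects, kernels)
    X = frame.X
    ols = fit_ols(X, Y)
    pidx = build_pair_index(design, zero_tol=zero_tol)

    resid = ols.residuals
    sigma2 = ols.sigma2_total
    comps = bins = None
    fixed = None
    for _ in range(max(iterations, 1)):
        prods = resid[pidx.i] * resid[pidx.j] / np.where(ols.valid, sigma2, np.nan)
        comps = estimate_components_mom(pidx, prods, sigma2, negative_mode=negative_mode)
        if estimator == "ml":
            from .moments import estimate_components_ml

            comps = estimate_components_ml(design, X, Y, theta_init=comps)
        elif estimator != "mom":
            raise ValueError("estimator must be 'mom' or 'ml'")
        bins = assign_bins(comps, n_bins)
        fixed = binned_gls(X, Y, design, bins, sigma2, ols, names, frame)
        resid = Y - X @ fixed.beta
    return FitResult(fixed=fixed, components=comps, bins=bins, ols=ols)


def binned_gls(X, Y, design, bins, sigma2, ols, names, frame) -> FixedEffectsResult:
    p, J = X.shape[1], Y.shape[1]
    beta = np.full((p, J), np.nan)
    se = np.full((p, J), np.nan)
    cov_base = []
    cell_of = np.full(J, -1, dtype=np.int64)
    for key, members, rep in bins.cells:
        cov = BlockCovariance(rep, design)
        b, s, base = fit_gls(X, Y[:, members], cov, sigma2[members])
        beta[:, members] = b
        se[:, members] = s
        cell_of[members] = len(cov_base)
        cov_base.append(base)
    z, pv = wald_inference(beta, se)
    return FixedEffectsResult(
        beta=beta,
        se=se,
        z=z,
        p_value=pv,
        sigma2_total=sigma2,
        cov_base=cov_base,
        cell_of_outcome=cell_of,
        covariate_names=list(frame.covariate_names),
        outcome_names=list(names),
    )


@dataclass
class BootstrapCI:
    """Percentile confidence intervals of variance components."""

    lower: np.ndarray      # (n_effects + 1) x J, normalized fractions
    upper: np.ndarray
    lower_raw: np.ndarray  # original variance scale (fraction * sigma2)
    upper_raw: np.ndarray
    point: VarianceComponents
    n_draws: int


def wild_bootstrap_ci(
    frame: ObservationFrame,
    Y,
    effects=("F", "S"),
    kernels=None,
    n_draws: int = 100,
    percentiles=(2.5, 97.5),
    seed: int | None = None,
    weights: str = "mammen",
    design: RandomEffectsDesign | None = None,
) -> BootstrapCI:
    """Wild-bootstrap CIs for the variance components.

    Each draw multiplies every family block of OLS residuals by an i.i.d.
    multiplier, rebuilds the outcomes, and re-estimates the components; the
    CI is the empirical percentile band across draws.  The family is the
    resampling unit because it is the exchangeable block of the model.

    Mammen's two-point weights are the default: a variance-component draw
    depends on the residual products within a block, which are scaled by the
    squared multiplier, so a weight with constant square (Rademacher signs,
    available via ``weights='rademacher'``) leaves them unchanged and yields
    degenerate intervals for the components.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if isinstance(Y, OutcomeMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if design is None:
        design = build_design(frame, effects, kernels)
    rng = np.random.default_rng(seed)
    X = frame.X
    ols = fit_ols(X, Y)
    pidx = build_pair_index(design)
    prods = residual_products(ols, pidx)
    point = estimate_components_mom(pidx, prods, ols.sigma2_total)

    lo_q, hi_q = percentiles
    min_draws = int(np.ceil(100.0 / min(lo_q, 100.0 - hi_q)))
    if n_draws < min_draws:
        warnings.warn(
            f"{n_draws} draws cannot resolve the {percentiles} percentiles; "
            "reporting min/max instead",
            stacklevel=2,
        )
    fam = frame.family_codes
    n_fam = fam.max() + 1
    fitted = X @ ols.beta
    draws_theta = np.empty((n_draws,) + point.theta.shape)
    draws_raw = np.empty_like(draws_theta)
    for b in range(n_draws):
        if weights == "rademacher":
            w = rng.choice([-1.0, 1.0], size=n_fam)
        elif weights == "mammen":
            phi = (1.0 + np.sqrt(5.0)) / 2.0
            w = rng.choice(
                [1.0 - phi, phi], size=n_fam, p=[phi / np.sqrt(5.0), 1.0 - phi / np.sqrt(5.0)]
            )
        else:
            raise ValueError("weights must be 'rademacher' or 'mammen'")
        Yb = fitted + ols.residuals * w[fam][:, None]
        ob = fit_ols(X, Yb)
        pb = ob.residuals[pidx.i] * ob.residuals[pidx.j] / np.where(
            ob.valid, ob.sigma2_total, np.nan
        )
        cb = estimate_components_mom(pidx, pb, ob.sigma2_total)
        draws_theta[b] = cb.theta
        draws_raw[b] = cb.theta * cb.sigma2_total
    lower = np.percentile(draws_theta, lo_q, axis=0)
    upper = np.percentile(draws_theta, hi_q, axis=0)
    lower_raw = np.percentile(draws_raw, lo_q, axis=0)
    upper_raw = np.percentile(draws_raw, hi_q, axis=0)
    return BootstrapCI(
        lower=lower,
        upper=upper,
        lower_raw=lower_raw,
        upper_raw=upper_raw,
        point=point,
        n_draws=n_draws,
    )
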