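"""Core domain types for the mass-univariate linear mixed-effects model.

The model for outcome ``j`` is ``y_j = X beta_j + eps_j`` with
``eps_j ~ N(0, V_j)``.  The residual covariance decomposes into variance
components contributed by random intercepts for grouping factors (family F,
subject S) and/or continuous relatedness kernels (e.g. a genetic relatedness
matrix A), plus uncorrelated measurement error E::

    V_j / sigma_j^2 = theta_F Z_F Z_F' + theta_S Z_S Z_S' + ... + theta_E I

Subjects are required to be nested within families, which makes every
kernel block-diagonal with respect to families and lets downstream solvers
factor V family-by-family.

The :class:`PairIndex` is the sparse set of observation pairs with at least
one nonzero kernel entry.  It is the design matrix of the method-of-moments
regression: the expected scaled product of residuals for a pair (i, i')
equals ``sum_e theta_e K_e(i, i')`` plus ``theta_E`` on the diagonal, so the
variance fractions can be estimated by regressing empirical residual
products on the kernel columns.  Pairs whose kernel row is entirely zero
contribute nothing to the normal equations and are dropped exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ObservationFrame",
    "CategoricalEffect",
    "KernelEffect",
    "RandomEffectsDesign",
    "PairIndex",
    "OutcomeMatrix",
    "build_design",
    "build_pair_index",
]

#: grouping-factor labels with a built-in meaning
_GROUPING_LABELS = {"F": "family", "S": "subject"}

_SYM_TOL = 1e-8


@dataclass
class ObservationFrame:
    """Observations with their grouping labels and fixed-effect covariates.

    Parameters
    ----------
    subject_id, family_id
        One label per observation.  Every subject must belong to exactly
        one family (nesting); crossed designs are rejected.
    X
        N x p covariate matrix (fixed effects).  Must have full column rank.
    covariate_names
        Optional p labels; defaults to ``x0..x{p-1}``.
    """

    subject_id: np.ndarray
    family_id: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.family_id = np.asarray(self.family_id)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n = self.X.shape[0]
        if self.subject_id.shape != (n,) or self.family_id.shape != (n,):
            raise ValueError("subject_id/family_id must have one entry per row of X")
        if not self.covariate_names:
            self.covariate_names = [f"x{k}" for k in range(self.X.shape[1])]
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        # subjects nested in families: each subject maps to exactly one family
        sub_fam = pd.DataFrame({"s": self.subject_id, "f": self.family_id})
        nfam_per_sub = sub_fam.groupby("s", sort=False)["f"].nunique()
        if (nfam_per_sub > 1).any():
            bad = nfam_per_sub[nfam_per_sub > 1].index.tolist()[:5]
            raise ValueError(
                f"subjects must be nested within families; offending subjects: {bad}"
            )
        if n > self.X.shape[1] and np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient")
        self.subject_codes = pd.factorize(self.subject_id)[0]
        self.family_codes = pd.factorize(self.family_id)[0]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class CategoricalEffect:
    """Random intercept for a grouping factor; implied kernel is ZZ'."""

    label: str
    codes: np.ndarray  # integer group code per observation

    @property
    def diag_mean(self) -> float:
        return 1.0  # ZZ' has unit diagonal

    def kernel_entries(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return (self.codes[i] == self.codes[j]).astype(np.float64)


@dataclass
class KernelEffect:
    """Random effect defined by a symmetric relatedness kernel (e.g. a GRM)."""

    label: str
    K: sp.csr_matrix

    @property
    def diag_mean(self) -> float:
        return float(self.K.diagonal().mean())

    def kernel_entries(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return np.asarray(self.K[i, j]).ravel()


@dataclass
class RandomEffectsDesign:
    """Ordered random-effect specs; the error effect E is implicit and last."""

    effects: list
    n_obs: int
    family_codes: np.ndarray
    subject_codes: np.ndarray

    def __post_init__(self) -> None:
        labels = [e.label for e in self.effects]
        if len(set(labels)) != len(labels):
            raise ValueError("effect labels must be unique")
        if "E" in labels:
            raise ValueError("the error effect E is implicit and may not be supplied")
        self._block_cache = None

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.effects] + ["E"]

    @property
    def n_effects(self) -> int:
        """Number of modeled effects, excluding the implicit error term."""
        return len(self.effects)

    @property
    def diag_means(self) -> np.ndarray:
        """Mean kernel diagonal per effect (error term last, always 1)."""
        return np.array([e.diag_mean for e in self.effects] + [1.0])


@dataclass
class PairIndex:
    """Sparse observation-pair design of the method-of-moments regression.

    ``L[q, e]`` holds the kernel value of effect ``e`` for pair ``q``; the
    last column is the diagonal indicator for the error variance.  Every
    diagonal pair (i, i) is present; an off-diagonal pair is present iff
    some kernel entry exceeds ``zero_tol`` in absolute value.
    """

    i: np.ndarray
    j: np.ndarray
    L: np.ndarray
    diag_mask: np.ndarray
    effect_labels: list[str]
    diag_means: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.i.shape[0]


@dataclass
class OutcomeMatrix:
    """N x J outcome matrix (voxels, vertices, ROIs, ... as columns)."""

    Y: np.ndarray
    outcome_names: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if not self.outcome_names:
            self.outcome_names = [f"y{k}" for k in range(self.Y.shape[1])]
        if len(self.outcome_names) != self.Y.shape[1]:
            raise ValueError("outcome_names length must match Y columns")
        if self.standardized:
            mu = self.Y.mean(axis=0)
            sd = self.Y.std(axis=0, ddof=0)
            ok = np.allclose(mu, 0.0, atol=1e-6) and np.allclose(sd, 1.0, atol=1e-6)
            if not ok:
                raise ValueError("standardized flag set but columns are not z-scored")

    @property
    def n_outcomes(self) -> int:
        return self.Y.shape[1]


def _as_csr(K, n: int) -> sp.csr_matrix:
    if sp.issparse(K):
        K = K.tocsr()
    else:
        K = sp.csr_matrix(np.asarray(K, dtype=np.float64))
    if K.shape != (n, n):
        raise ValueError(f"kernel must be {n} x {n}, got {K.shape}")
    asym = abs(K - K.T)
    if asym.nnz and asym.max() > _SYM_TOL:
        raise ValueError("kernel matrix is not symmetric")
    if K.diagonal().min() < 0:
        raise ValueError("kernel diagonal must be non-negative")
    return K


def build_design(
    frame: ObservationFrame,
    effect_labels: Sequence[str],
    kernel_inputs: Mapping[str, object] | None = None,
) -> RandomEffectsDesign:
    """Assemble the random-effects design from requested effect labels.

    ``"F"`` and ``"S"`` select family and subject random intercepts; any
    other label requires a matching N x N kernel in ``kernel_inputs``
    (aligned to observation order).  Kernels must be block-diagonal with
    respect to families: cross-family entries are rejected because the
    covariance solver factors V family by family.
    """
    kernel_inputs = kernel_inputs or {}
    effects = []
    for lab in effect_labels:
        if lab == "E":
            raise ValueError("the error effect E is implicit and may not be requested")
        if lab == "F":
            effects.append(CategoricalEffect("F", frame.family_codes))
        elif lab == "S":
            effects.append(CategoricalEffect("S", frame.subject_codes))
        elif lab in kernel_inputs:
            K = _as_csr(kernel_inputs[lab], frame.n_obs)
            coo = K.tocoo()
            cross = frame.family_codes[coo.row] != frame.family_codes[coo.col]
            if np.any(cross & (coo.data != 0)):
                raise ValueError(
                    f"kernel '{lab}' has nonzero entries between families; "
                    "only family-block-diagonal kernels are supported"
                )
            effects.append(KernelEffect(lab, K))
        else:
            raise ValueError(
                f"unknown random effect '{lab}': use 'F', 'S', or supply a kernel"
            )
    return RandomEffectsDesign(
        effects=effects,
        n_obs=frame.n_obs,
        family_codes=frame.family_codes,
        subject_codes=frame.subject_codes,
    )


def _categorical_pairs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All within-group off-diagonal pairs (i < j) of a grouping factor."""
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    # group boundaries
    starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    ends = np.r_[starts[1:], codes.shape[0]]
    ii, jj = [], []
    for s, e in zip(starts, ends):
        m = e - s
        if m < 2:
            continue
        members = order[s:e]
        a, b = np.triu_indices(m, k=1)
        ii.append(members[a])
        jj.append(members[b])
    if not ii:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(ii), np.concatenate(jj)


def build_pair_index(design: RandomEffectsDesign, zero_tol: float = 0.0) -> PairIndex:
    """Enumerate informative observation pairs and their kernel values.

    Returns the diagonal pairs plus every off-diagonal pair for which at
    least one effect's kernel entry exceeds ``zero_tol`` in absolute value.
    Dropping the remaining pairs is exact: an all-zero row of L contributes
    zero to both L'L and L'R.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    n = design.n_obs
    cand_i, cand_j = [], []
    for eff in design.effects:
        if isinstance(eff, CategoricalEffect):
            pi, pj = _categorical_pairs(eff.codes)
        else:
            coo = sp.triu(eff.K, k=1).tocoo()
            keep = np.abs(coo.data) > zero_tol
            pi, pj = coo.row[keep].astype(np.int64), coo.col[keep].astype(np.int64)
        cand_i.append(pi)
        cand_j.append(pj)
    if cand_i:
        off_i = np.concatenate(cand_i)
        off_j = np.concatenate(cand_j)
        lo = np.minimum(off_i, off_j)
        hi = np.maximum(off_i, off_j)
        keys = np.unique(lo.astype(np.int64) * n + hi)
        off_i, off_j = keys // n, keys % n
    else:
        off_i = off_j = np.empty(0, dtype=np.int64)

    pi = np.concatenate([np.arange(n, dtype=np.int64), off_i])
    pj = np.concatenate([np.arange(n, dtype=np.int64), off_j])
    diag_mask = np.zeros(pi.shape[0], dtype=bool)
    diag_mask[:n] = True

    L = np.empty((pi.shape[0], design.n_effects + 1))
    for e, eff in enumerate(design.effects):
        L[:, e] = eff.kernel_entries(pi, pj)
    L[:, -1] = diag_mask.astype(np.float64)

    # prune off-diagonal rows that fell below tolerance for every effect
    keep = diag_mask | (np.max(np.abs(L[:, :-1]), axis=1) > zero_tol)
    return PairIndex(
        i=pi[keep],
        j=pj[keep],
        L=L[keep],
        diag_mask=diag_mask[keep],
        effect_labels=design.labels,
        diag_means=design.diag_means,
    )
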