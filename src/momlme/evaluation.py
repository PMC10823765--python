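"""Reusable simulation studies: binning/MSE, type-I error, convergence,
and comparison against an independent maximum-likelihood solver.

Each study simulates family-structured data with known ground truth, runs
the moment/binned-GLS engine, and summarizes accuracy (mean squared error
per Monte-Carlo repeat), calibration (false-positive counts at nominal
alpha levels), or agreement with a per-outcome ML mixed-model fit
(statsmodels MixedLM, which shares no code with the engine).  Reports carry
the raw per-repeat records alongside every summary so the summaries are
recomputable.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gls, simulate
from .model_core import build_design, build_pair_index
from .moments import estimate_components_mom, fit_ols, residual_products

__all__ = [
    "StudyReport",
    "compute_mse",
    "count_false_positives",
    "reference_ml_fit",
    "compare_to_reference",
    "run_binning_study",
    "run_type1_study",
    "run_convergence_study",
    "default_bin_ladder",
]


@dataclass
class StudyReport:
    """Summary table plus the raw per-repeat records it was computed from."""

    study_id: str
    summary: pd.DataFrame
    records: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_dir(self, out_dir) -> None:
        from pathlib import Path

        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / f"{self.study_id}_summary.tsv", sep="\t", index=False)
        self.records.to_csv(out / f"{self.study_id}_records.tsv", sep="\t", index=False)
        with open(out / f"{self.study_id}_config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh)


def compute_mse(estimates: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean over repeats of the squared estimation error, per parameter.

    ``estimates`` has shape (repeats, ...) and ``truth`` the trailing shape;
    the result drops the repeat axis.
    """
    estimates = np.asarray(estimates, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if estimates.ndim < 1 or estimates.shape[1:] != truth.shape:
        raise ValueError(
            f"estimates {estimates.shape} do not stack over truth {truth.shape}"
        )
    return np.mean((estimates - truth) ** 2, axis=0)


def total_mse(mse_pj: np.ndarray) -> np.ndarray:
    """Sum the per-(effect, outcome) MSE over outcomes."""
    return mse_pj.sum(axis=-1)


def count_false_positives(p_values: np.ndarray, alphas) -> dict[float, int]:
    """Ceiling of the mean per-repeat total count of p below each alpha.

    ``p_values`` has shape (repeats, ...) where the trailing axes index the
    tests within one repeat; counts are summed within a repeat, averaged
    across repeats, then rounded toward positive infinity.
    """
    p_values = np.asarray(p_values, dtype=np.float64)
    out = {}
    for alpha in np.atleast_1d(alphas):
        a = float(alpha)
        if not 0.0 < a < 1.0:
            raise ValueError(f"invalid alpha {a}")
        per_repeat = (p_values < a).reshape(p_values.shape[0], -1).sum(axis=1)
        out[a] = int(math.ceil(per_repeat.mean()))
    return out


def reference_ml_fit(frame, Y, effects=("F", "S")):
    """Independent per-outcome ML mixed-model fit via statsmodels MixedLM.

    Family enters as the grouping random intercept and subject as a variance
    component nested within it.  Returns ``(beta, varcomp)`` where ``beta``
    is p x J and ``varcomp`` is 3 x J on the original variance scale with
    rows ordered (F, S, E).  Only the F/S/E specification is supported;
    kernel effects have no MixedLM counterpart here.
    """
    import statsmodels.api as sm

    if tuple(effects) != ("F", "S"):
        raise ValueError("the reference solver supports the ('F', 'S') design only")
    from .model_core import OutcomeMatrix

    if isinstance(Y, OutcomeMatrix):
        Y = Y.Y
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = frame.X
    p, J = X.shape[1], Y.shape[1]
    beta = np.empty((p, J))
    varcomp = np.empty((3, J))
    df = pd.DataFrame(X, columns=[f"c{k}" for k in range(p)])
    df["family"] = frame.family_id
    df["subject"] = frame.subject_id
    rhs = " + ".join(f"c{k}" for k in range(p))
    vc = {"subject": "0 + C(subject)"}
    for jcol in range(J):
        df["y"] = Y[:, jcol]
        md = sm.MixedLM.from_formula(
            f"y ~ 0 + {rhs}",
            groups="family",
            re_formula="1",
            vc_formula=vc,
            data=df,
        )
        res = md.fit(reml=False)
        beta[:, jcol] = res.fe_params.values
        varcomp[0, jcol] = float(res.cov_re.values[0, 0])
        varcomp[1, jcol] = float(res.vcomp[0])
        varcomp[2, jcol] = float(res.scale)
    return beta, varcomp


def compare_to_reference(beta_a, beta_b, vc_a=None, vc_b=None):
    """Total squared differences between two fits: fixed, then random effects.

    Sums squared estimate differences over effects and outcomes; variance
    components must be supplied on the original variance scale (reference
    standard deviations squared, engine fractions rescaled by sigma2).
    """
    beta_a = np.asarray(beta_a)
    beta_b = np.asarray(beta_b)
    if beta_a.shape != beta_b.shape:
        raise ValueError("fixed-effect estimate shapes differ")
    fixed = float(np.sum((beta_a - beta_b) ** 2))
    random = None
    if vc_a is not None and vc_b is not None:
        vc_a = np.asarray(vc_a)
        vc_b = np.asarray(vc_b)
        if vc_a.shape != vc_b.shape:
            raise ValueError("variance-component shapes differ")
        random = float(np.sum((vc_a - vc_b) ** 2))
    return fixed, random


def default_bin_ladder(J: int = 2000) -> list[int]:
    """The 20-value bin ladder: 1-5 by 1, 10-50 by 10, 10 log-spaced 100..J."""
    logs = np.unique(np.rint(np.logspace(2, np.log10(J), 10)).astype(int))
    return [1, 2, 3, 4, 5, 10, 20, 30, 40, 50] + logs.tolist()


def _spawn(seed, k: int):
    return None if seed is None else (int(seed) * 100003 + k) % (2**31 - 1)


def _fit_all_bins(frame, Y, design, bin_values):
    """One OLS/MoM pass, then a binned GLS per requested bin value.

    The component estimates do not depend on the bin count, so the moment
    stage is shared across the sweep; only binning and GLS are redone.
    """
    ols = fit_ols(frame.X, Y.Y)
    pidx = build_pair_index(design)
    comps = estimate_components_mom(
        pidx, residual_products(ols, pidx), ols.sigma2_total
    )
    out = {}
    for K in bin_values:
        bins = gls.assign_bins(comps, K)
        out[K] = gls.binned_gls(
            frame.X, Y.Y, design, bins, ols.sigma2_total, ols,
            Y.outcome_names, frame,
        )
    return out, comps


def run_binning_study(
    n_obs: int = 10_000,
    n_outcomes: int = 2000,
    n_fixed: int = 5,
    n_repeats: int = 50,
    bin_values=None,
    beta_range=(-0.02, 0.02),
    seed=None,
) -> StudyReport:
    """MSE of binned-GLS fixed effects as a function of the bin value.

    Ground truth is drawn once; every repeat draws a fresh family structure,
    covariates, and residuals, and fits the engine at each bin value.  The
    summary reports the total MSE (summed over outcomes) per fixed effect
    and its average over fixed effects, per bin value.
    """
    if bin_values is None:
        bin_values = default_bin_ladder(n_outcomes)
    truth = simulate.sample_true_params(
        n_outcomes, n_fixed, beta_range=beta_range, seed=_spawn(seed, 0)
    )
    est = {K: np.empty((n_repeats, n_fixed, n_outcomes)) for K in bin_values}
    rows = []
    for r in range(n_repeats):
        t0 = time.time()
        structure = simulate.simulate_structure(n_obs, seed=_spawn(seed, 1 + 3 * r))
        frame, Y = simulate.simulate_outcomes(
            truth, structure, seed=_spawn(seed, 2 + 3 * r)
        )
        design = build_design(frame, ("F", "S"))
        fits, _ = _fit_all_bins(frame, Y, design, bin_values)
        for K in bin_values:
            est[K][r] = fits[K].beta
            rows.append({"repeat": r, "bin": K, "seconds": time.time() - t0})
    summary_rows = []
    for K in bin_values:
        tm = total_mse(compute_mse(est[K], truth.beta_true))
        row = {"bin": K, "average_total_mse": float(tm.mean())}
        row.update({f"total_mse_fe{i}": float(v) for i, v in enumerate(tm)})
        summary_rows.append(row)
    return StudyReport(
        study_id="binning",
        summary=pd.DataFrame(summary_rows),
        records=pd.DataFrame(rows),
        config={
            "n_obs": n_obs,
            "n_outcomes": n_outcomes,
            "n_fixed": n_fixed,
            "n_repeats": n_repeats,
            "bin_values": list(map(int, bin_values)),
            "beta_range": list(beta_range),
            "seed": seed,
        },
    )


def run_type1_study(
    n_obs: int = 10_000,
    n_outcomes: int = 50,
    n_fixed: int = 100,
    n_repeats: int = 100,
    alphas=(0.05, 0.01, 0.001, 0.0001),
    bin_values=(20,),
    regime: str = "default",
    seed=None,
) -> StudyReport:
    """False-positive counts under zero fixed-effect slopes.

    With all slopes zero, every rejection is a false positive; the study
    counts rejections per repeat (summed over outcomes), averages across
    repeats, and rounds up.  ``regime='narrow'`` draws family and subject
    fractions in a narrow band so that many outcomes share a bin, the
    configuration used to probe whether binning distorts calibration across
    bin values.
    """
    truth = simulate.sample_true_params(
        n_outcomes, n_fixed, beta_range=(0.0, 0.0), regime=regime, seed=_spawn(seed, 0)
    )
    counts = {
        (K, float(a)): np.zeros(n_repeats) for K in bin_values for a in alphas
    }
    frac = {K: np.zeros(n_repeats) for K in bin_values}
    for r in range(n_repeats):
        structure = simulate.simulate_structure(n_obs, seed=_spawn(seed, 1 + 3 * r))
        frame, Y = simulate.simulate_outcomes(
            truth, structure, seed=_spawn(seed, 2 + 3 * r)
        )
        design = build_design(frame, ("F", "S"))
        fits, _ = _fit_all_bins(frame, Y, design, bin_values)
        for K in bin_values:
            pv = fits[K].p_value
            for a in alphas:
                counts[(K, float(a))][r] = np.sum(pv < a)
            frac[K][r] = np.mean(pv < 0.05)
    summary_rows = []
    for K in bin_values:
        for a in alphas:
            c = counts[(K, float(a))]
            summary_rows.append(
                {
                    "bin": K,
                    "alpha": float(a),
                    "avg_fp_ceil": int(math.ceil(c.mean())),
                    "mean_fp": float(c.mean()),
                    "expected_fp": float(a) * n_outcomes * n_fixed,
                }
            )
    records = pd.DataFrame(
        [
            {"bin": K, "alpha": a, "repeat": r, "fp": counts[(K, a)][r]}
            for (K, a) in counts
            for r in range(n_repeats)
        ]
    )
    return StudyReport(
        study_id="type1",
        summary=pd.DataFrame(summary_rows),
        records=records,
        config={
            "n_obs": n_obs,
            "n_outcomes": n_outcomes,
            "n_fixed": n_fixed,
            "n_repeats": n_repeats,
            "alphas": [float(a) for a in alphas],
            "bin_values": list(map(int, bin_values)),
            "regime": regime,
            "seed": seed,
        },
    )


def run_convergence_study(
    sample_sizes=(50, 100, 200, 500, 1000, 2000, 5000, 10_000),
    n_outcomes: int = 500,
    n_fixed: int = 5,
    n_repeats: int = 5,
    beta_range=(-0.2, 0.2),
    n_bins: int = 20,
    reference: bool = True,
    seed=None,
) -> StudyReport:
    """Parameter recovery versus sample size, against the ML reference.

    Per sample size and repeat, both the engine and (optionally) the ML
    reference are fit to the same data; squared errors versus the ground
    truth are summed over outcomes and averaged over repeats, separately for
    fixed effects and variance components (original variance scale).
    """
    rows = []
    for si, n_obs in enumerate(sample_sizes):
        truth = simulate.sample_true_params(
            n_outcomes, n_fixed, beta_range=beta_range, seed=_spawn(seed, 7000 + si)
        )
        vc_true = truth.theta_true * truth.total_variance
        for r in range(n_repeats):
            base = 17_000 + 97 * si + 3 * r
            structure = simulate.simulate_structure(n_obs, seed=_spawn(seed, base))
            frame, Y = simulate.simulate_outcomes(
                truth, structure, seed=_spawn(seed, base + 1)
            )
            fit = gls.fit(frame, Y, n_bins=n_bins)
            vc_fit = fit.components.theta * fit.components.sigma2_total
            row = {
                "n_obs": n_obs,
                "repeat": r,
                "mom_fixed_sse": float(np.sum((fit.fixed.beta - truth.beta_true) ** 2)),
                "mom_vc_sse": float(np.sum((vc_fit - vc_true) ** 2)),
            }
            if reference:
                beta_ml, vc_ml = reference_ml_fit(frame, Y)
                row["ml_fixed_sse"] = float(
                    np.sum((beta_ml - truth.beta_true) ** 2)
                )
                row["ml_vc_sse"] = float(np.sum((vc_ml - vc_true) ** 2))
            rows.append(row)
    records = pd.DataFrame(rows)
    summary = records.drop(columns="repeat").groupby("n_obs", as_index=False).mean()
    return StudyReport(
        study_id="convergence",
        summary=summary,
        records=records,
        config={
            "sample_sizes": list(map(int, sample_sizes)),
            "n_outcomes": n_outcomes,
            "n_fixed": n_fixed,
            "n_repeats": n_repeats,
            "beta_range": list(beta_range),
            "n_bins": n_bins,
            "reference": reference,
            "seed": seed,
        },
    )
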