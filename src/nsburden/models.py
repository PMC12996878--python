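"""Adjusted estimates: two-part cost model and negative binomial admissions.

Healthcare costs are semicontinuous (a point mass at zero plus a skewed
positive part), so the canonical adjusted-cost analysis is a two-part model:

* part 1 — logistic regression for Pr(cost > 0), fit on all patients;
* part 2 — gamma GLM with log link for E[cost | cost > 0], fit on spenders;
* expected cost for a covariate row is the product of the two predictions.

Annual inpatient admissions are overdispersed counts and are modelled with a
negative binomial (NB2) regression; the one-year follow-up window is fixed,
so no exposure offset is needed.

Adjusted group means come from recycled predictions (marginal
standardization): set the exposure to "documented negative symptoms" for
every patient, predict, and average; repeat with the exposure off.  The
difference and ratio of those two averages are the adjusted contrasts, with
percentile-bootstrap intervals over patients.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from ._design import DEFAULT_COVARIATES, DesignError, encode_design


class ModelError(RuntimeError):
    """Fitting failed in a way the caller must know about."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    family: str  # "two_part_gamma" | "negative_binomial"
    exposure: str = "ns"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self):
        if self.exposure in self.covariates:
            raise DesignError("exposure must not be duplicated among covariates")
        if self.family not in ("two_part_gamma", "negative_binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class TwoPartFit:
    spec: ModelSpec
    columns: tuple[str, ...]
    part1_params: Optional[pd.Series]  # log-odds scale; None when degenerate
    part2_params: pd.Series  # log-scale conditional mean
    part1_degenerate: bool
    n_used: int
    n_positive: int
    converged: bool
    exposure_wald_p: Mapping[str, float] = field(default_factory=dict)

    def predict_expected(self, X: pd.DataFrame) -> np.ndarray:
        """E[Y] = Pr(Y > 0) * E[Y | Y > 0] per row."""
        arr = X[list(self.columns)].to_numpy(dtype=float)
        if self.part1_degenerate or self.part1_params is None:
            p = np.ones(len(X))
        else:
            p = 1.0 / (1.0 + np.exp(-arr @ self.part1_params.to_numpy()))
        mu = np.exp(arr @ self.part2_params.to_numpy())
        return p * mu


@dataclass
class NegBinFit:
    spec: ModelSpec
    columns: tuple[str, ...]
    params: pd.Series  # log-rate scale
    alpha: float  # NB2 dispersion, > 0
    n_used: int
    converged: bool
    moment_fallback: bool
    exposure_wald_p: Mapping[str, float] = field(default_factory=dict)

    def predict_expected(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[list(self.columns)].to_numpy(dtype=float)
        return np.exp(arr @ self.params.to_numpy())


@dataclass(frozen=True)
class AdjustedEstimate:
    group_means: Mapping[str, float]  # {"NS": ..., "no_NS": ...}
    difference: float
    ratio: float
    ci_difference: tuple[float, float]
    ci_ratio: tuple[float, float]
    ci_mean_ns: tuple[float, float]
    ci_mean_no_ns: tuple[float, float]
    n_boot: int
    n_boot_failed: int
    seed: int
    wald_p: Mapping[str, float]
    bootstrap_p: float


def _fit_logit(y: np.ndarray, X: pd.DataFrame, start=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        warnings.simplefilter("error", PerfectSeparationWarning)
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, start_params=start)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ModelError("part 1 (logistic): perfect separation in the design") from exc
        except Exception:
            # Newton's singular-Hessian failure mode on nearly separated data;
            # a gradient method usually still converges
            try:
                res = model.fit(disp=0, maxiter=500, method="bfgs", start_params=start)
            except (PerfectSeparationError, PerfectSeparationWarning) as exc:
                raise ModelError("part 1 (logistic): perfect separation in the design") from exc
            except Exception as exc:
                raise ModelError(f"part 1 (logistic) failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ModelError("part 1 (logistic): separation suspected (non-finite coefficients)")
    return res

def _fit_gamma(y: np.ndarray, X: pd.DataFrame, start=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
        try:
            res = model.fit(maxiter=200, start_params=start)
        except Exception as exc:
            raise ModelError(f"part 2 (gamma GLM) failed: {exc}") from exc
    if not res.converged:
        raise ModelError("part 2 (gamma GLM) did not converge")
    return res


def fit_two_part(data: pd.DataFrame, spec: ModelSpec) -> TwoPartFit:
    """Fit the logistic + gamma-log-link two-part cost model.

    Part 1 uses every row (indicator cost > 0); part 2 only the positive-cost
    rows.  With no zero costs part 1 is degenerate (probability pinned at 1)
    and flagged rather than fitted.  Requires at least two positive costs.
    """
    y = data[spec.outcome].astype(float).to_numpy()
    if np.any(y < 0):
        raise ValueError("costs must be non-negative")
    positive = y > 0
    if positive.sum() < 2:
        raise ModelError("need >= 2 positive-cost observations for part 2")
    X = encode_design(data, exposure=spec.exposure, covariates=spec.covariates)

    wald: dict[str, float] = {}
    if positive.all():
        part1_params, degenerate, res1 = None, True, None
    else:
        res1 = _fit_logit(positive.astype(float), X)
        part1_params, degenerate = res1.params, False
        wald["part1"] = float(res1.pvalues[spec.exposure])

    # part 2 must stay full-rank on the positive subsample
    Xpos = encode_design(
        data.loc[positive], exposure=spec.exposure, covariates=spec.covariates
    )
    res2 = _fit_gamma(y[positive], Xpos)
    part2 = res2.params.reindex(X.columns).fillna(0.0)
    wald["part2"] = float(res2.pvalues[spec.exposure])

    return TwoPartFit(
        spec=spec,
        columns=tuple(X.columns),
        part1_params=part1_params,
        part2_params=part2,
        part1_degenerate=degenerate,
        n_used=len(y),
        n_positive=int(positive.sum()),
        converged=True,
        exposure_wald_p=wald,
    )


def fit_negbin(data: pd.DataFrame, spec: ModelSpec) -> NegBinFit:
    """Fit the NB2 negative binomial count model by maximum likelihood.

    Starts from a Poisson GLM with a moment estimate of the dispersion; on
    MLE failure the Poisson coefficients + moment dispersion are returned
    with ``moment_fallback=True``.  All-zero outcomes are degenerate and
    rejected.
    """
    y = data[spec.outcome].to_numpy()
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if not np.any(y > 0):
        raise ModelError("degenerate outcome: all counts are zero")
    y = y.astype(float)
    X = encode_design(data, exposure=spec.exposure, covariates=spec.covariates)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu = poisson.fittedvalues.to_numpy()
        alpha0 = float(max(((y - mu) ** 2 - mu).sum() / (mu**2).sum(), 1e-4))
        start = np.append(poisson.params.to_numpy(), alpha0)
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        converged, fallback = False, False
        try:
            res = model.fit(start_params=start, method="bfgs", maxiter=200, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
            if not converged:
                res = model.fit(start_params=res.params, method="nm", maxiter=2000, disp=0)
                converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
    if res is None or not converged or not np.all(np.isfinite(res.params)):
        params = pd.Series(poisson.params.to_numpy(), index=list(X.columns))
        return NegBinFit(
            spec=spec,
            columns=tuple(X.columns),
            params=params,
            alpha=max(alpha0, 1e-8),
            n_used=len(y),
            converged=False,
            moment_fallback=True,
            exposure_wald_p={"nb": float(poisson.pvalues[spec.exposure])},
        )
    raw = np.asarray(res.params, dtype=float)
    params = pd.Series(raw[: X.shape[1]], index=list(X.columns))
    alpha = float(max(raw[-1], 1e-8))
    return NegBinFit(
        spec=spec,
        columns=tuple(X.columns),
        params=params,
        alpha=alpha,
        n_used=len(y),
        converged=True,
        moment_fallback=False,
        exposure_wald_p={"nb": float(res.pvalues[spec.exposure])},
    )


def _refit(fit: TwoPartFit | NegBinFit, sample: pd.DataFrame):
    return (
        fit_two_part(sample, fit.spec)
        if isinstance(fit, TwoPartFit)
        else fit_negbin(sample, fit.spec)
    )


def _standardized_means(fit: TwoPartFit | NegBinFit, data: pd.DataFrame) -> tuple[float, float]:
    """Recycled predictions: population-average outcome with exposure on/off."""
    spec = fit.spec
    means = []
    for value in (1.0, 0.0):
        counterfactual = data.copy()
        counterfactual[spec.exposure] = value
        X = encode_design(
            counterfactual,
            exposure=spec.exposure,
            covariates=spec.covariates,
            drop_empty=False,
            require_full_rank=False,
        )
        means.append(float(np.mean(fit.predict_expected(X))))
    return means[0], means[1]


def adjusted_estimates(
    fit: TwoPartFit | NegBinFit,
    data: pd.DataFrame,
    n_boot: int = 500,
    seed: Optional[int] = None,
) -> AdjustedEstimate:
    """Adjusted group means, difference, and ratio with bootstrap intervals.

    Nonparametric percentile bootstrap over patients; each replicate refits
    the model (warm convergence via the same fitting path) and recomputes the
    standardized means.  Deterministic for a fixed seed; replicates whose
    refit fails are dropped and counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if seed is None:
        raise ValueError("a seed is required for reproducible intervals")
    mean_ns, mean_no = _standardized_means(fit, data)

    rng = np.random.default_rng(seed)
    n = len(data)
    boot = np.empty((n_boot, 2))
    failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            bfit = _refit(fit, sample)
            boot[b] = _standardized_means(bfit, sample)
        except (ModelError, DesignError, ValueError):
            boot[b] = np.nan
            failed += 1
    ok = boot[~np.isnan(boot).any(axis=1)]
    if len(ok) < 2:
        raise ModelError("bootstrap failed in nearly all replicates")
    diffs = ok[:, 0] - ok[:, 1]
    ratios = ok[:, 0] / ok[:, 1]

    def pct(a: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))

    n_ok = len(diffs)
    p_low = (np.sum(diffs <= 0) + 1) / (n_ok + 1)
    p_high = (np.sum(diffs >= 0) + 1) / (n_ok + 1)
    return AdjustedEstimate(
        group_means={"NS": mean_ns, "no_NS": mean_no},
        difference=mean_ns - mean_no,
        ratio=mean_ns / mean_no,
        ci_difference=pct(diffs),
        ci_ratio=pct(ratios),
        ci_mean_ns=pct(ok[:, 0]),
        ci_mean_no_ns=pct(ok[:, 1]),
        n_boot=n_boot,
        n_boot_failed=failed,
        seed=seed,
        wald_p=dict(fit.exposure_wald_p),
        bootstrap_p=float(min(1.0, 2 * min(p_low, p_high))),
    )


def coefficients_frame(fit: TwoPartFit | NegBinFit) -> pd.DataFrame:
    """Tidy coefficient table for reporting."""
    rows = []
    if isinstance(fit, TwoPartFit):
        if fit.part1_params is not None:
            for name, value in fit.part1_params.items():
                rows.append({"part": "part1_logit", "term": name, "estimate": value})
        for name, value in fit.part2_params.items():
            rows.append({"part": "part2_gamma_log", "term": name, "estimate": value})
    else:
        for name, value in fit.params.items():
            rows.append({"part": "negbin_log", "term": name, "estimate": value})
        rows.append({"part": "negbin_log", "term": "alpha", "estimate": fit.alpha})
    return pd.DataFrame(rows)
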