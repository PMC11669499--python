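"""Discrimination and calibration assessment of survival-probability models.

Discrimination is the Mann-Whitney AUROC (survivors are the positive class
for Ps; deaths with 1-Ps give the identical value), with DeLong variance
for confidence intervals and paired model comparison.  Calibration is
assessed three ways: the Hosmer-Lemeshow chi-square over deciles of
predicted risk, calibration-in-the-large (intercept of a logistic refit
with the model's logit as a fixed offset; ideal 0), and the calibration
slope (coefficient of the model's logit in a logistic refit; ideal 1),
plus the expected:observed event ratio with death as the event (ideal 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "auroc", "auroc_ci", "delong", "DelongResult",
    "hosmer_lemeshow", "hosmer_lemeshow_pvalue", "calibration_measures",
    "EvaluationReport", "ComparisonReport",
    "evaluate_probabilities", "compare_models",
]

_PS_EPS = 1e-12


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        y = (y == "alive").astype(int)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("both outcome classes must be present")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def auroc(ps, outcomes) -> float:
    """Mann-Whitney AUROC with ties counted one half.

    Probability that a random survivor is scored above a random
    non-survivor by ``ps``.
    """
    y = _check_binary(outcomes)
    ps = np.asarray(ps, dtype=float)
    ranks = _midrank(ps)
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


@dataclass
class DelongResult:
    """Paired AUROC comparison by the DeLong method."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    p_value: float


def _delong_components(ps: np.ndarray, y: np.ndarray):
    """Structural components (V10 per survivor, V01 per death) and the AUC."""
    pos = ps[y == 1]
    neg = ps[y == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong(ps_a, ps_b, outcomes, *, alpha: float = 0.05) -> DelongResult:
    """DeLong variance/covariance of two paired AUROCs and the two-sided p.

    Both probability vectors must score the same records in the same order.
    Identical vectors give a difference of exactly zero and p = 1.
    """
    y = _check_binary(outcomes)
    ps_a = np.asarray(ps_a, dtype=float)
    ps_b = np.asarray(ps_b, dtype=float)
    if ps_a.shape != ps_b.shape or ps_a.shape != y.shape:
        raise InvalidInputError("ps_a, ps_b and outcomes must score the same records")
    auc_a, v10_a, v01_a = _delong_components(ps_a, y)
    auc_b, v10_b, v01_b = _delong_components(ps_b, y)
    m, n = len(v10_a), len(v01_a)

    def _cov(u, v):
        return np.cov(u, v, ddof=1)[0, 1] if len(u) > 1 else 0.0

    var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
    var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
    cov_ab = _cov(v10_a, v10_b) / m + _cov(v01_a, v01_b) / n

    zq = norm.ppf(1 - alpha / 2)
    ci_a = (auc_a - zq * np.sqrt(var_a), auc_a + zq * np.sqrt(var_a))
    ci_b = (auc_b - zq * np.sqrt(var_b), auc_b + zq * np.sqrt(var_b))

    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2 * cov_ab
    if diff == 0.0 or var_diff <= 0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = 2 * norm.sf(abs(diff) / np.sqrt(var_diff))
    return DelongResult(float(auc_a), float(auc_b), float(var_a), float(var_b),
                        float(cov_ab), ci_a, ci_b, float(p))


def auroc_ci(ps, outcomes, *, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUROC with its DeLong normal-approximation confidence interval."""
    y = _check_binary(outcomes)
    ps = np.asarray(ps, dtype=float)
    auc, v10, v01 = _delong_components(ps, y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    zq = norm.ppf(1 - alpha / 2)
    return float(auc), (float(auc - zq * np.sqrt(var)), float(auc + zq * np.sqrt(var)))


def hosmer_lemeshow(ps, outcomes, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over quantile groups of predicted risk.

    Records are ranked by ``ps`` and cut into ``groups`` near-equal bins
    with ties kept together (tied boundaries merge bins forward, reducing
    the group count).  Returns ``(stat, df, p)`` with df = g - 2 and p the
    upper-tail chi-square probability.
    """
    y = _check_binary(outcomes)
    ps = np.asarray(ps, dtype=float)
    if len(ps) < groups:
        raise DegenerateDataError(f"need at least {groups} records for {groups} groups")
    bins = pd.qcut(ps, groups, labels=False, duplicates="drop")
    g = int(bins.max()) + 1
    if g < 3:
        raise DegenerateDataError(
            f"only {g} distinct risk group(s) after tie merging; "
            "the chi-square needs at least 3"
        )
    stat = 0.0
    for b in range(g):
        mask = bins == b
        nb = int(mask.sum())
        o1 = float(y[mask].sum())          # observed survivors
        e1 = float(ps[mask].sum())         # expected survivors
        o0, e0 = nb - o1, nb - e1          # deaths
        stat += (o1 - e1) ** 2 / max(e1, _PS_EPS) + (o0 - e0) ** 2 / max(e0, _PS_EPS)
    df = g - 2
    return float(stat), df, hosmer_lemeshow_pvalue(stat, df)


def hosmer_lemeshow_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability for a Hosmer-Lemeshow statistic."""
    if stat < 0 or df < 1:
        raise InvalidInputError("need stat >= 0 and df >= 1")
    return float(chi2.sf(stat, df))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _newton_logistic(X, y, offset, max_iter=100, tol=1e-12):
    """Tiny Newton solver for logistic y ~ X beta + offset (p <= 2)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def calibration_measures(ps, outcomes) -> tuple[float, float, float]:
    """Calibration-in-the-large, calibration slope and the E:O event ratio.

    CITL is the intercept of a logistic refit of the outcomes with
    logit(ps) as a fixed offset; the slope is the coefficient of logit(ps)
    in a free logistic refit.  The E:O ratio uses death as the event:
    expected deaths sum(1 - ps) over observed deaths.  Ps of exactly 0 or 1
    are clipped to machine-safe bounds with a warning.
    """
    y = _check_binary(outcomes).astype(float)
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        import warnings

        warnings.warn("ps outside (0,1) clipped for calibration", stacklevel=2)
        ps = np.clip(ps, _PS_EPS, 1 - _PS_EPS)
    lp = _logit(ps)
    n = len(y)
    citl = float(_newton_logistic(np.ones((n, 1)), y, offset=lp)[0])
    slope = float(_newton_logistic(np.column_stack([np.ones(n), lp]), y,
                                   offset=np.zeros(n))[1])
    observed_deaths = float(np.sum(1.0 - y))
    expected_deaths = float(np.sum(1.0 - ps))
    eo = expected_deaths / observed_deaths
    return citl, slope, float(eo)


@dataclass
class EvaluationReport:
    """Discrimination and calibration of one model on one cohort."""

    auroc: float
    auroc_ci: tuple[float, float]
    hl_stat: float
    hl_df: int
    hl_p: float
    aic: float
    bic: float
    citl: float
    slope: float
    eo_ratio: float
    n: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc, "auroc_ci": list(self.auroc_ci),
            "hl_stat": self.hl_stat, "hl_df": self.hl_df, "hl_p": self.hl_p,
            "aic": self.aic, "bic": self.bic,
            "citl": self.citl, "slope": self.slope, "eo_ratio": self.eo_ratio,
            "n": self.n,
        }


@dataclass
class ComparisonReport:
    """Head-to-head comparison of two survival-probability models."""

    report_a: EvaluationReport
    report_b: EvaluationReport
    delong_p: float
    preferred_by_aic: str
    preferred_by_bic: str

    def to_dict(self) -> dict:
        return {
            "model_a": self.report_a.to_dict(),
            "model_b": self.report_b.to_dict(),
            "delong_p": self.delong_p,
            "preferred_by_aic": self.preferred_by_aic,
            "preferred_by_bic": self.preferred_by_bic,
        }


def evaluate_probabilities(
    ps, outcomes, *, groups: int = 10, k: int = 8, log_likelihood: float | None = None
) -> EvaluationReport:
    """Full evaluation report for one vector of survival probabilities.

    ``k`` is the parameter count charged by AIC/BIC; when ``log_likelihood``
    is not supplied the Bernoulli log-likelihood of the outcomes under
    ``ps`` is used (appropriate when ``ps`` came from a model fitted to
    this cohort).
    """
    y = _check_binary(outcomes)
    ps = np.asarray(ps, dtype=float)
    auc, ci = auroc_ci(ps, y)
    stat, df, p = hosmer_lemeshow(ps, y, groups=groups)
    citl, slope, eo = calibration_measures(ps, y)
    if log_likelihood is None:
        psc = np.clip(ps, _PS_EPS, 1 - _PS_EPS)
        log_likelihood = float(np.sum(y * np.log(psc) + (1 - y) * np.log(1 - psc)))
    n = len(y)
    return EvaluationReport(
        auroc=auc, auroc_ci=ci, hl_stat=stat, hl_df=df, hl_p=p,
        aic=2 * k - 2 * log_likelihood, bic=k * np.log(n) - 2 * log_likelihood,
        citl=citl, slope=slope, eo_ratio=eo, n=n,
    )


def compare_models(
    ps_a, ps_b, outcomes, *, names=("model_a", "model_b"),
    k_a: int = 8, k_b: int = 8, groups: int = 10,
    log_likelihood_a: float | None = None, log_likelihood_b: float | None = None,
) -> ComparisonReport:
    """Evaluate two models on the same cohort and compare their AUROCs."""
    rep_a = evaluate_probabilities(ps_a, outcomes, groups=groups, k=k_a,
                                   log_likelihood=log_likelihood_a)
    rep_b = evaluate_probabilities(ps_b, outcomes, groups=groups, k=k_b,
                                   log_likelihood=log_likelihood_b)
    d = delong(ps_a, ps_b, outcomes)
    return ComparisonReport(
        report_a=rep_a, report_b=rep_b, delong_p=d.p_value,
        preferred_by_aic=names[0] if rep_a.aic <= rep_b.aic else names[1],
        preferred_by_bic=names[0] if rep_a.bic <= rep_b.bic else names[1],
    )
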