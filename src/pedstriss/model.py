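"""Mechanism-stratified TRISS refitting by maximum-likelihood logistic regression.

The pediatric refit keeps the TRISS functional form — survival modelled as
logistic in RTS, ISS and age — but estimates the four coefficients
separately for blunt and penetrating trauma, with age entering as a
continuous covariate in years.  Survival (not death) is the modelled
outcome, matching the Ps = P(survive) convention.

The public surface follows the model/results idiom: build a
:class:`PedsTrissModel` from a cohort table, call :meth:`~PedsTrissModel.fit`,
and read estimates, standard errors, information criteria and diagnostics
off the returned :class:`PedsTrissResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidInputError, SeparationError
from .scores import (
    CoefficientSet,
    compute_iss_table,
    compute_rts,
    linear_predictor,
    survival_probability,
)

__all__ = ["FitResult", "ModelFitPair", "fit_logistic", "derive_peds_triss",
           "PedsTrissModel", "PedsTrissResults"]

_PREDICTOR_NAMES = ("intercept", "rts", "iss", "age")


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit for one mechanism stratum.

    ``params`` is the raw estimate vector in design-column order;
    ``coefficients`` maps it onto the TRISS (b0, b1, b2, b3) slots.
    """

    coefficients: CoefficientSet
    params: np.ndarray
    log_likelihood: float
    n: int
    converged: bool
    covariance: np.ndarray
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class ModelFitPair:
    """Blunt and penetrating stratum fits with pooled information criteria.

    The pooled log-likelihood is the sum over strata (the strata are
    independent), k counts every estimated coefficient, and AIC/BIC follow
    the usual definitions with n the total records across both strata.
    """

    blunt: FitResult
    penetrating: FitResult
    log_likelihood: float
    k: int
    n: int

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2 * self.log_likelihood

    def coefficient_sets(self) -> dict[str, CoefficientSet]:
        return {"blunt": self.blunt.coefficients,
                "penetrating": self.penetrating.coefficients}


def _negloglike(beta, X, y):
    eta = X @ beta
    # log(1+exp(-|eta|)) form is stable for large |eta|
    return -(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    mechanism: str = "blunt",
    label: str = "refit",
    tol: float = 1e-10,
    max_iter: int = 100,
    names: tuple[str, ...] = _PREDICTOR_NAMES,
) -> FitResult:
    """Newton-Raphson MLE for P(survive) = logistic(X beta).

    ``X`` is the (n, p) design including the intercept column; ``y`` is 1
    for survivors.  Convergence is declared when the relative change in the
    log-likelihood falls below ``tol``.  Quasi-complete separation is
    detected as a coefficient diverging past 15 on the standardised scale
    and raised as :class:`SeparationError` naming the worst predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidInputError("X must be (n, p) aligned with y")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise InvalidInputError("y must be binary 0/1")
    if len(classes) < 2:
        raise DegenerateDataError(
            "outcome has a single class (everyone %s); coefficients are not identifiable"
            % ("survived" if classes[0] == 1.0 else "died")
        )

    n, p = X.shape
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # intercept / constant columns
    beta = np.zeros(p)
    # start from the marginal log-odds for faster, monotone convergence
    pbar = y.mean()
    beta[0] = np.log(pbar / (1 - pbar))

    ll = -_negloglike(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; predictors are collinear or separated"
            ) from None
        # step-halving to guarantee likelihood ascent
        new_ll = -_negloglike(beta + step, X, y)
        shrink = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            shrink += 1
            if shrink > 50:
                break
            new_ll = -_negloglike(beta + step, X, y)
        beta = beta + step
        std_beta = beta * scale
        std_beta[0] = 0.0  # intercept is not a separation signal
        if np.any(np.abs(std_beta) > 15.0):
            worst = names[int(np.argmax(np.abs(std_beta)))]
            raise SeparationError(
                f"coefficient for {worst!r} diverged (|standardised| > 15): "
                "data are (quasi-)completely separated"
            )
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    if p == 4 and names == _PREDICTOR_NAMES:
        coeffs = CoefficientSet(mechanism, *beta, se=tuple(se), label=label)
    else:
        # reduced/custom designs are carried with unmapped slots zeroed
        full = dict(zip(names, beta))
        coeffs = CoefficientSet(
            mechanism,
            full.get("intercept", 0.0),
            full.get("rts", 0.0),
            full.get("iss", 0.0),
            full.get("age", 0.0),
            label=label + " (reduced design)",
        )
    return FitResult(coeffs, beta, float(ll), n, converged, cov, it)


def _design(df: pd.DataFrame, include_age: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(len(df)), df["rts"].to_numpy(float), df["iss"].to_numpy(float)]
    names = ["intercept", "rts", "iss"]
    if include_age:
        cols.append(df["age_years"].to_numpy(float))
        names.append("age")
    return np.column_stack(cols), tuple(names)


def _ensure_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "rts" not in df.columns:
        df["rts"] = compute_rts(df["gcs"].to_numpy(), df["sbp"].to_numpy(), df["rr"].to_numpy())
    if "iss" not in df.columns:
        ais_cols = ["ais_head", "ais_face", "ais_chest",
                    "ais_abdomen", "ais_extremity", "ais_external"]
        df["iss"] = compute_iss_table(df[ais_cols].to_numpy())
    return df


class PedsTrissModel:
    """Pediatric TRISS refit: stratified logistic survival model.

    Parameters
    ----------
    cohort : DataFrame
        One row per admission with ``mechanism`` ('blunt'/'penetrating'),
        ``outcome`` ('alive'/'dead'), ``age_years``, and either precomputed
        ``rts``/``iss`` or the raw inputs (``gcs``/``sbp``/``rr`` and
        ``iss`` or six ``ais_*`` columns) from which they are derived.
    include_age : bool
        Include continuous age in the design (the pediatric refit); set
        False for the age-free reduced model used in specification checks.

    Examples
    --------
    >>> res = PedsTrissModel(cohort).fit()
    >>> res.params["blunt"].b1_rts
    >>> print(res.summary())
    """

    def __init__(self, cohort: pd.DataFrame, *, include_age: bool = True):
        required = {"mechanism", "outcome", "age_years"}
        missing = required - set(cohort.columns)
        if missing:
            raise InvalidInputError(f"cohort is missing columns {sorted(missing)}")
        self.cohort = _ensure_scores(cohort)
        self.include_age = include_age
        bad = ~self.cohort["mechanism"].isin(("blunt", "penetrating"))
        if bad.any():
            raise InvalidInputError("mechanism must be 'blunt' or 'penetrating'")

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "PedsTrissModel":
        return cls(cohort, **kwargs)

    def fit(self, *, tol: float = 1e-10, max_iter: int = 100) -> "PedsTrissResults":
        fits = {}
        for mech in ("blunt", "penetrating"):
            sub = self.cohort[self.cohort["mechanism"] == mech]
            if len(sub) == 0:
                raise DegenerateDataError(f"no records in {mech} stratum")
            X, names = _design(sub, self.include_age)
            y = (sub["outcome"].to_numpy() == "alive").astype(float)
            try:
                fits[mech] = fit_logistic(
                    X, y, mechanism=mech, label=f"refit {mech}",
                    tol=tol, max_iter=max_iter, names=names,
                )
            except (DegenerateDataError, SeparationError) as exc:
                raise type(exc)(f"{mech} stratum: {exc}") from exc
        k = (4 if self.include_age else 3) * 2
        pair = ModelFitPair(
            blunt=fits["blunt"],
            penetrating=fits["penetrating"],
            log_likelihood=fits["blunt"].log_likelihood + fits["penetrating"].log_likelihood,
            k=k,
            n=fits["blunt"].n + fits["penetrating"].n,
        )
        return PedsTrissResults(self, pair)


class PedsTrissResults:
    """Fitted pediatric TRISS model: estimates, uncertainty and diagnostics."""

    def __init__(self, model: PedsTrissModel, pair: ModelFitPair):
        self.model = model
        self.fit_pair = pair
        self.params = pair.coefficient_sets()
        self.aic = pair.aic
        self.bic = pair.bic
        self.llf = pair.log_likelihood
        self.nobs = pair.n

    def predict(self, cohort: pd.DataFrame | None = None) -> np.ndarray:
        """Survival probabilities Ps for ``cohort`` (default: training data)."""
        df = self.model.cohort if cohort is None else _ensure_scores(cohort)
        ps = np.empty(len(df))
        for mech, cs in self.params.items():
            mask = (df["mechanism"] == mech).to_numpy()
            ps[mask] = survival_probability(
                linear_predictor(cs, df.loc[mask, "rts"].to_numpy(),
                                 df.loc[mask, "iss"].to_numpy(),
                                 df.loc[mask, "age_years"].to_numpy())
            )
        return ps

    def evaluate(self, cohort: pd.DataFrame | None = None, **kwargs):
        """Discrimination/calibration report on ``cohort`` (default: training)."""
        from .evaluation import evaluate_probabilities

        df = self.model.cohort if cohort is None else _ensure_scores(cohort)
        y = (df["outcome"].to_numpy() == "alive").astype(int)
        return evaluate_probabilities(
            self.predict(df), y, k=self.fit_pair.k,
            log_likelihood=self.llf if cohort is None else None, **kwargs,
        )

    def bootstrap_validate(self, n_boot: int = 500, seed: int = 0, **kwargs):
        """Optimism-corrected internal validation of this model's recipe."""
        from .validation import bootstrap_validate

        return bootstrap_validate(
            self.model.cohort, n_boot=n_boot, seed=seed,
            include_age=self.model.include_age, **kwargs,
        )

    def summary(self) -> str:
        lines = [
            "Pediatric TRISS refit (logistic MLE, survival outcome)",
            f"  n = {self.nobs}, k = {self.fit_pair.k}, "
            f"lnL = {self.llf:.3f}, AIC = {self.aic:.1f}, BIC = {self.bic:.1f}",
            "",
            f"  {'stratum':<12}{'term':<12}{'coef':>10}{'se':>10}",
        ]
        for mech in ("blunt", "penetrating"):
            fr = getattr(self.fit_pair, mech)
            beta = fr.coefficients.beta
            se = fr.coefficients.se or (np.nan,) * 4
            for name, b, s in zip(("b0", "b1 (RTS)", "b2 (ISS)", "b3 (Age)"), beta, se):
                lines.append(f"  {mech:<12}{name:<12}{b:>10.3f}{s:>10.3f}")
            lines.append(
                f"  {mech:<12}{'':<12}  n={fr.n}, lnL={fr.log_likelihood:.3f}, "
                f"converged={fr.converged} ({fr.n_iter} iter)"
            )
        return "\n".join(lines)


def derive_peds_triss(cohort: pd.DataFrame, *, include_age: bool = True) -> ModelFitPair:
    """Functional wrapper: fit both mechanism strata and pool the fit."""
    return PedsTrissModel(cohort, include_age=include_age).fit().fit_pair
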