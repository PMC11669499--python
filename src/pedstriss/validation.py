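"""Optimism-corrected bootstrap internal validation (Harrell procedure).

A model recipe fitted and evaluated on the same cohort looks better than
it will on new data.  The optimism bootstrap quantifies that: for each
resample, refit the whole recipe on the bootstrap sample, evaluate it on
both the bootstrap sample and the original cohort, and call the mean
difference the optimism.  Corrected performance = apparent - optimism.
Reported metrics: C statistic (AUROC), calibration-in-the-large,
calibration slope, and the expected:observed death ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SeparationError, ValidationUnstableError
from .evaluation import auroc, calibration_measures

__all__ = ["ValidationReport", "bootstrap_validate"]

METRICS = ("c_statistic", "citl", "slope", "eo_ratio")


def _metrics(ps: np.ndarray, y: np.ndarray) -> dict[str, float]:
    # refit probabilities can saturate to 1.0 at float precision
    ps = np.clip(ps, 1e-12, 1 - 1e-12)
    citl, slope, eo = calibration_measures(ps, y)
    return {"c_statistic": auroc(ps, y), "citl": citl, "slope": slope, "eo_ratio": eo}


@dataclass
class ValidationReport:
    """Apparent, optimism and corrected performance from the bootstrap."""

    n_boot: int
    seed: int
    n_failed: int
    apparent: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    distributions: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot, "seed": self.seed, "n_failed": self.n_failed,
            "apparent": self.apparent, "optimism": self.optimism,
            "corrected": self.corrected,
        }

    def summary(self) -> str:
        lines = [
            f"Bootstrap internal validation ({self.n_boot} resamples, "
            f"{self.n_failed} failed, seed {self.seed})",
            f"  {'metric':<14}{'apparent':>10}{'optimism':>10}{'corrected':>11}",
        ]
        for m in METRICS:
            lines.append(
                f"  {m:<14}{self.apparent[m]:>10.4f}{self.optimism[m]:>10.4f}"
                f"{self.corrected[m]:>11.4f}"
            )
        return "\n".join(lines)


def _resample_indices(rng, mechanism: np.ndarray, stratified: bool) -> np.ndarray:
    n = len(mechanism)
    if not stratified:
        return rng.integers(0, n, size=n)
    parts = []
    for mech in ("blunt", "penetrating"):
        pool = np.flatnonzero(mechanism == mech)
        if len(pool):
            parts.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(parts)


def bootstrap_validate(
    cohort: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    *,
    include_age: bool = True,
    stratified: bool = True,
    max_failure_frac: float = 0.2,
    indices: list[np.ndarray] | None = None,
) -> ValidationReport:
    """Optimism-corrected validation of the stratified TRISS refit recipe.

    Resampling is at the patient level and, by default, stratified by
    mechanism so every resample can fit both strata.  Resamples whose
    refit fails (separation or a single-class stratum) are skipped and
    counted; more than ``max_failure_frac`` failures raises
    :class:`ValidationUnstableError`.  ``indices`` substitutes explicit
    resample index arrays for the random ones (diagnostics/testing).

    Fully reproducible for fixed ``(cohort, n_boot, seed)``.
    """
    from .model import PedsTrissModel

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cohort = cohort.reset_index(drop=True)
    y = (cohort["outcome"].to_numpy() == "alive").astype(int)
    mechanism = cohort["mechanism"].to_numpy()

    apparent_res = PedsTrissModel(cohort, include_age=include_age).fit()
    apparent = _metrics(apparent_res.predict(), y)

    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {m: [] for m in METRICS}
    n_failed = 0
    for i in range(n_boot):
        idx = indices[i] if indices is not None else _resample_indices(
            rng, mechanism, stratified
        )
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            res = PedsTrissModel(boot, include_age=include_age).fit()
            m_boot = _metrics(res.predict(), y[idx])
            m_orig = _metrics(res.predict(cohort), y)
        except (DegenerateDataError, SeparationError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for m in METRICS:
            draws[m].append(m_boot[m] - m_orig[m])

    if n_failed > max_failure_frac * n_boot:
        raise ValidationUnstableError(
            f"{n_failed}/{n_boot} bootstrap refits failed; the cohort is too "
            "small or too separated for stable internal validation"
        )
    optimism = {m: float(np.mean(draws[m])) for m in METRICS}
    corrected = {m: apparent[m] - optimism[m] for m in METRICS}
    return ValidationReport(
        n_boot=n_boot, seed=seed, n_failed=n_failed,
        apparent=apparent, optimism=optimism, corrected=corrected,
        distributions={m: np.asarray(draws[m]) for m in METRICS},
    )
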