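"""Synthetic pediatric trauma cohort generator.

Emulates the marginal structure of a single-center pediatric trauma
registry: a right-skewed age mix dominated by adolescents, ~73% male,
~66% blunt mechanism, a right-skewed ISS distribution (median 9,
roughly a third with ISS >= 16) and physiology (GCS, SBP, RR) that
degrades with injury severity.  Survival outcomes are drawn from a
TRISS-family logistic model so that every downstream stage — refitting,
calibration assessment, bootstrap validation, benchmarking — can be
exercised end-to-end without access to patient data.

The joint distribution is induced by a single latent severity variable
per patient: it drives ISS through a discretised log-normal and, through
a correlated physiology latent, pushes GCS/SBP/RR away from their
healthy baselines.  This is the simplest structure that reproduces the
survivor/non-survivor contrasts of a real registry (deaths concentrate
at high ISS and deranged physiology); it does not attempt to model
region-specific injury patterns or physiology measurement artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .scores import CoefficientSet, builtin_coefficients, compute_rts, linear_predictor, survival_probability

__all__ = ["SynthConfig", "default_config", "generate_cohort", "inject_missingness"]

#: Age bands (years, half-open) and their default probabilities.
AGE_BAND_EDGES = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 18.0))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort data-generating process.

    The defaults reproduce the target registry marginals; the
    ``mortality_logit_offset`` is an additive shift on the outcome-model
    linear predictor that calibrates overall mortality (0 means outcomes
    come exactly from the named coefficient set).
    """

    n: int = 1013
    seed: int = 0
    age_band_probs: tuple[float, float, float, float] = (0.212, 0.218, 0.239, 0.331)
    male_frac: float = 0.73
    blunt_frac: float = 0.662
    # ISS ~ round(LogNormal(log 9, 1.0)) clipped to [1, 75]:
    # median 9, quartiles ~ (5, 18), P(ISS >= 16) ~ 0.30.
    iss_log_median: float = float(np.log(9.0))
    iss_log_sigma: float = 1.0
    # Correlation between the ISS latent and the physiology latent.
    physiology_rho: float = 0.7
    # Physiology departs from healthy baselines once the latent exceeds
    # this threshold; slopes set how fast each vital degrades.
    severity_threshold: float = 0.45
    gcs_slope: float = 6.0
    sbp_slope: float = 30.0
    rr_slope: float = 8.0
    outcome_model: Mapping[str, CoefficientSet] = field(
        default_factory=lambda: builtin_coefficients("peds_triss")
    )
    # Default calibrates overall mortality to ~5.7%; set to 0 to draw
    # outcomes exactly from the named coefficient set.
    mortality_logit_offset: float = -0.9
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 0:
            raise InvalidInputError("n must be non-negative")
        probs = np.asarray(self.age_band_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise InvalidInputError("age_band_probs must be four non-negative values summing to 1")
        for name in ("male_frac", "blunt_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if not 0.0 <= abs(self.physiology_rho) <= 1.0:
            raise InvalidInputError("physiology_rho must be in [-1, 1]")
        for f, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise InvalidInputError(f"missing rate for {f!r} must be in [0, 1]")


def default_config(**overrides) -> SynthConfig:
    """The default cohort configuration; keyword overrides replace fields."""
    return replace(SynthConfig(), **overrides) if overrides else SynthConfig()


def generate_cohort(config: SynthConfig | None = None, **overrides) -> pd.DataFrame:
    """Draw a synthetic cohort as a DataFrame, a pure function of the config.

    Columns: ``record_id, age_years, sex, mechanism, gcs, sbp, rr, iss,
    outcome`` plus the generated ``ps_true`` (the survival probability each
    outcome was drawn from, kept for diagnostics).
    """
    config = default_config(**overrides) if config is None else (
        replace(config, **overrides) if overrides else config
    )
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)

    band = rng.choice(4, size=n, p=np.asarray(config.age_band_probs, dtype=float))
    lows = np.array([e[0] for e in AGE_BAND_EDGES])
    widths = np.array([e[1] - e[0] for e in AGE_BAND_EDGES])
    age = lows[band] + widths[band] * rng.uniform(size=n)

    sex = np.where(rng.uniform(size=n) < config.male_frac, "male", "female")
    mechanism = np.where(rng.uniform(size=n) < config.blunt_frac, "blunt", "penetrating")

    u = rng.standard_normal(n)  # severity latent
    iss = np.clip(
        np.rint(np.exp(config.iss_log_median + config.iss_log_sigma * u)), 1, 75
    ).astype(int)

    rho = config.physiology_rho
    v = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    excess = np.maximum(0.0, v - config.severity_threshold)

    gcs = np.clip(np.rint(15.0 - config.gcs_slope * excess), 3, 15).astype(int)
    sbp = np.clip(
        np.rint(90.0 + 2.0 * age + 8.0 * rng.standard_normal(n) - config.sbp_slope * excess),
        0, None,
    ).astype(int)
    rr = np.clip(
        np.rint(28.0 - 0.8 * age + 3.0 * rng.standard_normal(n) - config.rr_slope * excess),
        0, None,
    ).astype(int)

    rts = compute_rts(gcs, sbp, rr)
    b = np.empty(n)
    for mech, cs in config.outcome_model.items():
        mask = mechanism == mech
        b[mask] = linear_predictor(cs, rts[mask], iss[mask], age[mask])
    ps = survival_probability(b + config.mortality_logit_offset)
    survived = rng.uniform(size=n) < ps

    return pd.DataFrame(
        {
            "record_id": [f"S{i:07d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "mechanism": mechanism,
            "gcs": gcs,
            "sbp": sbp,
            "rr": rr,
            "iss": iss,
            "outcome": np.where(survived, "alive", "dead"),
            "ps_true": ps,
        }
    )


def inject_missingness(
    cohort: pd.DataFrame, rates: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Mask fields completely at random at the given per-field rates.

    Returns a copy; masked cells become missing (NA).  Reproducible for a
    fixed (cohort, rates, seed).
    """
    for f, r in rates.items():
        if f not in cohort.columns:
            raise InvalidInputError(f"unknown field {f!r}")
        if not 0.0 <= r <= 1.0:
            raise InvalidInputError(f"missing rate for {f!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for f in sorted(rates):
        mask = rng.uniform(size=len(out)) < rates[f]
        if mask.any():
            col = out[f]
            if col.dtype.kind in "iub":
                out[f] = col.astype("float64")
            out.loc[mask, f] = np.nan if out[f].dtype.kind == "f" else pd.NA
    return out
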