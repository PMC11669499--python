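"""Deterministic trauma severity scoring: RTS, ISS and the TRISS survival model.

The TRISS family estimates a probability of survival (Ps) for a trauma
admission from three inputs — the Revised Trauma Score (RTS, physiology),
the Injury Severity Score (ISS, anatomy) and age — through a logistic model

    Ps = 1 / (1 + exp(-b)),    b = b0 + b1*RTS + b2*ISS + b3*age

with one coefficient set per injury mechanism (blunt or penetrating).

Two built-in coefficient sets are provided: ``peds_triss``, a pediatric
refit in which age enters as a continuous covariate in years, and
``mtos_original``, the adult coefficients derived from the Major Trauma
Outcome Study.  In the original model age is a dichotomy at 55 years, so
for a pediatric population the age term is identically zero; the built-in
encodes that by setting the age coefficient to zero and keeping the
published 55+ coefficient in the label for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError, NoInjuryError

__all__ = [
    "CoefficientSet",
    "RTS_WEIGHTS",
    "code_gcs",
    "code_sbp",
    "code_rr",
    "compute_rts",
    "compute_iss",
    "linear_predictor",
    "survival_probability",
    "builtin_coefficients",
    "age_adjusted_hypotension",
    "score_cohort",
    "RTS_MAX",
    "ISS_MAX",
]


#: Champion RTS component weights for (GCS, SBP, RR) coded categories.
RTS_WEIGHTS = (0.9368, 0.7326, 0.2908)

#: Maximum attainable RTS: all three components coded 4.
RTS_MAX = 4 * sum(RTS_WEIGHTS)  # 7.8408, reported as 7.84

#: Maximum attainable ISS: three regions at AIS 5 (or any AIS 6).
ISS_MAX = 75


def code_gcs(gcs):
    """Champion coded category (0-4) for a Glasgow Coma Scale score 3-15."""
    gcs = np.asarray(gcs)
    if np.any((gcs < 3) | (gcs > 15)):
        raise InvalidInputError("GCS must be in [3, 15]")
    out = np.select([gcs >= 13, gcs >= 9, gcs >= 6, gcs >= 4], [4, 3, 2, 1], default=0)
    return out if out.ndim else int(out)


def code_sbp(sbp):
    """Champion coded category (0-4) for systolic blood pressure in mmHg."""
    sbp = np.asarray(sbp)
    if np.any(sbp < 0) or not np.all(np.isfinite(sbp)):
        raise InvalidInputError("SBP must be non-negative and finite")
    out = np.select([sbp > 89, sbp >= 76, sbp >= 50, sbp >= 1], [4, 3, 2, 1], default=0)
    return out if out.ndim else int(out)


def code_rr(rr):
    """Champion coded category (0-4) for respiratory rate in breaths/min."""
    rr = np.asarray(rr)
    if np.any(rr < 0) or not np.all(np.isfinite(rr)):
        raise InvalidInputError("RR must be non-negative and finite")
    out = np.select(
        [(rr >= 10) & (rr <= 29), rr > 29, rr >= 6, rr >= 1], [4, 3, 2, 1], default=0
    )
    return out if out.ndim else int(out)


def compute_rts(gcs, sbp, rr):
    """Revised Trauma Score: weighted sum of the three coded categories.

    Accepts scalars or arrays.  The result lies in [0, 7.8408]; clinical
    reports round to two decimals (maximum 7.84) but full precision is
    carried here.
    """
    wg, ws, wr = RTS_WEIGHTS
    return wg * code_gcs(gcs) + ws * code_sbp(sbp) + wr * code_rr(rr)


def compute_iss(severities: Sequence[int]) -> int:
    """Injury Severity Score from six AIS region severities.

    ``severities`` holds one AIS severity (0-6, 0 = no injury) per ISS body
    region (head/neck, face, chest, abdomen, extremities, external).  The
    score is the sum of squares of the three most severe regions; an AIS of
    6 in any region (unsurvivable) sets the score to 75 by registry
    convention.

    Raises :class:`NoInjuryError` on an all-zero profile so the caller can
    decide whether that record is scorable.
    """
    sev = np.asarray(severities, dtype=int)
    if sev.shape != (6,):
        raise InvalidInputError("AIS profile must have exactly six regions")
    if np.any((sev < 0) | (sev > 6)):
        raise InvalidInputError("AIS severities must be integers in [0, 6]")
    if np.all(sev == 0):
        raise NoInjuryError("no codable injury: all six AIS regions are zero")
    if np.any(sev == 6):
        return ISS_MAX
    top3 = np.sort(sev)[-3:]
    return int(np.sum(top3**2))


def compute_iss_table(severities) -> np.ndarray:
    """Vectorised ISS for an (n, 6) array of AIS severities.

    All-zero rows yield 0 rather than raising; callers that require a
    codable injury should filter those rows first.
    """
    sev = np.asarray(severities, dtype=int)
    if sev.ndim != 2 or sev.shape[1] != 6:
        raise InvalidInputError("expected an (n, 6) array of AIS severities")
    if np.any((sev < 0) | (sev > 6)):
        raise InvalidInputError("AIS severities must be integers in [0, 6]")
    top3 = np.sort(sev, axis=1)[:, -3:]
    iss = np.sum(top3**2, axis=1)
    iss[np.any(sev == 6, axis=1)] = ISS_MAX
    return iss


@dataclass(frozen=True)
class CoefficientSet:
    """TRISS logistic coefficients for one injury mechanism.

    ``b = b0 + b1_rts*RTS + b2_iss*ISS + b3_age*age``; standard errors are
    optional (present for fitted sets, absent for purely tabulated ones).
    """

    mechanism: str
    b0: float
    b1_rts: float
    b2_iss: float
    b3_age: float
    se: tuple[float, float, float, float] | None = None
    label: str = ""

    def __post_init__(self):
        if self.mechanism not in ("blunt", "penetrating"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for b in (self.b0, self.b1_rts, self.b2_iss, self.b3_age):
            if not np.isfinite(b):
                raise ValueError("coefficients must be finite")
        if self.se is not None and any(s < 0 for s in self.se):
            raise ValueError("standard errors must be non-negative")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.b0, self.b1_rts, self.b2_iss, self.b3_age])

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "b0": self.b0,
            "b1_rts": self.b1_rts,
            "b2_iss": self.b2_iss,
            "b3_age": self.b3_age,
            "se": list(self.se) if self.se is not None else None,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        se = d.get("se")
        return cls(
            mechanism=d["mechanism"],
            b0=float(d["b0"]),
            b1_rts=float(d["b1_rts"]),
            b2_iss=float(d["b2_iss"]),
            b3_age=float(d["b3_age"]),
            se=tuple(float(s) for s in se) if se is not None else None,
            label=d.get("label", ""),
        )


# Pediatric refit with continuous age in years.
_PEDS_TRISS = {
    "blunt": CoefficientSet(
        "blunt", 2.406, 0.744, -0.137, 0.073,
        se=(1.100, 0.161, 0.030, 0.058), label="peds_triss blunt",
    ),
    "penetrating": CoefficientSet(
        "penetrating", 4.293, 0.811, -0.121, -0.190,
        se=(1.833, 0.134, 0.039, 0.096), label="peds_triss penetrating",
    ),
}

# Adult MTOS coefficients (Boyd et al. 1987).  The published age term
# (-1.9052 blunt / -2.6676 penetrating) applies only to ages 55+, so it is
# identically zero for a pediatric cohort and encoded as 0 here.
_MTOS_ORIGINAL = {
    "blunt": CoefficientSet(
        "blunt", -1.2470, 0.9544, -0.0768, 0.0,
        label="mtos_original blunt (age term 0 below 55 y; 55+ coefficient -1.9052)",
    ),
    "penetrating": CoefficientSet(
        "penetrating", -0.6029, 1.1430, -0.1516, 0.0,
        label="mtos_original penetrating (age term 0 below 55 y; 55+ coefficient -2.6676)",
    ),
}

_BUILTINS = {"peds_triss": _PEDS_TRISS, "mtos_original": _MTOS_ORIGINAL}


def builtin_coefficients(name: str) -> dict[str, CoefficientSet]:
    """Return the named built-in coefficient pair ``{mechanism: CoefficientSet}``.

    ``peds_triss`` is the pediatric continuous-age refit; ``mtos_original``
    is the adult MTOS set with the age term zeroed for under-55 patients.
    """
    try:
        return dict(_BUILTINS[name])
    except KeyError:
        raise KeyError(
            f"unknown coefficient set {name!r}; available: {sorted(_BUILTINS)}"
        ) from None


def linear_predictor(coeffs: CoefficientSet, rts, iss, age):
    """TRISS linear predictor b = b0 + b1*RTS + b2*ISS + b3*age."""
    return coeffs.b0 + coeffs.b1_rts * np.asarray(rts) + coeffs.b2_iss * np.asarray(
        iss
    ) + coeffs.b3_age * np.asarray(age)


def survival_probability(b):
    """Logistic transform 1/(1+exp(-b)), strictly inside (0, 1)."""
    return expit(b)


def age_adjusted_hypotension(age, sbp, *, infant_threshold=60.0, child_intercept=70.0,
                             child_slope=2.0, adolescent_threshold=90.0):
    """Age-adjusted systolic hypotension flag (PALS convention by default).

    Thresholds: SBP < 60 mmHg below 1 year, < 70 + 2*age for 1-10 years,
    < 90 mmHg above 10 years.  All cut points are configurable.
    """
    age = np.asarray(age, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    threshold = np.where(
        age < 1.0,
        infant_threshold,
        np.where(age <= 10.0, child_intercept + child_slope * age, adolescent_threshold),
    )
    out = sbp < threshold
    return out if out.ndim else bool(out)


def score_cohort(cohort, coefficients: Mapping[str, CoefficientSet] | str = "peds_triss"):
    """Annotate a cohort table with RTS, ISS, linear predictor and Ps.

    ``cohort`` is a DataFrame with columns ``age_years, mechanism, gcs, sbp,
    rr`` and either ``iss`` or the six ``ais_*`` columns.  Returns a copy
    with ``rts``, ``iss``, ``b`` and ``ps`` columns added.
    """
    import pandas as pd

    if isinstance(coefficients, str):
        coefficients = builtin_coefficients(coefficients)
    df = cohort.copy()
    df["rts"] = compute_rts(df["gcs"].to_numpy(), df["sbp"].to_numpy(), df["rr"].to_numpy())
    if "iss" not in df.columns or df["iss"].isna().all():
        ais_cols = [
            "ais_head", "ais_face", "ais_chest",
            "ais_abdomen", "ais_extremity", "ais_external",
        ]
        df["iss"] = compute_iss_table(df[ais_cols].to_numpy())
    b = np.empty(len(df), dtype=float)
    for mech, cs in coefficients.items():
        mask = (df["mechanism"] == mech).to_numpy()
        b[mask] = linear_predictor(
            cs,
            df.loc[mask, "rts"].to_numpy(),
            df.loc[mask, "iss"].to_numpy(),
            df.loc[mask, "age_years"].to_numpy(),
        )
    unknown = ~df["mechanism"].isin(coefficients).to_numpy()
    if unknown.any():
        bad = sorted(df.loc[unknown, "mechanism"].unique())
        raise InvalidInputError(f"no coefficients for mechanism(s) {bad}")
    df["b"] = b
    df["ps"] = survival_probability(b)
    return df
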