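"""DEF outcome benchmarking: the Flora Z, the M case-mix index and the W score.

These statistics compare observed survival in a cohort against the
survival expected under a reference model (classically the MTOS norms):

* ``Z = (S - sum(Pi)) / sqrt(sum(Pi*Qi))`` with S the observed survivor
  count, Pi each patient's expected survival probability and Qi = 1 - Pi.
  |Z| < 1.96 means survival does not differ significantly from the
  reference at the 5% level.  The normal approximation is only trusted
  when both sum(Pi) and sum(Qi) reach 5 (expected-count rule); below
  that the result carries a validity flag and a warning.
* ``M`` compares case-mix: each cohort's patients are fractioned over six
  survival-probability bands and M is the sum of band-wise minima between
  the two groups.  M >= 0.88 is the conventional threshold for
  comparable case mix (Z is only interpretable when case mix matches).
* ``W = 100 * (S - sum(Pi)) / n``: excess survivors per 100 patients
  relative to expectation (the standard DEF definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "DEFAULT_BAND_EDGES", "z_statistic", "band_fractions",
    "m_statistic", "w_statistic", "BenchmarkResult", "benchmark",
]

#: Interior cut points of the six MTOS survival-probability bands
#: (0-0.25, 0.25-0.50, 0.50-0.75, 0.75-0.90, 0.90-0.95, 0.95-1.00),
#: applied with half-open lower edges and both extremes included.
DEFAULT_BAND_EDGES = (0.25, 0.50, 0.75, 0.90, 0.95)

MIN_EXPECTED = 5.0
Z_CRITICAL = 1.96
M_SIMILAR = 0.88


def _survivors(outcomes) -> np.ndarray:
    out = np.asarray(outcomes)
    if out.dtype.kind in "USO":
        return (out == "alive").astype(int)
    return out.astype(int)


def _check_ps(ps) -> np.ndarray:
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise DegenerateDataError("empty cohort")
    if np.any((ps < 0) | (ps > 1)) or not np.all(np.isfinite(ps)):
        raise InvalidInputError("survival probabilities must lie in [0, 1]")
    return ps


def z_statistic(ps, outcomes) -> tuple[float, bool]:
    """Flora's Z: standardised excess of observed over expected survivors.

    Returns ``(z, valid)`` where ``valid`` is False (with a warning) when
    sum(Pi) < 5 or sum(Qi) < 5.
    """
    ps = _check_ps(ps)
    y = _survivors(outcomes)
    if ps.shape != y.shape:
        raise InvalidInputError("ps and outcomes must be aligned")
    s = float(y.sum())
    sum_pi = float(ps.sum())
    sum_qi = float((1.0 - ps).sum())
    sum_piqi = float((ps * (1.0 - ps)).sum())
    valid = sum_pi >= MIN_EXPECTED and sum_qi >= MIN_EXPECTED
    if not valid:
        warnings.warn(
            f"Z validity rule violated (sum Pi = {sum_pi:.2f}, sum Qi = {sum_qi:.2f}; "
            "both must be at least 5): normal approximation unreliable",
            stacklevel=2,
        )
    z = (s - sum_pi) / np.sqrt(sum_piqi)
    return float(z), valid


def band_fractions(ps, edges=DEFAULT_BAND_EDGES) -> np.ndarray:
    """Fraction of patients in each of the six survival-probability bands.

    Bands are half-open on the lower edge, ``(e_{k-1}, e_k]``, with 0 and 1
    included at the extremes; fractions sum to 1.
    """
    ps = _check_ps(ps)
    edges = tuple(edges)
    if len(edges) != 5 or any(e1 >= e2 for e1, e2 in zip(edges, edges[1:])):
        raise InvalidInputError("band edges must be five increasing interior cut points")
    # searchsorted with side='left' puts ps == edge into the lower band
    idx = np.searchsorted(edges, ps, side="left")
    return np.bincount(idx, minlength=6) / ps.size


def m_statistic(bands_group, bands_reference) -> float:
    """Case-mix comparability: sum of band-wise minimum fractions.

    Symmetric in its arguments; equals 1 iff the two band vectors are
    identical, and at least 0.88 conventionally means comparable case mix.
    """
    a = np.asarray(bands_group, dtype=float)
    b = np.asarray(bands_reference, dtype=float)
    for v in (a, b):
        if v.shape != (6,) or np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise InvalidInputError("band vectors must be six non-negative fractions summing to 1")
    return float(np.minimum(a, b).sum())


def w_statistic(ps, outcomes) -> float:
    """Excess survivors per 100 patients: 100 * (S - sum(Pi)) / n."""
    ps = _check_ps(ps)
    y = _survivors(outcomes)
    if ps.shape != y.shape:
        raise InvalidInputError("ps and outcomes must be aligned")
    return float(100.0 * (y.sum() - ps.sum()) / ps.size)


@dataclass
class BenchmarkResult:
    """Z, M and W against a reference model, with validity flags."""

    z: float
    m: float | None
    w: float
    s_observed: int
    sum_pi: float
    sum_piqi: float
    band_fractions: np.ndarray
    reference_band_fractions: np.ndarray | None
    z_valid: bool
    n: int

    @property
    def z_significant(self) -> bool:
        """True when |Z| exceeds 1.96 (survival differs from the reference)."""
        return abs(self.z) > Z_CRITICAL

    @property
    def comparable_case_mix(self) -> bool | None:
        """True when M >= 0.88; None when no reference band mix was given."""
        return None if self.m is None else self.m >= M_SIMILAR

    def to_dict(self) -> dict:
        return {
            "z": self.z, "m": self.m, "w": self.w,
            "s_observed": self.s_observed, "sum_pi": self.sum_pi,
            "sum_piqi": self.sum_piqi,
            "band_fractions": self.band_fractions.tolist(),
            "reference_band_fractions": (
                None if self.reference_band_fractions is None
                else self.reference_band_fractions.tolist()
            ),
            "z_valid": self.z_valid, "z_significant": self.z_significant,
            "comparable_case_mix": self.comparable_case_mix, "n": self.n,
        }

    def summary(self) -> str:
        lines = [
            f"DEF benchmark on {self.n} patients: "
            f"S = {self.s_observed}, sum Pi = {self.sum_pi:.2f}",
            f"  Z = {self.z:+.3f} "
            f"({'not ' if not self.z_significant else ''}significant at |Z| > 1.96"
            f"{'; validity rule violated' if not self.z_valid else ''})",
            f"  W = {self.w:+.2f} excess survivors per 100 patients",
        ]
        if self.m is not None:
            label = "comparable" if self.comparable_case_mix else "not comparable"
            lines.append(f"  M = {self.m:.3f} (case mix {label} at the 0.88 threshold)")
        return "\n".join(lines)


def benchmark(
    ps, outcomes, *, reference_band_fractions=None, reference_ps=None,
    edges=DEFAULT_BAND_EDGES,
) -> BenchmarkResult:
    """Full DEF benchmark of a cohort against a reference survival model.

    ``ps`` are the reference-model survival probabilities of the cohort's
    own patients (they define both the Z expectation and the cohort's band
    mix).  M needs the reference group's band mix, supplied either
    directly (``reference_band_fractions``) or as a reference-scored
    cohort (``reference_ps``); with neither, M is omitted.
    """
    ps = _check_ps(ps)
    y = _survivors(outcomes)
    z, valid = z_statistic(ps, y)
    w = w_statistic(ps, y)
    fracs = band_fractions(ps, edges)
    ref = None
    if reference_band_fractions is not None:
        ref = np.asarray(reference_band_fractions, dtype=float)
    elif reference_ps is not None:
        ref = band_fractions(reference_ps, edges)
    m = m_statistic(fracs, ref) if ref is not None else None
    return BenchmarkResult(
        z=z, m=m, w=w, s_observed=int(y.sum()), sum_pi=float(ps.sum()),
        sum_piqi=float((ps * (1 - ps)).sum()), band_fractions=fracs,
        reference_band_fractions=ref, z_valid=valid, n=ps.size,
    )
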