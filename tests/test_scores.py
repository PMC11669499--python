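"""Deterministic scoring: RTS, ISS, linear predictor, Ps and coefficient sets."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedstriss.errors import InvalidInputError, NoInjuryError
from pedstriss.scores import (
    RTS_WEIGHTS,
    CoefficientSet,
    age_adjusted_hypotension,
    builtin_coefficients,
    code_gcs,
    code_rr,
    code_sbp,
    compute_iss,
    compute_iss_table,
    compute_rts,
    linear_predictor,
    survival_probability,
)

# one representative raw value per coded category
GCS_BY_CODE = {0: 3, 1: 4, 2: 7, 3: 10, 4: 15}
SBP_BY_CODE = {0: 0, 1: 30, 2: 60, 3: 80, 4: 120}
RR_BY_CODE = {0: 0, 1: 3, 2: 7, 3: 35, 4: 18}


@pytest.mark.parametrize(
    "gcs,sbp,rr,expected",
    [
        (15, 120, 18, 7.8408),  # all codes 4: the printed maximum 7.84
        (3, 0, 0, 0.0),
        (12, 80, 35, 5.8806),   # codes (3,3,3)
    ],
)
def test_rts_examples(gcs, sbp, rr, expected):
    assert compute_rts(gcs, sbp, rr) == pytest.approx(expected, abs=1e-10)


def test_rts_exhaustive_code_enumeration():
    """Every 5x5x5 code combination matches the weighted lookup-table oracle,
    and the maximum 7.8408 is attained only at all codes 4."""
    wg, ws, wr = RTS_WEIGHTS
    values = {}
    for cg, cs, cr in itertools.product(range(5), repeat=3):
        rts = compute_rts(GCS_BY_CODE[cg], SBP_BY_CODE[cs], RR_BY_CODE[cr])
        assert rts == pytest.approx(wg * cg + ws * cs + wr * cr, abs=1e-12)
        values[(cg, cs, cr)] = rts
    top = max(values, key=values.get)
    assert top == (4, 4, 4)
    assert values[top] == pytest.approx(7.8408)
    assert sum(np.isclose(v, 7.8408) for v in values.values()) == 1


@pytest.mark.parametrize(
    "coder,bounds",
    [
        (code_gcs, [(3, 0), (4, 1), (5, 1), (6, 2), (8, 2), (9, 3), (12, 3), (13, 4), (15, 4)]),
        (code_sbp, [(0, 0), (1, 1), (49, 1), (50, 2), (75, 2), (76, 3), (89, 3), (90, 4)]),
        (code_rr, [(0, 0), (1, 1), (5, 1), (6, 2), (9, 2), (10, 4), (29, 4), (30, 3)]),
    ],
)
def test_coded_category_boundaries(coder, bounds):
    for raw, code in bounds:
        assert coder(raw) == code


def test_rts_input_validation():
    with pytest.raises(InvalidInputError):
        compute_rts(16, 120, 18)
    with pytest.raises(InvalidInputError):
        compute_rts(2, 120, 18)
    with pytest.raises(InvalidInputError):
        compute_rts(15, -5, 18)
    with pytest.raises(InvalidInputError):
        compute_rts(15, 120, -1)


@pytest.mark.parametrize(
    "profile,expected",
    [
        ([5, 5, 5, 0, 0, 0], 75),
        ([1, 0, 0, 0, 0, 0], 1),
        ([4, 1, 3, 2, 0, 0], 29),  # 16 + 9 + 4
        ([6, 0, 0, 0, 0, 0], 75),  # unsurvivable forces the maximum
        ([2, 2, 0, 0, 0, 0], 8),   # fewer than three injured regions
    ],
)
def test_iss_examples(profile, expected):
    assert compute_iss(profile) == expected


def test_iss_brute_force_oracle():
    """All profiles over a severity grid match sort-and-square-top-three."""
    for profile in itertools.product(range(6), repeat=6):
        if all(s == 0 for s in profile):
            continue
        oracle = sum(s**2 for s in sorted(profile)[-3:])
        assert compute_iss(profile) == oracle
    # vectorised path agrees with the scalar one
    profiles = np.array(list(itertools.product(range(6), repeat=3)))[1:]
    full = np.hstack([profiles, np.zeros_like(profiles)])
    assert np.array_equal(
        compute_iss_table(full), [compute_iss(p) for p in full]
    )


def test_iss_errors():
    with pytest.raises(NoInjuryError):
        compute_iss([0, 0, 0, 0, 0, 0])
    with pytest.raises(InvalidInputError):
        compute_iss([1, 2, 3])
    with pytest.raises(InvalidInputError):
        compute_iss([7, 0, 0, 0, 0, 0])


def test_linear_predictor_hand_examples():
    peds = builtin_coefficients("peds_triss")
    zero = CoefficientSet("blunt", 0, 0, 0, 0)
    assert linear_predictor(zero, 7.84, 25, 10) == 0.0
    assert linear_predictor(peds["blunt"], 7.84, 9, 12) == pytest.approx(7.88196)
    assert linear_predictor(peds["penetrating"], 4, 31, 15) == pytest.approx(0.936)


def test_survival_probability_examples():
    assert survival_probability(0.0) == 0.5
    assert survival_probability(7.88196) == pytest.approx(0.99962, abs=5e-6)
    assert survival_probability(0.936) == pytest.approx(0.7183, abs=5e-5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(-700, 700))
def test_logistic_symmetry(b):
    assert survival_probability(-b) == pytest.approx(
        1.0 - survival_probability(b), abs=1e-12
    )


def test_builtin_coefficient_values():
    peds = builtin_coefficients("peds_triss")
    assert peds["blunt"].beta == pytest.approx([2.406, 0.744, -0.137, 0.073])
    assert peds["blunt"].se == pytest.approx([1.100, 0.161, 0.030, 0.058])
    assert peds["penetrating"].beta == pytest.approx([4.293, 0.811, -0.121, -0.190])
    mtos = builtin_coefficients("mtos_original")
    # adult age term is zero below 55, hence identically zero for children
    assert mtos["blunt"].b3_age == 0.0
    assert mtos["penetrating"].b3_age == 0.0
    with pytest.raises(KeyError):
        builtin_coefficients("nonsense")


def test_ps_monotone_in_rts_and_iss():
    """b1 > 0 and b2 < 0 for both mechanisms: Ps rises with RTS, falls with ISS."""
    for cs in builtin_coefficients("peds_triss").values():
        rts = np.linspace(0, 7.8408, 50)
        ps_rts = survival_probability(linear_predictor(cs, rts, 20, 10))
        assert np.all(np.diff(ps_rts) > 0)
        iss = np.arange(1, 76)
        ps_iss = survival_probability(linear_predictor(cs, 6.0, iss, 10))
        assert np.all(np.diff(ps_iss) < 0)


@pytest.mark.parametrize(
    "age,sbp,expected",
    [
        (12, 120, False),
        (5, 60, True),    # threshold 70 + 2*5 = 80
        (16, 95, False),  # threshold 90 above 10 years
        (0.5, 55, True),  # infant threshold 60
        (0.5, 65, False),
    ],
)
def test_age_adjusted_hypotension(age, sbp, expected):
    assert age_adjusted_hypotension(age, sbp) is expected


def test_coefficient_set_json_round_trip():
    cs = builtin_coefficients("peds_triss")["penetrating"]
    restored = CoefficientSet.from_dict(json.loads(json.dumps(cs.to_dict())))
    assert restored == cs


def test_coefficient_set_validation():
    with pytest.raises(ValueError):
        CoefficientSet("sideways", 0, 0, 0, 0)
    with pytest.raises(ValueError):
        CoefficientSet("blunt", np.inf, 0, 0, 0)
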