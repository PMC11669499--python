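"""Discrimination and calibration: AUROC/DeLong, Hosmer-Lemeshow, recalibration."""

import numpy as np
import pytest

from pedstriss.errors import DegenerateDataError, InvalidInputError
from pedstriss.evaluation import (
    auroc,
    auroc_ci,
    calibration_measures,
    compare_models,
    delong,
    evaluate_probabilities,
    hosmer_lemeshow,
    hosmer_lemeshow_pvalue,
)


@pytest.mark.parametrize(
    "ps,y,expected",
    [
        ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
        ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),      # perfect separation
        ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),      # all ties count half
    ],
)
def test_auroc_hand_examples(ps, y, expected):
    assert auroc(ps, y) == pytest.approx(expected)


def test_auroc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    ps = rng.uniform(size=500).round(2)  # rounding creates ties
    y = (rng.uniform(size=500) < ps).astype(int)
    assert auroc(ps, y) == pytest.approx(roc_auc_score(y, ps), abs=1e-12)


def test_auroc_invariant_under_monotone_transform(rng):
    ps = rng.uniform(0.01, 0.99, size=300)
    y = (rng.uniform(size=300) < ps).astype(int)
    base = auroc(ps, y)
    for f in (lambda p: p**3, np.log, lambda p: 1 / (1 + np.exp(-5 * p))):
        assert auroc(f(ps), y) == pytest.approx(base, abs=1e-12)


def test_auroc_single_class_errors():
    with pytest.raises(DegenerateDataError):
        auroc([0.2, 0.8], [1, 1])


def _delong_brute_force(ps_a, ps_b, y):
    """Independent oracle: structural components from the pairwise kernel."""
    def components(ps):
        pos, neg = ps[y == 1], ps[y == 0]
        psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)

    auc_a, v10_a, v01_a = components(np.asarray(ps_a, float))
    auc_b, v10_b, v01_b = components(np.asarray(ps_b, float))
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    from scipy.stats import norm

    p = 2 * norm.sf(abs(auc_a - auc_b) / np.sqrt(var_a + var_b - 2 * cov))
    return auc_a, auc_b, var_a, var_b, cov, p


def test_delong_matches_brute_force_oracle(rng):
    """Midrank implementation equals the O(mn) definition on a 20-record fixture."""
    y = np.array([1] * 12 + [0] * 8)
    ps_a = rng.uniform(0.05, 0.99, size=20).round(2)
    ps_b = np.clip(ps_a + rng.normal(0, 0.15, size=20), 0.01, 0.99)
    d = delong(ps_a, ps_b, y)
    auc_a, auc_b, var_a, var_b, cov, p = _delong_brute_force(ps_a, ps_b, y)
    assert d.auc_a == pytest.approx(auc_a, abs=1e-10)
    assert d.auc_b == pytest.approx(auc_b, abs=1e-10)
    assert d.var_a == pytest.approx(var_a, abs=1e-10)
    assert d.var_b == pytest.approx(var_b, abs=1e-10)
    assert d.cov_ab == pytest.approx(cov, abs=1e-10)
    assert d.p_value == pytest.approx(p, abs=1e-10)


def test_delong_identical_models_p_is_one(rng):
    ps = rng.uniform(size=100)
    y = (rng.uniform(size=100) < 0.5).astype(int)
    d = delong(ps, ps, y)
    assert d.p_value == 1.0
    assert d.auc_a == d.auc_b


def test_delong_ci_width_shrinks_with_n(rng):
    ps = rng.uniform(0.3, 0.99, size=250)
    y = (rng.uniform(size=250) < ps).astype(int)
    _, ci_small = auroc_ci(ps, y)
    big_ps, big_y = np.tile(ps, 4), np.tile(y, 4)
    _, ci_big = auroc_ci(big_ps, big_y)
    ratio = (ci_big[1] - ci_big[0]) / (ci_small[1] - ci_small[0])
    assert ratio == pytest.approx(0.5, abs=0.02)  # ~1/sqrt(4)


def test_delong_alignment_error(rng):
    with pytest.raises(InvalidInputError):
        delong([0.5, 0.6], [0.5, 0.6, 0.7], [1, 0, 1])


def test_hl_pvalues_match_printed_convention():
    """Upper-tail chi-square at df 8 (deciles) reproduces the printed p-values."""
    assert round(hosmer_lemeshow_pvalue(9.7, 8), 1) == 0.3
    assert round(hosmer_lemeshow_pvalue(16.6, 8), 2) == 0.03


def test_hl_perfectly_calibrated_bins():
    """Observed survivors equal expected in every bin: stat 0, p 1."""
    levels = np.arange(1, 11) / 20.0  # 0.05 ... 0.50
    ps, y = [], []
    for v in levels:
        k = int(round(v * 20))
        ps += [v] * 20
        y += [1] * k + [0] * (20 - k)
    stat, df, p = hosmer_lemeshow(np.array(ps), np.array(y), groups=10)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert df == 8
    assert p == pytest.approx(1.0)


def test_hl_ties_merge_bins(rng):
    """Heavily tied ps collapse to fewer groups; df adjusts to g - 2."""
    ps = np.repeat([0.1, 0.3, 0.6, 0.9], 75)
    y = (rng.uniform(size=300) < ps).astype(int)
    stat, df, p = hosmer_lemeshow(ps, y, groups=10)
    assert df == 2  # four tied levels leave 4 quantile groups, not 10
    assert 0 <= p <= 1
    with pytest.raises(DegenerateDataError, match="distinct risk group"):
        hosmer_lemeshow(np.repeat([0.2, 0.9], 50), (rng.uniform(size=100) < 0.5).astype(int))


def test_hl_too_few_records():
    with pytest.raises(DegenerateDataError):
        hosmer_lemeshow([0.5, 0.6, 0.7], [1, 0, 1], groups=10)


def test_hl_pvalues_uniform_under_null():
    """HL p-values are ~Uniform(0,1) on probabilities refit to outcomes drawn
    from the true model; df = g - 2 charges the estimated parameters, so the
    null replicate must refit rather than reuse the generating ps."""
    from scipy.stats import kstest

    from pedstriss.model import fit_logistic

    rng = np.random.default_rng(777)
    pvals = []
    for _ in range(500):
        x = rng.standard_normal(2000)
        y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-(0.3 + x)))).astype(float)
        X = np.column_stack([np.ones(2000), x])
        fr = fit_logistic(X, y, names=("intercept", "x"))
        ps = 1 / (1 + np.exp(-(X @ fr.params)))
        pvals.append(hosmer_lemeshow(ps, y)[2])
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_calibration_ideals_under_correct_model():
    rng = np.random.default_rng(101)
    ps = rng.uniform(0.2, 0.95, size=100_000)
    y = (rng.uniform(size=ps.size) < ps).astype(int)
    citl, slope, eo = calibration_measures(ps, y)
    assert citl == pytest.approx(0.0, abs=0.05)
    assert slope == pytest.approx(1.0, abs=0.05)
    assert eo == pytest.approx(1.0, abs=0.05)


def test_calibration_detects_constructed_miscalibration():
    rng = np.random.default_rng(102)
    ps = rng.uniform(0.2, 0.95, size=50_000)
    y = (rng.uniform(size=ps.size) < ps).astype(int)
    logit = np.log(ps / (1 - ps))
    shrunk = 1 / (1 + np.exp(-logit / 2))   # half-strength predictions
    assert calibration_measures(shrunk, y)[1] == pytest.approx(2.0, abs=0.1)
    shifted = 1 / (1 + np.exp(-(logit + 1)))  # +1 logit everywhere
    assert calibration_measures(shifted, y)[0] == pytest.approx(-1.0, abs=0.1)


def test_calibration_matches_statsmodels(null_cohort):
    import statsmodels.api as sm

    from pedstriss.scores import score_cohort

    scored = score_cohort(null_cohort)
    ps = scored["ps"].to_numpy()
    y = (scored["outcome"] == "alive").astype(int).to_numpy()
    citl, slope, _ = calibration_measures(ps, y)
    lp = np.log(ps / (1 - ps))
    ref_citl = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                      offset=lp).fit().params[0]
    ref_slope = sm.Logit(y, np.column_stack([np.ones(len(y)), lp])).fit(disp=0).params[1]
    assert citl == pytest.approx(ref_citl, abs=1e-6)
    assert slope == pytest.approx(ref_slope, abs=1e-6)


def test_clipping_warns():
    with pytest.warns(UserWarning):
        calibration_measures([0.0, 0.5, 1.0, 0.4], [0, 1, 1, 0])


def test_evaluation_and_comparison_reports(null_cohort):
    from pedstriss.scores import score_cohort

    y = (null_cohort["outcome"] == "alive").astype(int).to_numpy()
    ps_a = score_cohort(null_cohort, "peds_triss")["ps"].to_numpy()
    ps_b = score_cohort(null_cohort, "mtos_original")["ps"].to_numpy()
    rep = evaluate_probabilities(ps_a, y)
    assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]
    assert rep.hl_p == pytest.approx(hosmer_lemeshow_pvalue(rep.hl_stat, rep.hl_df))
    cmp_rep = compare_models(ps_a, ps_b, y, names=("peds", "mtos"), k_b=6)
    assert 0 <= cmp_rep.delong_p <= 1
    # the generating model should win the information criteria
    assert cmp_rep.preferred_by_aic == "peds"
    assert cmp_rep.preferred_by_bic == "peds"
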