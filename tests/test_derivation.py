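"""Tests for the three-step derivation pipeline against closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest

import strokesofa as ss
from strokesofa.derivation import (
    CutpointResult,
    PredictorSpec,
    apply_normal_range_override,
    default_derivation_config,
    derive_score,
    dichotomize,
    enumerate_and_rank_models,
    fit_logistic,
    nagelkerke_r2,
    round_cutoff,
    univariable_screen,
    youden_cutpoint,
)


def _two_by_two(a, b, c, d):
    """Exposure/outcome vectors for a 2x2 table (exposed cases a, exposed
    controls b, unexposed cases c, unexposed controls d)."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return x, y


def test_logistic_or_matches_closed_form_2x2():
    x, y = _two_by_two(10, 10, 5, 20)
    fit = fit_logistic(x, y, names=["exposed"])
    assert math.exp(fit.coefficients["exposed"]) == pytest.approx(4.0, rel=1e-6)
    # Wald CI by direct arithmetic: exp(ln 4 +- 1.96 sqrt(1/10+1/10+1/5+1/20))
    se = math.sqrt(1 / 10 + 1 / 10 + 1 / 5 + 1 / 20)
    assert fit.standard_errors["exposed"] == pytest.approx(se, rel=1e-4)


def test_logistic_null_association_or_one():
    x, y = _two_by_two(10, 30, 10, 30)  # identical outcome rates in both arms
    fit = fit_logistic(x, y, names=["exposed"])
    beta = fit.coefficients["exposed"]
    se = fit.standard_errors["exposed"]
    assert math.exp(beta) == pytest.approx(1.0, abs=1e-6)
    assert beta - 1.96 * se < 0 < beta + 1.96 * se


def test_logistic_separation_flagged_not_silent():
    x = np.r_[np.ones(15), np.zeros(15)]
    fit = fit_logistic(x, x.copy(), names=["x"])
    assert fit.separated


def test_logistic_preconditions():
    with pytest.raises(ValueError, match="below the minimal"):
        fit_logistic([1, 0, 1], [1, 0, 1])
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(np.arange(20), np.ones(20))


# --------------------------------------------------------------------------
# Youden cutpoints
# --------------------------------------------------------------------------


def _brute_force_youden(values, labels, direction):
    """Oracle: evaluate J at every midpoint threshold by explicit counting."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    distinct = np.unique(values)
    best_j, best_t = -np.inf, None
    candidates = (distinct[:-1] + distinct[1:]) / 2
    for t in candidates:
        pos = values >= t if direction == "high_is_bad" else values < t
        sens = pos[labels == 1].mean()
        spec = (~pos)[labels == 0].mean()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j = j
    return best_j


def test_youden_perfect_separation_midpoint():
    values = np.array([1, 2, 3, 10, 11], float)
    labels = np.array([0, 0, 0, 1, 1])
    cut = youden_cutpoint(values, labels, "high_is_bad")
    assert cut.youden_j == pytest.approx(1.0)
    assert cut.raw_cutoff == pytest.approx(6.5)


@pytest.mark.parametrize("direction", ["high_is_bad", "low_is_bad"])
@pytest.mark.parametrize("seed", range(25))
def test_youden_equals_exhaustive_search(direction, seed):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 15, size=40).astype(float)
    labels = (rng.random(40) < 0.4).astype(int)
    if labels.sum() in (0, len(labels)) or len(np.unique(values)) < 2:
        return
    cut = youden_cutpoint(values, labels, direction)
    assert cut.youden_j == pytest.approx(
        _brute_force_youden(values, labels, direction), abs=1e-12
    )


def test_youden_null_labels_give_small_j(rng):
    values = rng.normal(size=4000)
    labels = (rng.random(4000) < 0.5).astype(int)
    cut = youden_cutpoint(values, labels)
    assert cut.youden_j < 0.08  # sampling-noise bound at n = 4000


def test_youden_tie_breaks_toward_inclusive_threshold():
    # alternating labels: J ties at the two outer candidates (J = 0.5 each)
    values = np.array([1.0, 2.0, 3.0, 4.0])
    hi = youden_cutpoint(values, np.array([0, 1, 0, 1]), "high_is_bad")
    lo = youden_cutpoint(values, np.array([1, 0, 1, 0]), "low_is_bad")
    assert hi.youden_j == pytest.approx(0.5)
    assert lo.youden_j == pytest.approx(0.5)
    assert hi.raw_cutoff == pytest.approx(1.5)  # lowest candidate: most inclusive
    assert lo.raw_cutoff == pytest.approx(3.5)  # highest candidate: most inclusive


def test_youden_rejects_constant_or_single_class():
    with pytest.raises(ValueError, match="constant"):
        youden_cutpoint([2.0, 2.0, 2.0], [0, 1, 0])
    with pytest.raises(ValueError, match="both classes"):
        youden_cutpoint([1.0, 2.0], [1, 1])


@pytest.mark.parametrize(
    "raw, is_bp, expected",
    [
        (13.6, False, 14.0),
        (67.3, True, 65.0),
        (87.5, True, 90.0),  # halves away from zero
        (1.15, False, 1.0),
        (-2.5, False, -3.0),
        (149.5, False, 150.0),
    ],
)
def test_round_cutoff(raw, is_bp, expected):
    assert round_cutoff(raw, is_bp) == expected


# --------------------------------------------------------------------------
# normal-range override
# --------------------------------------------------------------------------


def _cut(predictor, rounded, direction="low_is_bad"):
    c = CutpointResult(predictor=predictor, direction=direction,
                       raw_cutoff=rounded, youden_j=0.3)
    c.rounded_cutoff = rounded
    return c


def test_override_applies_inside_normal_range():
    spec = PredictorSpec("platelets", "coagulation", "low_is_bad",
                         normal_range=(150, 400), established_cutoff=150)
    cut = apply_normal_range_override(_cut("platelets", 210.0), spec)
    assert cut.overridden and cut.final_cutoff == 150


def test_override_skipped_without_config_entry():
    spec = PredictorSpec("nihss", "cns", "high_is_bad")
    cut = apply_normal_range_override(_cut("nihss", 14.0, "high_is_bad"), spec)
    assert not cut.overridden and cut.final_cutoff == 14


def test_override_skipped_outside_normal_range():
    spec = PredictorSpec("creatinine", "renal", "high_is_bad",
                         normal_range=(0.5, 1.2), established_cutoff=1.2)
    cut = apply_normal_range_override(_cut("creatinine", 1.4, "high_is_bad"), spec)
    assert not cut.overridden and cut.final_cutoff == 1.4


def test_override_without_established_cutoff_errors():
    spec = PredictorSpec("platelets", "coagulation", "low_is_bad",
                         normal_range=(150, 400))
    with pytest.raises(ValueError, match="established"):
        apply_normal_range_override(_cut("platelets", 210.0), spec)


# --------------------------------------------------------------------------
# Nagelkerke R^2
# --------------------------------------------------------------------------


def test_nagelkerke_bounds_and_formula():
    ll0 = 100 * math.log(0.5)  # balanced null
    assert nagelkerke_r2(ll0, ll0, 100) == 0.0
    assert nagelkerke_r2(ll0, 0.0, 100) == pytest.approx(1.0)
    # independent arithmetic of the Cox-Snell / Nagelkerke formulas
    cs = 1 - math.exp(2 * (-69.31 + 50.0) / 100)
    expected = cs / (1 - math.exp(2 * -69.31 / 100))
    assert nagelkerke_r2(-69.31, -50.0, 100) == pytest.approx(expected)
    assert expected == pytest.approx(0.4272, abs=5e-4)


def test_nagelkerke_rejects_degenerate_null():
    with pytest.raises(ValueError, match="degenerate"):
        nagelkerke_r2(0.0, 0.0, 50)
    with pytest.raises(ValueError, match="ll_model"):
        nagelkerke_r2(-10.0, -20.0, 50)


# --------------------------------------------------------------------------
# univariable screen
# --------------------------------------------------------------------------


def _screen_config(*specs):
    return ss.DerivationConfig(predictors=list(specs))


def test_screen_recovers_generative_or(rng):
    n = 2000
    x = rng.normal(10, 4, size=n)
    true_or = 1.15
    p = 1 / (1 + np.exp(-(math.log(true_or) * (x - 10) - 0.3)))
    y = (rng.random(n) < p).astype(float)
    df = pd.DataFrame({"x": x, "poor_outcome": y})
    results = univariable_screen(df, _screen_config(PredictorSpec("x", "organ")))
    (res,) = results
    assert res.significant and res.carried_forward
    assert res.ci_low < true_or < res.ci_high


def test_screen_null_predictor_not_carried(rng):
    df = pd.DataFrame(
        {"x": rng.normal(size=2000), "poor_outcome": (rng.random(2000) < 0.4) * 1.0}
    )
    (res,) = univariable_screen(df, _screen_config(PredictorSpec("x", "organ")))
    assert not res.carried_forward  # may rarely fail by design alpha; seed fixed


def test_screen_forced_predictor_carried_despite_null(rng):
    df = pd.DataFrame(
        {"map": rng.normal(85, 10, 2000), "poor_outcome": (rng.random(2000) < 0.4) * 1.0}
    )
    (res,) = univariable_screen(
        df, _screen_config(PredictorSpec("map", "cardiovascular", "low_is_bad", forced=True))
    )
    assert res.carried_forward and res.forced and not res.significant


def test_screen_excludes_all_missing_predictor(rng):
    df = pd.DataFrame(
        {
            "x": rng.normal(size=100),
            "empty": [np.nan] * 100,
            "poor_outcome": (rng.random(100) < 0.5) * 1.0,
        }
    )
    results = univariable_screen(
        df, _screen_config(PredictorSpec("x", "a"), PredictorSpec("empty", "b"))
    )
    assert [r.predictor for r in results] == ["x"]


# --------------------------------------------------------------------------
# model enumeration / full pipeline
# --------------------------------------------------------------------------


def test_enumeration_finds_generative_predictors(rng):
    n = 1500
    a = (rng.random(n) < 0.4).astype(float)
    b = (rng.random(n) < 0.3).astype(float)
    noise = (rng.random(n) < 0.35).astype(float)
    p = 1 / (1 + np.exp(-(-1.2 + 1.4 * a + 1.2 * b)))
    y = pd.Series((rng.random(n) < p).astype(float))
    items = pd.DataFrame({"a": a, "b": b, "noise": noise})
    config = _screen_config(
        PredictorSpec("a", "organ1"), PredictorSpec("b", "organ2"),
        PredictorSpec("noise", "organ3"),
    )
    fits, selected = enumerate_and_rank_models(items, y, config)
    assert len(fits) == 7  # subsets of 3 organs, one candidate each, non-empty
    assert set(selected.predictors) == {"a", "b"}  # noise adds < tolerance R^2


def test_enumeration_single_candidate_trivial():
    rng = np.random.default_rng(0)
    a = (rng.random(300) < 0.5).astype(float)
    y = pd.Series((rng.random(300) < (0.25 + 0.4 * a)).astype(float))
    config = _screen_config(PredictorSpec("a", "organ"))
    fits, selected = enumerate_and_rank_models(pd.DataFrame({"a": a}), y, config)
    assert len(fits) == 1 and selected.predictors == ("a",)


def test_preference_rule_breaks_near_ties(rng):
    # two interchangeable single-item models: prefer the flagged one
    n = 2000
    a = (rng.random(n) < 0.4).astype(float)
    b = a.copy()  # identical predictive content -> exact R^2 tie
    p = 1 / (1 + np.exp(-(-1.0 + 1.5 * a)))
    y = pd.Series((rng.random(n) < p).astype(float))
    config = _screen_config(
        PredictorSpec("rr", "respiration"),
        PredictorSpec("spo2", "respiration", preferred=True),
    )
    items = pd.DataFrame({"rr": a, "spo2": b})
    _, selected = enumerate_and_rank_models(items, y, config)
    assert selected.predictors == ("spo2",)


def test_derive_score_null_outcome_with_forced_only(rng):
    n = 400
    df = pd.DataFrame(
        {
            "map": np.round(rng.normal(85, 12, n)),
            "creatinine": np.round(np.exp(rng.normal(0, 0.3, n)), 1),
            "poor_outcome": (rng.random(n) < 0.5) * 1.0,
        }
    )
    config = ss.DerivationConfig(
        predictors=[
            PredictorSpec("map", "cardiovascular", "low_is_bad",
                          is_blood_pressure=True, forced=True, established_cutoff=70),
            PredictorSpec("creatinine", "renal", "high_is_bad", forced=True,
                          normal_range=(0.5, 1.2), established_cutoff=1.2),
        ]
    )
    report = derive_score(df, config)
    assert report.selected.nagelkerke_r2 < 0.05
    assert len(report.definition.items) >= 1


def test_derive_score_minimum_size_gate():
    df = pd.DataFrame({"x": np.arange(20.0), "poor_outcome": [0, 1] * 10})
    with pytest.raises(ValueError, match="below minimum"):
        derive_score(df, ss.DerivationConfig(predictors=[PredictorSpec("x", "o")]))


def test_dichotomize_directions():
    df = pd.DataFrame({"spo2": [88.0, 92.0, np.nan]})
    cut = _cut("spo2", 90.0, "low_is_bad")
    cut.final_cutoff = 90.0
    out = dichotomize(df, cut)
    assert list(out[:2]) == [1.0, 0.0] and np.isnan(out[2])
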