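"""Unit and property tests for the SOFA / S-SOFA scoring engines."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

import strokesofa as ss
from strokesofa.scoring import (
    ObservationSet,
    PHYSIOLOGIC_BOUNDS,
    SEVERITY_DIRECTION,
    S_SOFA,
    SOFA,
    ScoringConfig,
    ValidationError,
    apply_score,
    s_sofa_total,
    sepsis3_positive,
    sofa_total,
    spo2_fio2_ratio,
    worst_of_day,
)


@pytest.mark.parametrize(
    "obs_kwargs, expected_total",
    [
        # healthy values across all six organs score zero
        (dict(gcs=15, pao2=450, fio2=1.0, map=80, platelets=300, bilirubin=0.5,
              creatinine=0.8), 0),
        # worst band in every organ reaches the 24-point ceiling
        (dict(gcs=5, pao2=90, fio2=1.0, norepinephrine=0.2, platelets=15,
              bilirubin=13, creatinine=6), 24),
        # one point each from CNS (GCS 13-14), coagulation (<150), renal (1.2-1.9)
        (dict(gcs=13, platelets=140, creatinine=1.2), 3),
    ],
)
def test_sofa_band_lookup(obs_kwargs, expected_total):
    assert sofa_total(ObservationSet(**obs_kwargs)).total == expected_total


@pytest.mark.parametrize(
    "obs_kwargs, expected_total",
    [
        # all five cutoffs met exactly at their boundaries
        (dict(nihss=14, spo2=89, map=69, platelets=149, creatinine=1.2), 5),
        (dict(nihss=0, spo2=98, map=90, platelets=250, creatinine=0.8), 0),
        # exactly the NIHSS and MAP items positive
        (dict(nihss=20, spo2=95, map=65, platelets=300, creatinine=0.9), 2),
    ],
)
def test_s_sofa_binary_items(obs_kwargs, expected_total):
    assert s_sofa_total(ObservationSet(**obs_kwargs)).total == expected_total


def test_missing_components_score_zero_and_are_reported():
    result = s_sofa_total(ObservationSet(nihss=20))
    assert result.total == 1
    assert set(result.missing_components) == {
        "respiration", "cardiovascular", "coagulation", "renal",
    }


def test_spo2_fio2_substitution_flagged_and_capped():
    # PaO2 absent: the SpO2/FiO2 surrogate maps through the equivalence bands
    res = sofa_total(ObservationSet(spo2=88, fio2=0.40))
    assert res.substitutions_used == ["respiration"]
    assert res.per_organ_points["respiration"] == 2  # 220 < 357
    # saturated oximetry is uninformative: no substitution, organ missing
    res = sofa_total(ObservationSet(spo2=100, fio2=0.40))
    assert "respiration" in res.missing_components
    # PaO2 present wins over the surrogate
    res = sofa_total(ObservationSet(pao2=90, fio2=1.0, spo2=99))
    assert res.per_organ_points["respiration"] == 4
    assert res.substitutions_used == []


@pytest.mark.parametrize(
    "spo2, fio2, expected",
    [(96, 0.21, 457.142857), (90, 1.0, 90.0), (88, 0.40, 220.0)],
)
def test_spo2_fio2_ratio_arithmetic(spo2, fio2, expected):
    assert spo2_fio2_ratio(spo2, fio2) == pytest.approx(expected)


def test_vasopressor_tiers_max_applicable_wins():
    assert sofa_total(ObservationSet(dopamine=3)).per_organ_points["cardiovascular"] == 2
    assert sofa_total(ObservationSet(dobutamine=5)).per_organ_points["cardiovascular"] == 2
    assert sofa_total(ObservationSet(dopamine=10)).per_organ_points["cardiovascular"] == 3
    assert sofa_total(ObservationSet(norepinephrine=0.05)).per_organ_points["cardiovascular"] == 3
    assert sofa_total(ObservationSet(norepinephrine=0.2)).per_organ_points["cardiovascular"] == 4
    # several drugs running: the highest tier applies
    assert sofa_total(
        ObservationSet(dopamine=2, norepinephrine=0.3)
    ).per_organ_points["cardiovascular"] == 4
    # hypotension alone scores 1
    assert sofa_total(ObservationSet(map=69)).per_organ_points["cardiovascular"] == 1


def test_renal_urine_output_escalation():
    assert sofa_total(ObservationSet(creatinine=1.0, urine_output_24h=450)).per_organ_points["renal"] == 3
    assert sofa_total(ObservationSet(creatinine=1.0, urine_output_24h=150)).per_organ_points["renal"] == 4
    assert sofa_total(ObservationSet(creatinine=5.0)).per_organ_points["renal"] == 4


def test_ventilation_requirement_config_flag():
    obs = ObservationSet(pao2=90, fio2=1.0, ventilated=False)
    assert sofa_total(obs).per_organ_points["respiration"] == 4  # Table-style default
    strict = ScoringConfig(require_ventilation_for_high_resp=True)
    assert sofa_total(obs, strict).per_organ_points["respiration"] == 2
    obs_vent = dataclasses.replace(obs, ventilated=True)
    assert sofa_total(obs_vent, strict).per_organ_points["respiration"] == 4


def test_out_of_bounds_value_names_field():
    with pytest.raises(ValidationError, match="gcs"):
        sofa_total(ObservationSet(gcs=17))
    with pytest.raises(ValidationError, match="fio2"):
        sofa_total(ObservationSet(spo2=95, fio2=0.10))


# --------------------------------------------------------------------------
# worst-of-day aggregation
# --------------------------------------------------------------------------


def test_worst_of_day_directional_extremes():
    a = ObservationSet(map=80, creatinine=0.9)
    b = ObservationSet(map=65, creatinine=1.3)
    worst = worst_of_day([a, b])
    assert worst.map == 65 and worst.creatinine == 1.3


def test_worst_of_day_identity_and_missing_carry():
    only = ObservationSet(map=75, platelets=200)
    assert worst_of_day([only]) == only
    partial = worst_of_day([ObservationSet(map=75), ObservationSet(platelets=180)])
    assert partial.map == 75 and partial.platelets == 180


def test_worst_of_day_empty_list_rejected():
    with pytest.raises(ValueError):
        worst_of_day([])


_obs_strategy = st.builds(
    ObservationSet,
    gcs=st.one_of(st.none(), st.integers(3, 15)),
    nihss=st.one_of(st.none(), st.integers(0, 42)),
    map=st.one_of(st.none(), st.integers(40, 140)),
    spo2=st.one_of(st.none(), st.integers(70, 100)),
    platelets=st.one_of(st.none(), st.integers(5, 500)),
    creatinine=st.one_of(st.none(), st.floats(0.2, 9.9)),
    bilirubin=st.one_of(st.none(), st.floats(0.1, 20)),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(_obs_strategy, min_size=1, max_size=4), st.randoms())
def test_worst_of_day_idempotent_and_order_invariant(observations, rnd):
    worst = worst_of_day(observations)
    assert worst_of_day([worst]) == worst
    shuffled = list(observations)
    rnd.shuffle(shuffled)
    assert worst_of_day(shuffled) == worst


@settings(max_examples=80, deadline=None, derandomize=True)
@given(_obs_strategy)
def test_totals_bounded_and_additive(obs):
    for definition in (SOFA, S_SOFA):
        result = apply_score(definition, obs)
        assert 0 <= result.total <= definition.max_total
        assert result.total == sum(result.per_organ_points.values())


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    _obs_strategy,
    st.sampled_from(["gcs", "map", "spo2", "platelets", "creatinine", "bilirubin", "nihss"]),
    st.floats(0.01, 0.5),
)
def test_single_variable_worsening_never_lowers_total(obs, variable, frac):
    """Moving one variable toward severity is monotone for both scores."""
    value = getattr(obs, variable)
    if value is None:
        return
    lo, hi = PHYSIOLOGIC_BOUNDS[variable]
    if SEVERITY_DIRECTION[variable] == "low":
        worse = value - frac * (value - lo)
    else:
        worse = value + frac * (hi - value)
    worse_obs = dataclasses.replace(obs, **{variable: worse})
    for definition in (SOFA, S_SOFA):
        assert (
            apply_score(definition, worse_obs).total
            >= apply_score(definition, obs).total
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_obs_strategy, st.integers(3, 15), st.integers(5, 500))
def test_missing_component_dominated_by_any_completion(obs, gcs, platelets):
    """A score with missing components never exceeds any completion of them."""
    base = dataclasses.replace(obs, gcs=None, platelets=None)
    completed = dataclasses.replace(obs, gcs=gcs, platelets=platelets)
    assert sofa_total(base).total <= sofa_total(completed).total


# --------------------------------------------------------------------------
# the Delta >= 2 positivity rule
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "baseline, window, expected",
    [(2, [3, 5], True), (0, [1], False), (3, [4, 4], False), (0, [2], True)],
)
def test_sepsis3_rule(baseline, window, expected):
    assert sepsis3_positive(baseline, window) is expected


def test_sepsis3_rejects_empty_window():
    with pytest.raises(ValueError):
        sepsis3_positive(1, [])


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    st.integers(0, 24),
    st.lists(st.integers(0, 24), min_size=1, max_size=3),
    st.integers(1, 5),
    st.integers(1, 5),
)
def test_sepsis3_monotone_in_window_antitone_in_baseline(base, window, bump, drop):
    ref = sepsis3_positive(base, window)
    higher_window = [w + bump for w in window]
    assert sepsis3_positive(base, higher_window) >= ref
    assert sepsis3_positive(base + drop, window) <= ref


def test_score_patient_applies_rule_over_window():
    record = ss.PatientRecord(
        patient_id="T1",
        admission=ObservationSet(nihss=10, spo2=96, map=80, platelets=200, creatinine=0.8),
        infection_onset=ObservationSet(nihss=15, spo2=88, map=80, platelets=200, creatinine=0.8),
        day_after_onset=ObservationSet(nihss=15, spo2=92, map=65, platelets=140, creatinine=1.3),
        mrs_3mo=4,
    )
    scored = ss.score_patient(record, S_SOFA)
    assert scored["baseline_total"] == 0
    assert scored["onset_total"] == 2
    assert scored["window_max"] == 4
    assert scored["positive"] is True


def test_patient_record_invariants_enforced():
    obs = ObservationSet()
    with pytest.raises(ValidationError):
        ss.PatientRecord("X", obs, obs, mrs_3mo=6, died_3mo=False)
    with pytest.raises(ValidationError):
        ss.PatientRecord("X", obs, obs, died_in_hospital=True, died_3mo=False)
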