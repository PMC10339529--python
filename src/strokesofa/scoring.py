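"""Organ-dysfunction scoring: SOFA and the Stroke-SOFA (S-SOFA) simplification.

The SOFA score grades six organ systems (CNS, respiration, cardiovascular,
coagulation, liver, renal) from 0 to 4 each, for a total of 0-24.  The S-SOFA
score replaces it with five binary bedside items tailored to stroke patients
(NIHSS >= 14, SpO2 < 90 %, MAP < 70 mmHg, platelets < 150 x10^9/l,
creatinine >= 1.2 mg/dl), for a total of 0-5.  Under the Sepsis-3 convention
an acute rise of >= 2 points over the admission baseline, within the window
from infection onset to the following day, flags sepsis; both scores use the
same rule.

Conventions implemented here:

* a missing component contributes 0 points and is listed in
  ``ScoreResult.missing_components`` (conservative imputation at the score
  level, not a raw value of zero);
* when PaO2 is unavailable, the respiration item falls back to the
  SpO2/FiO2 ratio through a configurable equivalence table;
* printed band edges with gaps (e.g. bilirubin "6.0-11.9" then ">= 12.0")
  are closed on the severe side so every value maps to exactly one band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationSet",
    "ScoringConfig",
    "ScoreItem",
    "BandItem",
    "RespirationItem",
    "CardiovascularItem",
    "RenalItem",
    "ScoreDefinition",
    "ScoreResult",
    "PatientRecord",
    "ValidationError",
    "validate_observation",
    "spo2_fio2_ratio",
    "worst_of_day",
    "sofa_total",
    "s_sofa_total",
    "apply_score",
    "sepsis3_positive",
    "score_patient",
    "SOFA",
    "S_SOFA",
    "SEVERITY_DIRECTION",
    "PHYSIOLOGIC_BOUNDS",
    "TIMEPOINTS",
]


class ValidationError(ValueError):
    """Raised when an observation or cohort value violates physiologic bounds."""


TIMEPOINTS = ("admission", "infection_onset", "day_after_onset", "other")


@dataclass
class ObservationSet:
    """One patient-timepoint's raw physiology; every field independently missable.

    Units: SpO2 percent, PaO2 mmHg, FiO2 fraction (0.21-1.0), pressures mmHg,
    vasopressors ug/kg/min, platelets 10^9/l, bilirubin and creatinine mg/dl,
    urine output ml/day, temperature deg C.
    """

    gcs: float | None = None
    nihss: float | None = None
    spo2: float | None = None
    pao2: float | None = None
    fio2: float | None = None
    map: float | None = None
    systolic_bp: float | None = None
    respiratory_rate: float | None = None
    dopamine: float | None = None
    dobutamine: float | None = None
    epinephrine: float | None = None
    norepinephrine: float | None = None
    platelets: float | None = None
    bilirubin: float | None = None
    creatinine: float | None = None
    urine_output_24h: float | None = None
    temperature: float | None = None
    lactate: float | None = None
    leukocytes: float | None = None
    crp: float | None = None
    procalcitonin: float | None = None
    urea: float | None = None
    ventilated: bool | None = None
    timepoint_label: str = "other"


#: inclusive (low, high) physiologic plausibility bounds for validation
PHYSIOLOGIC_BOUNDS: dict[str, tuple[float, float]] = {
    "gcs": (3, 15),
    "nihss": (0, 42),
    "spo2": (1, 100),
    "pao2": (10, 700),
    "fio2": (0.21, 1.0),
    "map": (10, 250),
    "systolic_bp": (30, 320),
    "respiratory_rate": (0, 80),
    "dopamine": (0, 100),
    "dobutamine": (0, 100),
    "epinephrine": (0, 10),
    "norepinephrine": (0, 10),
    "platelets": (0, 3000),
    "bilirubin": (0, 80),
    "creatinine": (0, 30),
    "urine_output_24h": (0, 20000),
    "temperature": (25, 45),
    "lactate": (0, 40),
    "leukocytes": (0, 300),
    "crp": (0, 700),
    "procalcitonin": (0, 1000),
    "urea": (0, 500),
}

#: severity direction per variable: "low" = lower is worse, "high" = higher is worse
SEVERITY_DIRECTION: dict[str, str] = {
    "gcs": "low",
    "nihss": "high",
    "spo2": "low",
    "pao2": "low",
    "fio2": "high",
    "map": "low",
    "systolic_bp": "low",
    "respiratory_rate": "high",
    "dopamine": "high",
    "dobutamine": "high",
    "epinephrine": "high",
    "norepinephrine": "high",
    "platelets": "low",
    "bilirubin": "high",
    "creatinine": "high",
    "urine_output_24h": "low",
    "temperature": "high",
    "lactate": "high",
    "leukocytes": "high",
    "crp": "high",
    "procalcitonin": "high",
    "urea": "high",
}


def validate_observation(obs: ObservationSet) -> None:
    """Raise :class:`ValidationError` naming the first out-of-bounds field."""
    for name, (lo, hi) in PHYSIOLOGIC_BOUNDS.items():
        value = getattr(obs, name)
        if value is None:
            continue
        if not (lo <= value <= hi):
            raise ValidationError(
                f"{name}={value!r} outside physiologic bounds [{lo}, {hi}]"
            )
    if obs.timepoint_label not in TIMEPOINTS:
        raise ValidationError(
            f"timepoint_label={obs.timepoint_label!r} not one of {TIMEPOINTS}"
        )


@dataclass
class ScoringConfig:
    """Interval and substitution conventions for the SOFA engine.

    ``spo2_fio2_bands`` are the SpO2/FiO2 equivalents of the PaO2/FiO2 cutoffs
    400/300/200/100 (defaults are the published nonlinear equivalents); a value
    strictly below the k-th entry scores at least k points.  SpO2 readings at
    or above ``spo2_uninformative_cap`` make the ratio uninformative (pulse
    oximetry saturates) and disable substitution.
    """

    spo2_fio2_bands: tuple[float, float, float, float] = (512.0, 357.0, 214.0, 89.0)
    spo2_uninformative_cap: float = 100.0
    require_ventilation_for_high_resp: bool = False


DEFAULT_SCORING_CONFIG = ScoringConfig()


def spo2_fio2_ratio(spo2: float, fio2: float) -> float:
    """SpO2/FiO2 ratio used as the PaO2/FiO2 surrogate when PaO2 is missing."""
    if not (0 < spo2 <= 100):
        raise ValidationError(f"spo2={spo2!r} outside (0, 100]")
    if not (0.21 <= fio2 <= 1.0):
        raise ValidationError(f"fio2={fio2!r} outside [0.21, 1.0]")
    return spo2 / fio2


def _bands_points(value: float, thresholds: Sequence[float], direction: str) -> int:
    """Points = number of thresholds crossed in the severe direction.

    ``thresholds`` are ordered from least to most severe; ``direction`` "lt"
    scores when value < threshold, "ge" when value >= threshold.
    """
    points = 0
    for k, thr in enumerate(thresholds, start=1):
        crossed = value < thr if direction == "lt" else value >= thr
        if crossed:
            points = k
    return points


# --------------------------------------------------------------------------
# score items
# --------------------------------------------------------------------------


class ScoreItem:
    """One organ-system item of a score definition."""

    organ_system: str
    variables: tuple[str, ...]
    max_points: int

    def score(
        self, obs: ObservationSet, config: ScoringConfig
    ) -> tuple[int | None, bool]:
        """Return ``(points, substitution_used)``; points None when unassessable."""
        raise NotImplementedError


@dataclass
class BandItem(ScoreItem):
    """Single-variable graded (or binary) item with ordered severity thresholds.

    ``thresholds[k-1]`` crossed (in ``direction``) awards ``points[k-1]``; the
    most severe crossed band wins.  A binary item has one threshold and one
    point value.
    """

    organ_system: str
    variable: str
    direction: str  # "lt" (low is bad) or "ge" (high is bad)
    thresholds: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("lt", "ge"):
            raise ValueError(f"direction must be 'lt' or 'ge', got {self.direction!r}")
        if len(self.thresholds) != len(self.points):
            raise ValueError("thresholds and points must have equal length")
        severity = list(self.thresholds)
        if self.direction == "lt":
            if any(a <= b for a, b in zip(severity, severity[1:])):
                raise ValueError("'lt' thresholds must be strictly decreasing")
        else:
            if any(a >= b for a, b in zip(severity, severity[1:])):
                raise ValueError("'ge' thresholds must be strictly increasing")
        if any(a >= b for a, b in zip(self.points, self.points[1:])):
            raise ValueError("points must be strictly increasing")
        self.variables = (self.variable,)
        self.max_points = max(self.points)

    def score(self, obs, config):
        value = getattr(obs, self.variable)
        if value is None:
            return None, False
        pts = 0
        for thr, p in zip(self.thresholds, self.points):
            crossed = value < thr if self.direction == "lt" else value >= thr
            if crossed:
                pts = p
        return pts, False


@dataclass
class RespirationItem(ScoreItem):
    """SOFA respiration: PaO2/FiO2 bands with SpO2/FiO2 substitution.

    PaO2/FiO2 < 400/300/200/100 scores 1/2/3/4.  When PaO2 is missing but
    SpO2 and FiO2 are available (and SpO2 below the uninformative cap), the
    SpO2/FiO2 ratio is mapped through the configured equivalence bands and the
    substitution is flagged in the result.
    """

    organ_system: str = "respiration"
    pf_bands: tuple[float, float, float, float] = (400.0, 300.0, 200.0, 100.0)

    def __post_init__(self) -> None:
        self.variables = ("pao2", "fio2", "spo2")
        self.max_points = 4

    def score(self, obs, config):
        if obs.pao2 is not None and obs.fio2 is not None:
            points = _bands_points(obs.pao2 / obs.fio2, self.pf_bands, "lt")
            substituted = False
        elif (
            obs.spo2 is not None
            and obs.fio2 is not None
            and obs.spo2 < config.spo2_uninformative_cap
        ):
            ratio = spo2_fio2_ratio(obs.spo2, obs.fio2)
            points = _bands_points(ratio, config.spo2_fio2_bands, "lt")
            substituted = True
        else:
            return None, False
        if (
            config.require_ventilation_for_high_resp
            and points >= 3
            and not obs.ventilated
        ):
            points = 2
        return points, substituted


@dataclass
class CardiovascularItem(ScoreItem):
    """SOFA cardiovascular: hypotension and vasopressor tiers.

    4: dopamine > 15 or epinephrine/norepinephrine > 0.1 ug/kg/min;
    3: 5 < dopamine <= 15 or epinephrine/norepinephrine <= 0.1 (any dose > 0);
    2: dopamine <= 5 (any dose > 0) or dobutamine (any dose);
    1: MAP < 70 mmHg; the maximum applicable tier wins.
    """

    organ_system: str = "cardiovascular"
    map_cutoff: float = 70.0

    def __post_init__(self) -> None:
        self.variables = ("map", "dopamine", "dobutamine", "epinephrine", "norepinephrine")
        self.max_points = 4

    def score(self, obs, config):
        dopa = obs.dopamine or 0.0
        dobu = obs.dobutamine or 0.0
        epi = obs.epinephrine or 0.0
        norepi = obs.norepinephrine or 0.0
        if dopa > 15 or epi > 0.1 or norepi > 0.1:
            return 4, False
        if dopa > 5 or epi > 0 or norepi > 0:
            return 3, False
        if dopa > 0 or dobu > 0:
            return 2, False
        if obs.map is not None:
            return (1 if obs.map < self.map_cutoff else 0), False
        if all(
            getattr(obs, v) is None
            for v in ("map", "dopamine", "dobutamine", "epinephrine", "norepinephrine")
        ):
            return None, False
        return 0, False


@dataclass
class RenalItem(ScoreItem):
    """SOFA renal: creatinine bands with urine-output escalation.

    Creatinine 1.2-1.9 / 2.0-3.4 / 3.5-4.9 / >= 5.0 mg/dl scores 1/2/3/4;
    urine output < 500 ml/d scores at least 3, < 200 ml/d scores 4; the worse
    of the two applies.
    """

    organ_system: str = "renal"
    creatinine_thresholds: tuple[float, ...] = (1.2, 2.0, 3.5, 5.0)

    def __post_init__(self) -> None:
        self.variables = ("creatinine", "urine_output_24h")
        self.max_points = 4

    def score(self, obs, config):
        crea_pts = None
        if obs.creatinine is not None:
            crea_pts = _bands_points(obs.creatinine, self.creatinine_thresholds, "ge")
        urine_pts = None
        if obs.urine_output_24h is not None:
            if obs.urine_output_24h < 200:
                urine_pts = 4
            elif obs.urine_output_24h < 500:
                urine_pts = 3
            else:
                urine_pts = 0
        if crea_pts is None and urine_pts is None:
            return None, False
        return max(p for p in (crea_pts, urine_pts) if p is not None), False


@dataclass
class ScoreDefinition:
    """A parameterized point score: ordered items plus the Delta >= 2 rule."""

    name: str
    items: tuple[ScoreItem, ...]
    positivity_delta: int = 2

    @property
    def max_total(self) -> int:
        return sum(item.max_points for item in self.items)


@dataclass
class ScoreResult:
    """Per-organ points, the total, and bookkeeping on substitutions/missingness."""

    score_name: str
    per_organ_points: dict[str, int]
    total: int
    substitutions_used: list[str] = field(default_factory=list)
    missing_components: list[str] = field(default_factory=list)


def apply_score(
    definition: ScoreDefinition,
    obs: ObservationSet,
    config: ScoringConfig | None = None,
    validate: bool = True,
) -> ScoreResult:
    """Score one observation set against a definition.

    Missing components contribute 0 points and are listed; the respiration
    substitution, when used, is flagged.
    """
    if validate:
        validate_observation(obs)
    config = config or DEFAULT_SCORING_CONFIG
    per_organ: dict[str, int] = {}
    missing: list[str] = []
    substitutions: list[str] = []
    for item in definition.items:
        points, substituted = item.score(obs, config)
        if points is None:
            per_organ[item.organ_system] = 0
            missing.append(item.organ_system)
        else:
            per_organ[item.organ_system] = points
            if substituted:
                substitutions.append(item.organ_system)
    total = sum(per_organ.values())
    return ScoreResult(
        score_name=definition.name,
        per_organ_points=per_organ,
        total=total,
        substitutions_used=substitutions,
        missing_components=missing,
    )


#: the standard six-organ SOFA score (0-24)
SOFA = ScoreDefinition(
    name="sofa",
    items=(
        BandItem("cns", "gcs", "lt", (15, 13, 10, 6), (1, 2, 3, 4)),
        RespirationItem(),
        CardiovascularItem(),
        BandItem("coagulation", "platelets", "lt", (150, 100, 50, 20), (1, 2, 3, 4)),
        BandItem("liver", "bilirubin", "ge", (1.2, 2.0, 6.0, 12.0), (1, 2, 3, 4)),
        RenalItem(),
    ),
)

#: the five-item binary Stroke-SOFA score (0-5)
S_SOFA = ScoreDefinition(
    name="s-sofa",
    items=(
        BandItem("cns", "nihss", "ge", (14,), (1,)),
        BandItem("respiration", "spo2", "lt", (90,), (1,)),
        BandItem("cardiovascular", "map", "lt", (70,), (1,)),
        BandItem("coagulation", "platelets", "lt", (150,), (1,)),
        BandItem("renal", "creatinine", "ge", (1.2,), (1,)),
    ),
)


def sofa_total(obs: ObservationSet, config: ScoringConfig | None = None) -> ScoreResult:
    """Total SOFA score (0-24) for one observation set."""
    return apply_score(SOFA, obs, config)


def s_sofa_total(obs: ObservationSet, config: ScoringConfig | None = None) -> ScoreResult:
    """Total S-SOFA score (0-5) for one observation set."""
    return apply_score(S_SOFA, obs, config)


# --------------------------------------------------------------------------
# daily aggregation and the Sepsis-3 rule
# --------------------------------------------------------------------------

_VALUE_FIELDS = tuple(PHYSIOLOGIC_BOUNDS)


def worst_of_day(observations: Iterable[ObservationSet]) -> ObservationSet:
    """Per-variable severity-directed extreme over one calendar day.

    Lower-is-worse variables take the minimum, higher-is-worse the maximum;
    missing values are ignored unless a variable is missing everywhere.
    Idempotent and order-invariant by construction.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("worst_of_day requires a non-empty list of observations")
    out = ObservationSet(timepoint_label=observations[0].timepoint_label)
    for name in _VALUE_FIELDS:
        values = [getattr(o, name) for o in observations if getattr(o, name) is not None]
        if not values:
            continue
        worst = min(values) if SEVERITY_DIRECTION[name] == "low" else max(values)
        setattr(out, name, worst)
    vent = [o.ventilated for o in observations if o.ventilated is not None]
    if vent:
        out.ventilated = any(vent)
    return out


def sepsis3_positive(
    baseline_total: float, window_totals: Sequence[float], delta: float = 2
) -> bool:
    """Sepsis-3 positivity: max score in the infection window rose >= delta over baseline."""
    window_totals = list(window_totals)
    if not window_totals:
        raise ValueError("window_totals must be non-empty")
    return max(window_totals) - baseline_total >= delta


# --------------------------------------------------------------------------
# patient records
# --------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Admission / infection-onset / day-after observations plus outcomes and flags."""

    patient_id: str
    admission: ObservationSet
    infection_onset: ObservationSet
    day_after_onset: ObservationSet | None = None
    mrs_3mo: int | None = None
    died_in_hospital: bool = False
    died_3mo: bool = False
    icu: bool = False
    treatment_limitation: bool = False
    dnr_dni: bool = False

    def __post_init__(self) -> None:
        if self.mrs_3mo is not None:
            if not (0 <= self.mrs_3mo <= 6):
                raise ValidationError(f"mrs_3mo={self.mrs_3mo} outside 0-6")
            if (self.mrs_3mo == 6) != bool(self.died_3mo):
                raise ValidationError(
                    f"patient {self.patient_id}: mrs_3mo == 6 must coincide with died_3mo"
                )
        if self.died_in_hospital and not self.died_3mo:
            raise ValidationError(
                f"patient {self.patient_id}: died_in_hospital implies died_3mo"
            )

    def observation(self, timepoint: str) -> ObservationSet | None:
        return {
            "admission": self.admission,
            "infection_onset": self.infection_onset,
            "day_after_onset": self.day_after_onset,
        }[timepoint]


def score_patient(
    record: PatientRecord,
    definition: ScoreDefinition,
    config: ScoringConfig | None = None,
    baseline: str = "admission",
    window: Sequence[str] = ("infection_onset", "day_after_onset"),
) -> dict:
    """Score all timepoints of one patient and apply the Delta >= 2 rule.

    Returns a dict with per-timepoint totals, the baseline total, the window
    maximum, the delta, and the positivity flag.  Window timepoints with no
    observation are skipped; at least one must be present.
    """
    totals: dict[str, int | None] = {}
    for tp in ("admission", "infection_onset", "day_after_onset"):
        obs = record.observation(tp)
        totals[tp] = apply_score(definition, obs, config).total if obs is not None else None
    base = totals[baseline]
    if base is None:
        raise ValueError(f"patient {record.patient_id}: baseline timepoint {baseline!r} missing")
    window_totals = [totals[tp] for tp in window if totals[tp] is not None]
    if not window_totals:
        raise ValueError(f"patient {record.patient_id}: no observations in window {window!r}")
    delta = max(window_totals) - base
    return {
        "patient_id": record.patient_id,
        "score": definition.name,
        "admission_total": totals["admission"],
        "onset_total": totals["infection_onset"],
        "day_after_total": totals["day_after_onset"],
        "baseline_total": base,
        "window_max": max(window_totals),
        "delta": delta,
        "positive": sepsis3_positive(base, window_totals, definition.positivity_delta),
    }
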