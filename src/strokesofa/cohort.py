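"""Synthetic cohorts of stroke patients with infection, with known ground truth.

No patient-level data are distributable for this problem, so the generator
emulates the statistical structure the analyses assume: three observation
timepoints per patient (admission, infection onset, day after onset), a latent
septic course in about a third of patients producing correlated multi-organ
deterioration at onset, a disability outcome (mRS 0-6 at three months) linked
monotonically to stroke severity and dysfunction burden, care-setting flags
(ICU ~24 %, treatment limitations ~20 %), and care-setting-dependent
missingness (e.g. PaO2 rarely measured outside the ICU).

Default marginal targets (sepsis by the Delta >= 2 rule ~33 %, poor outcome
mRS 5-6 ~51.7 %, ICU ~24.3 %, treatment limitations ~20.2 %) describe a
general cohort of stroke patients with stroke-associated infection.  Latent
flags and the mRS are assigned by rank (empirical quantiles of a latent
logistic-noise score), so the configured marginals are matched closely at any
cohort size while the severity ordering carries the score-outcome
association.  The Delta >= 2 sepsis fraction is emergent: it results from the
calibrated deterioration magnitudes, not from a label.

Limitations are documented in the methods note: no physiologic time-series
dynamics (only the three analysis timepoints), and the organ-correlation
structure is a plausible default, not an estimate from real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scoring import ObservationSet, PatientRecord, ScoreDefinition

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "GroundTruth",
    "generate_cohort",
    "generate_from_score",
    "matches_definition",
    "DEFAULT_MRS_CUMULATIVE",
]

#: default cumulative mRS distribution P(mRS <= k), k = 0..5, for a cohort of
#: stroke patients with stroke-associated infection (mRS 6 = death, 36.3 %)
DEFAULT_MRS_CUMULATIVE = (0.010, 0.064, 0.115, 0.259, 0.482, 0.637)

_ORGANS = ("cns", "respiration", "cardiovascular", "coagulation", "renal")


@dataclass
class CohortSpec:
    """Knobs of the generative model; defaults are the study-like conditions."""

    n_patients: int = 400
    seed: int | None = None
    sepsis_fraction: float = 0.33
    poor_outcome_fraction: float = 0.517
    icu_fraction: float = 0.243
    treatment_limitation_fraction: float = 0.202
    dnr_dni_fraction: float = 0.36
    #: multiplies all septic organ-deterioration magnitudes
    deterioration_scale: float = 1.0
    #: multiplies non-septic day-to-day physiologic noise
    noise_scale: float = 1.0
    #: weight of the dysfunction burden in the outcome linear predictor
    outcome_effect: float = 1.1
    #: weight of baseline stroke severity in the outcome linear predictor
    severity_effect: float = 1.0
    #: probability a 3-month death already occurred in hospital
    in_hospital_death_share: float = 0.507
    #: per-variable missingness as (non-ICU rate, ICU rate)
    missingness: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pao2": (0.92, 0.35),
            "fio2": (0.05, 0.02),
            "urine_output_24h": (0.75, 0.20),
            "bilirubin": (0.25, 0.10),
            "lactate": (0.60, 0.15),
            "procalcitonin": (0.70, 0.40),
            "urea": (0.10, 0.05),
            "crp": (0.05, 0.02),
            "leukocytes": (0.03, 0.02),
            "platelets": (0.03, 0.02),
            "creatinine": (0.03, 0.02),
            "spo2": (0.01, 0.005),
            "map": (0.01, 0.005),
            "respiratory_rate": (0.05, 0.02),
            "temperature": (0.02, 0.01),
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "sepsis_fraction",
            "poor_outcome_fraction",
            "icu_fraction",
            "treatment_limitation_fraction",
            "dnr_dni_fraction",
            "in_hospital_death_share",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class GroundTruth:
    """Latent generative state stored alongside the cohort for recovery tests;
    never consumed by the pipelines under test."""

    table: pd.DataFrame  # per-patient: septic, burden, eta, per-organ dysfunction


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    truth: GroundTruth
    spec: CohortSpec


def _rank_flag(score: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Top-``fraction`` indicator of (score + logistic noise): matches the
    marginal frequency by rank while keeping a graded severity link."""
    n = len(score)
    k = int(round(n * fraction))
    if k <= 0:
        return np.zeros(n, dtype=bool)
    latent = score + rng.logistic(size=n)
    cut = np.partition(latent, n - k)[n - k]
    return latent >= cut


def _mrs_from_latent(
    eta: np.ndarray, cumulative: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign mRS 0-6 by empirical quantiles of eta + logistic noise (higher
    latent score -> worse mRS), matching the cumulative distribution by rank."""
    n = len(eta)
    latent = eta + rng.logistic(size=n)
    order = np.argsort(latent)  # ascending: best outcomes first
    mrs = np.empty(n, dtype=int)
    bounds = np.round(np.concatenate([[0.0], cumulative, [1.0]]) * n).astype(int)
    for k in range(7):
        mrs[order[bounds[k] : bounds[k + 1]]] = k
    return mrs


def _scaled_cumulative(spec: CohortSpec) -> np.ndarray:
    """Rescale the default mRS distribution to the configured poor-outcome
    fraction, keeping the within-stratum shape (death share among poor
    outcomes, category ratios among non-poor outcomes)."""
    base = np.asarray(DEFAULT_MRS_CUMULATIVE)
    poor0 = 1.0 - base[4]
    poor = spec.poor_outcome_fraction
    out = base.copy()
    out[:4] = base[:4] * ((1.0 - poor) / (1.0 - poor0))  # non-poor shape kept
    out[4] = 1.0 - poor
    out[5] = 1.0 - poor * (1.0 - base[5]) / poor0  # death share among poor kept
    return np.clip(out, 0.0, 1.0)


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort under ``spec``.

    ``seed`` overrides ``spec.seed``.  Returns the patient records, the
    latent ground truth, and the spec used.
    """
    spec = spec or CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    # latent patient state ---------------------------------------------------
    sev = rng.standard_normal(n)  # baseline stroke severity
    age = np.clip(78 + 11 * (0.5 * sev + math.sqrt(0.75) * rng.standard_normal(n)), 35, 99)
    tl = _rank_flag(0.9 * sev + 0.035 * (age - 78), spec.treatment_limitation_fraction, rng)
    septic = _rank_flag(0.8 * sev + 0.9 * tl, spec.sepsis_fraction, rng)
    icu = _rank_flag(0.7 * sev + 0.8 * septic, spec.icu_fraction, rng)
    dnr = _rank_flag(0.05 * (age - 78) + 0.6 * sev + 1.5 * tl, spec.dnr_dni_fraction, rng)

    # per-organ dysfunction of the septic course (shared factor + organ noise)
    d_base = np.where(septic, rng.gamma(2.0, 0.5, size=n) + 0.6, 0.0)
    t = {
        organ: np.where(septic, np.clip(d_base + 0.5 * rng.standard_normal(n), 0.05, None), 0.0)
        for organ in _ORGANS
    }
    burden = sum(t.values()) / len(_ORGANS)

    # admission observations -------------------------------------------------
    nihss0 = np.clip(np.round(11 + 8 * sev + 2.5 * rng.standard_normal(n)), 0, 42)
    gcs0 = np.clip(np.round(15 - 0.22 * nihss0 - np.abs(rng.standard_normal(n))), 3, 15)
    map0 = np.round(88 + 12 * rng.standard_normal(n))
    spo2_0 = np.clip(np.round(96.5 - 1.8 * np.abs(rng.standard_normal(n))), 70, 100)
    rr0 = np.clip(np.round(17 + 3 * rng.standard_normal(n)), 8, 60)
    plt0 = np.clip(np.round(255 + 75 * rng.standard_normal(n)), 15, 900)
    crea0 = np.round(np.exp(np.log(0.95) + 0.30 * rng.standard_normal(n)), 1)
    bili0 = np.round(np.exp(np.log(0.6) + 0.40 * rng.standard_normal(n)), 1)
    temp0 = np.round(36.8 + 0.5 * rng.standard_normal(n), 1)
    leuk0 = np.round(np.exp(np.log(8.5) + 0.30 * rng.standard_normal(n)), 1)
    crp0 = np.round(np.exp(np.log(12) + 0.8 * rng.standard_normal(n)), 1)
    urea0 = np.round(np.exp(np.log(40) + 0.35 * rng.standard_normal(n)), 0)
    lact0 = np.round(np.exp(np.log(1.2) + 0.35 * rng.standard_normal(n)), 1)
    pct0 = np.round(np.exp(np.log(0.08) + 0.7 * rng.standard_normal(n)), 2)
    urine0 = np.clip(np.round(1800 + 500 * rng.standard_normal(n), -1), 100, None)
    pao2_0 = np.round(88 + 14 * rng.standard_normal(n))
    fio2_0 = np.where(icu & (rng.random(n) < 0.4), 0.21 + 0.2 * rng.random(n), 0.21)

    ds = spec.deterioration_scale
    ns = spec.noise_scale

    def onset_shift(day2: bool) -> dict[str, np.ndarray]:
        """Deterioration from admission to infection onset (or the day after:
        the septic course persists with mild variation)."""
        persist = rng.uniform(0.85, 1.15, size=n) if day2 else 1.0
        sick = septic.astype(float) * persist * ds
        e = lambda s: rng.standard_normal(n) * s * ns  # noqa: E731
        return {
            "nihss": np.round(sick * (3 + 2.5 * t["cns"]) + e(1.0)),
            "gcs": -np.round(sick * (1 + 1.1 * t["cns"]) + np.abs(e(0.4))),
            "map": -sick * (10 + 9 * t["cardiovascular"]) + e(6.0),
            "spo2": -sick * (3 + 3 * t["respiration"]) - np.abs(e(1.2)),
            "respiratory_rate": sick * (4 + 3 * t["respiration"]) + 1.5 + e(2.0),
            "platelets": -sick * (40 + 45 * t["coagulation"]) + e(18.0),
            "crea_factor": 1 + sick * 0.35 * t["renal"] + e(0.05),
            "urine_factor": 1 - sick * 0.3 * np.clip(t["renal"], 0, 2) / 2,
            "temperature": sick * (0.8 + 0.4 * burden) + 0.5 + np.abs(e(0.4)),
            "crp": sick * (70 + 50 * burden) + 45 + np.abs(e(25.0)),
            "leukocytes": sick * (3 + 2 * burden) + 2 + e(1.5),
            "lactate": sick * 0.8 * burden + np.abs(e(0.3)),
            "procalcitonin": sick * (0.6 + 1.5 * burden),
        }

    def assemble(shift: dict[str, np.ndarray] | None, label: str) -> dict[str, np.ndarray]:
        if shift is None:
            zero = np.zeros(n)
            shift = {
                k: (np.ones(n) if k.endswith("_factor") else zero)
                for k in (
                    "nihss gcs map spo2 respiratory_rate platelets crea_factor "
                    "urine_factor temperature crp leukocytes lactate procalcitonin"
                ).split()
            }
        vals = {
            "nihss": np.clip(nihss0 + shift["nihss"], 0, 42),
            "gcs": np.clip(gcs0 + shift["gcs"], 3, 15),
            "map": np.clip(np.round(map0 + shift["map"]), 30, 200),
            "spo2": np.clip(np.round(spo2_0 + shift["spo2"]), 55, 100),
            "respiratory_rate": np.clip(np.round(rr0 + shift["respiratory_rate"]), 6, 70),
            "platelets": np.clip(np.round(plt0 + shift["platelets"]), 5, 1200),
            "creatinine": np.round(np.clip(crea0 * shift["crea_factor"], 0.2, 20), 1),
            "urine_output_24h": np.clip(np.round(urine0 * shift["urine_factor"], -1), 50, None),
            "bilirubin": np.clip(bili0, 0.1, 30),
            "temperature": np.round(np.clip(temp0 + shift["temperature"], 34, 42.5), 1),
            "crp": np.round(np.clip(crp0 + shift["crp"], 0.1, 600), 1),
            "leukocytes": np.round(np.clip(leuk0 + shift["leukocytes"], 0.5, 200), 1),
            "lactate": np.round(np.clip(lact0 + shift["lactate"], 0.2, 30), 1),
            "procalcitonin": np.round(np.clip(pct0 + shift["procalcitonin"], 0.01, 900), 2),
            "urea": np.clip(urea0, 5, 400),
            "pao2": np.clip(np.round(pao2_0 + 0.9 * shift["spo2"] * 2.5), 35, 600),
            "fio2": np.round(np.clip(fio2_0 + (0.21 if label != "admission" else 0.0)
                                     * septic * icu * np.clip(t["respiration"], 0, 2) / 2, 0.21, 1.0), 2),
        }
        return vals

    onset1 = onset_shift(day2=False)
    onset2 = onset_shift(day2=True)
    tp_values = {
        "admission": assemble(None, "admission"),
        "infection_onset": assemble(onset1, "infection_onset"),
        "day_after_onset": assemble(onset2, "day_after_onset"),
    }

    # vasopressors: septic ICU patients with a marked cardiovascular course
    norepi_on = septic & icu & (rng.random(n) < 0.5)
    norepi_dose = np.round(np.clip(0.02 + 0.08 * t["cardiovascular"], 0.01, 2.0), 2)
    for label in ("infection_onset", "day_after_onset"):
        tp_values[label]["norepinephrine"] = np.where(norepi_on, norepi_dose, np.nan)

    # missingness ------------------------------------------------------------
    for label, vals in tp_values.items():
        for var, (rate_ward, rate_icu) in spec.missingness.items():
            rate = np.where(icu, rate_icu, rate_ward)
            drop = rng.random(n) < rate
            if var in vals:
                vals[var] = np.where(drop, np.nan, vals[var])

    # outcome ----------------------------------------------------------------
    eta = (
        spec.severity_effect * sev
        + spec.outcome_effect * burden * len(_ORGANS)
        + 0.8 * tl
        + 0.035 * (age - 78)
    )
    mrs = _mrs_from_latent(eta, _scaled_cumulative(spec), rng)
    died_3mo = mrs == 6
    died_hosp = died_3mo & (rng.random(n) < spec.in_hospital_death_share)

    # assemble records -------------------------------------------------------
    def _f(x) -> float | None:
        return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)

    records: list[PatientRecord] = []
    for i in range(n):
        obs = {}
        for label, vals in tp_values.items():
            kwargs = {var: _f(vals[var][i]) for var in vals}
            obs[label] = ObservationSet(timepoint_label=label, **kwargs)
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                admission=obs["admission"],
                infection_onset=obs["infection_onset"],
                day_after_onset=obs["day_after_onset"],
                mrs_3mo=int(mrs[i]),
                died_in_hospital=bool(died_hosp[i]),
                died_3mo=bool(died_3mo[i]),
                icu=bool(icu[i]),
                treatment_limitation=bool(tl[i]),
                dnr_dni=bool(dnr[i]),
            )
        )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "septic": septic,
                "burden": burden,
                "eta": eta,
                "severity": sev,
                "age": age,
                **{f"dysfunction_{o}": t[o] for o in _ORGANS},
            }
        )
    )
    return SyntheticCohort(records=records, truth=truth, spec=spec)


# --------------------------------------------------------------------------
# score-driven generator for derivation recovery tests
# --------------------------------------------------------------------------

#: marginal samplers for raw predictor values (units as in ObservationSet);
#: centered so each default S-SOFA cutoff has usable density on both sides
def _default_samplers(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "nihss": np.clip(np.round(13 + 7 * rng.standard_normal(n)), 0, 42),
        "spo2": np.clip(np.round(92.5 + 3.0 * rng.standard_normal(n)), 70, 100),
        "map": np.round(73 + 11 * rng.standard_normal(n)),
        "platelets": np.clip(np.round(170 + 60 * rng.standard_normal(n)), 10, 600),
        "creatinine": np.round(np.exp(np.log(1.05) + 0.35 * rng.standard_normal(n)), 1),
        "gcs": np.clip(np.round(13.5 - 2 * np.abs(rng.standard_normal(n))), 3, 15),
        "respiratory_rate": np.clip(np.round(18 + 4 * rng.standard_normal(n)), 8, 50),
        "bilirubin": np.round(np.exp(np.log(0.7) + 0.4 * rng.standard_normal(n)), 1),
        "temperature": np.round(37.0 + 0.7 * rng.standard_normal(n), 1),
    }


def generate_from_score(
    definition: ScoreDefinition,
    effect_per_point: float = 1.8,
    n: int = 2000,
    seed: int | None = None,
    noise_predictors: tuple[str, ...] = ("bilirubin", "temperature"),
    outcome_rate: float = 0.40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Training frame whose outcome is generated from a known binary score.

    Raw variables are drawn from the default marginal samplers; the outcome is
    Bernoulli with log-odds ``alpha + effect_per_point * total`` where the
    total counts the definition's items at their true cutoffs, and ``alpha``
    is set so the marginal outcome rate is near ``outcome_rate``.  Returns the
    frame (predictors + ``poor_outcome``) and a ground-truth frame with the
    item indicators and totals, for parameter-recovery testing.
    """
    rng = np.random.default_rng(seed)
    values = _default_samplers(rng, n)
    cols = {
        item.variable for item in definition.items  # type: ignore[attr-defined]
    } | set(noise_predictors)
    missing = cols - set(values)
    if missing:
        raise ValueError(f"no sampler for variables {sorted(missing)}")
    frame = pd.DataFrame({c: values[c] for c in sorted(cols)})
    total = np.zeros(n)
    truth_cols = {}
    for item in definition.items:
        x = frame[item.variable].to_numpy(dtype=float)  # type: ignore[attr-defined]
        thr = item.thresholds[0]  # type: ignore[attr-defined]
        ind = (x >= thr) if item.direction == "ge" else (x < thr)  # type: ignore[attr-defined]
        pts = ind.astype(float) * item.points[0]  # type: ignore[attr-defined]
        total += pts
        truth_cols[f"item_{item.variable}"] = ind.astype(int)  # type: ignore[attr-defined]
    if effect_per_point == 0.0:
        import warnings

        warnings.warn("effect_per_point = 0: recovery testing is meaningless on null data")
    # alpha matching the target marginal rate at the realized item totals
    from scipy.special import expit, logit
    from scipy.optimize import brentq

    def mean_rate(alpha: float) -> float:
        return float(expit(alpha + effect_per_point * total).mean())

    lo, hi = -30.0, 30.0
    alpha = brentq(lambda a: mean_rate(a) - outcome_rate, lo, hi)
    p = expit(alpha + effect_per_point * total)
    y = (rng.random(n) < p).astype(int)
    frame["poor_outcome"] = y
    truth = pd.DataFrame({**truth_cols, "total": total, "p_outcome": p})
    return frame, truth


def matches_definition(
    candidate: ScoreDefinition,
    truth: ScoreDefinition,
    tol: float = 1.0,
    bp_tol: float = 5.0,
    bp_variables: tuple[str, ...] = ("map", "systolic_bp"),
) -> bool:
    """True when the candidate has exactly the truth's items and every cutoff
    within the rounding resolution (+-1 unit; +-5 for blood pressure)."""
    cand = {item.variable: item for item in candidate.items}  # type: ignore[attr-defined]
    true = {item.variable: item for item in truth.items}  # type: ignore[attr-defined]
    if set(cand) != set(true):
        return False
    for var, t_item in true.items():
        c_item = cand[var]
        if c_item.direction != t_item.direction:  # type: ignore[attr-defined]
            return False
        allowed = bp_tol if var in bp_variables else tol
        if abs(c_item.thresholds[0] - t_item.thresholds[0]) > allowed + 1e-9:  # type: ignore[attr-defined]
            return False
    return True
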