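"""Cohort file I/O, outcome definitions, score-definition files, and the
validation orchestration producing the AUC comparison report.

Cohort files are comma-separated UTF-8 with a header, one row per
patient-timepoint; missing values are empty cells.  A column dictionary maps
accepted aliases onto the canonical :class:`~strokesofa.scoring.ObservationSet`
field names and enforces physiologic ranges with row/column context.

Outcome definitions are centralized here: poor = mRS 5-6, unfavourable =
mRS 4-6, independence = mRS 0-2, death at 3 months = mRS 6, plus in-hospital
death as its own flag.
"""

from __future__ import annotations

import configparser
import io as _io
import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from . import auc as auc_mod
from .scoring import (
    PHYSIOLOGIC_BOUNDS,
    S_SOFA,
    SOFA,
    BandItem,
    CardiovascularItem,
    ObservationSet,
    PatientRecord,
    RenalItem,
    RespirationItem,
    ScoreDefinition,
    ScoringConfig,
    ValidationError,
    apply_score,
    score_patient,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnDictionary",
    "DEFAULT_DICTIONARY",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "training_frame",
    "outcome_vector",
    "subgroup_mask",
    "OUTCOMES",
    "SUBGROUPS",
    "ValidationReport",
    "run_validation",
    "score_definition_to_text",
    "score_definition_from_text",
    "write_score_definition",
    "read_score_definition",
]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files, naming the offending row/column."""


_OBS_FIELDS = [
    f.name
    for f in dc_fields(ObservationSet)
    if f.name not in ("timepoint_label", "ventilated")
]

_META_COLUMNS = [
    "patient_id",
    "timepoint",
    "mrs_3mo",
    "died_in_hospital",
    "died_3mo",
    "icu",
    "treatment_limitation",
    "dnr_dni",
]

_TIMEPOINT_ALIASES = {
    "admission": "admission",
    "baseline": "admission",
    "infection_onset": "infection_onset",
    "onset": "infection_onset",
    "day_after_onset": "day_after_onset",
    "day-after": "day_after_onset",
    "day_after": "day_after_onset",
}


@dataclass
class ColumnDictionary:
    """Canonical field -> accepted aliases (all compared lower-case)."""

    aliases: dict[str, tuple[str, ...]]

    def resolve(self, column: str) -> str | None:
        c = column.strip().lower()
        for canonical, names in self.aliases.items():
            if c == canonical or c in names:
                return canonical
        return None


DEFAULT_DICTIONARY = ColumnDictionary(
    aliases={
        **{name: () for name in _META_COLUMNS},
        "gcs": ("glasgow_coma_scale",),
        "nihss": ("nihss_score",),
        "spo2": ("peripheral_oxygen_saturation", "spo2_pct"),
        "pao2": ("pao2_mmhg",),
        "fio2": ("fio2_fraction",),
        "map": ("mean_arterial_pressure", "map_mmhg"),
        "systolic_bp": ("sbp", "systolic_blood_pressure"),
        "respiratory_rate": ("rr", "resp_rate"),
        "dopamine": (),
        "dobutamine": (),
        "epinephrine": ("adrenaline",),
        "norepinephrine": ("noradrenaline",),
        "platelets": ("thrombocytes", "thrombocyte_count", "platelet_count"),
        "bilirubin": (),
        "creatinine": (),
        "urine_output_24h": ("urine_output",),
        "temperature": ("temp",),
        "lactate": (),
        "leukocytes": ("wbc", "leukocyte_count"),
        "crp": ("c_reactive_protein",),
        "procalcitonin": ("pct",),
        "urea": (),
        "ventilated": (),
    }
)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Long-format frame: one row per patient-timepoint, outcomes repeated."""
    rows = []
    for r in records:
        for tp in ("admission", "infection_onset", "day_after_onset"):
            obs = r.observation(tp)
            if obs is None:
                continue
            row: dict = {"patient_id": r.patient_id, "timepoint": tp}
            for name in _OBS_FIELDS:
                row[name] = getattr(obs, name)
            row.update(
                mrs_3mo=r.mrs_3mo,
                died_in_hospital=int(r.died_in_hospital),
                died_3mo=int(r.died_3mo),
                icu=int(r.icu),
                treatment_limitation=int(r.treatment_limitation),
                dnr_dni=int(r.dnr_dni),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("1", "true", "yes"):
            return True
        if v in ("0", "false", "no", ""):
            return False
        raise CohortFormatError(f"{context}: unparsable boolean {value!r}")
    if pd.isna(value):
        return False
    return bool(int(value))


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Typed, range-checked records from a long-format frame."""
    if "patient_id" not in df.columns or "timepoint" not in df.columns:
        raise CohortFormatError("required columns 'patient_id' and 'timepoint' missing")
    records: list[PatientRecord] = []
    for pid, group in df.groupby("patient_id", sort=True):
        obs_by_tp: dict[str, ObservationSet] = {}
        for idx, row in group.iterrows():
            tp_raw = str(row["timepoint"]).strip().lower()
            tp = _TIMEPOINT_ALIASES.get(tp_raw)
            if tp is None:
                raise CohortFormatError(
                    f"row {idx}: unknown timepoint {row['timepoint']!r}"
                )
            if tp in obs_by_tp:
                raise CohortFormatError(
                    f"row {idx}: duplicate timepoint {tp!r} for patient {pid!r}"
                )
            kwargs: dict = {"timepoint_label": tp}
            for name in _OBS_FIELDS:
                if name not in row.index or pd.isna(row[name]):
                    continue
                try:
                    value = float(row[name])
                except (TypeError, ValueError):
                    raise CohortFormatError(
                        f"row {idx}, column {name!r}: unparsable value {row[name]!r}"
                    ) from None
                lo, hi = PHYSIOLOGIC_BOUNDS[name]
                if not (lo <= value <= hi):
                    raise CohortFormatError(
                        f"row {idx}, column {name!r}: value {value} outside [{lo}, {hi}]"
                    )
                kwargs[name] = value
            obs_by_tp[tp] = ObservationSet(**kwargs)
        if "admission" not in obs_by_tp or "infection_onset" not in obs_by_tp:
            raise CohortFormatError(
                f"patient {pid!r}: needs both admission and infection_onset rows"
            )
        first = group.iloc[0]
        mrs = None
        if "mrs_3mo" in group.columns and not pd.isna(first["mrs_3mo"]):
            mrs = int(first["mrs_3mo"])
        def flag(col: str) -> bool:
            return (
                _parse_bool(first[col], f"patient {pid!r}, column {col!r}")
                if col in group.columns
                else False
            )
        try:
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    admission=obs_by_tp["admission"],
                    infection_onset=obs_by_tp["infection_onset"],
                    day_after_onset=obs_by_tp.get("day_after_onset"),
                    mrs_3mo=mrs,
                    died_in_hospital=flag("died_in_hospital"),
                    died_3mo=flag("died_3mo"),
                    icu=flag("icu"),
                    treatment_limitation=flag("treatment_limitation"),
                    dnr_dni=flag("dnr_dni"),
                )
            )
        except ValidationError as err:
            raise CohortFormatError(f"patient {pid!r}: {err}") from err
    return records


def read_cohort(
    path, dictionary: ColumnDictionary | None = None
) -> list[PatientRecord]:
    """Read a delimited cohort file into validated patient records."""
    dictionary = dictionary or DEFAULT_DICTIONARY
    df = pd.read_csv(path)
    renames: dict[str, str] = {}
    for col in df.columns:
        canonical = dictionary.resolve(col)
        if canonical is not None:
            renames[col] = canonical
        else:
            logger.warning("column %r not in the dictionary; ignored", col)
    df = df.rename(columns=renames)
    dup = df.columns[df.columns.duplicated()]
    if len(dup):
        raise CohortFormatError(f"duplicate canonical columns after aliasing: {list(dup)}")
    return frame_to_records(df)


def write_cohort(records: list[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def training_frame(
    records: list[PatientRecord],
    predictors: list[str],
    timepoint: str = "infection_onset",
    outcome: str = "poor",
    outcome_column: str = "poor_outcome",
) -> pd.DataFrame:
    """One row per patient: predictor values at ``timepoint`` plus the binary
    outcome — the input shape of the derivation pipeline."""
    rows = []
    y = outcome_vector(records, outcome)
    for r, yi in zip(records, y):
        obs = r.observation(timepoint)
        row = {"patient_id": r.patient_id}
        for name in predictors:
            row[name] = getattr(obs, name) if obs is not None else None
        row[outcome_column] = yi
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# outcomes and subgroups
# --------------------------------------------------------------------------

OUTCOMES = ("poor", "unfavourable", "independent", "death_3mo", "death_hospital")

SUBGROUPS = ("full", "no_limitations", "icu", "non_icu",
             "icu_no_limitations", "non_icu_no_limitations")


def outcome_vector(records: list[PatientRecord], outcome: str) -> np.ndarray:
    """Binary outcome per patient (NaN where the mRS is missing)."""
    def from_mrs(r: PatientRecord, pred) -> float:
        return float("nan") if r.mrs_3mo is None else float(pred(r.mrs_3mo))

    if outcome == "poor":
        return np.array([from_mrs(r, lambda m: m >= 5) for r in records])
    if outcome == "unfavourable":
        return np.array([from_mrs(r, lambda m: m >= 4) for r in records])
    if outcome == "independent":
        return np.array([from_mrs(r, lambda m: m <= 2) for r in records])
    if outcome == "death_3mo":
        return np.array([float(r.died_3mo) for r in records])
    if outcome == "death_hospital":
        return np.array([float(r.died_in_hospital) for r in records])
    raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")


def subgroup_mask(records: list[PatientRecord], subgroup: str) -> np.ndarray:
    if subgroup == "full":
        return np.ones(len(records), dtype=bool)
    if subgroup == "no_limitations":
        return np.array([not r.treatment_limitation for r in records])
    if subgroup == "icu":
        return np.array([r.icu for r in records])
    if subgroup == "non_icu":
        return np.array([not r.icu for r in records])
    if subgroup == "icu_no_limitations":
        return np.array([r.icu and not r.treatment_limitation for r in records])
    if subgroup == "non_icu_no_limitations":
        return np.array([(not r.icu) and not r.treatment_limitation for r in records])
    raise ValueError(f"unknown subgroup {subgroup!r}; choose from {SUBGROUPS}")


# --------------------------------------------------------------------------
# validation orchestration
# --------------------------------------------------------------------------


def _wald_or(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """2x2 odds ratio (exposed cases a, exposed controls b, unexposed cases c,
    unexposed controls d) with a Wald 95 % CI; infinite with a zero cell."""
    import math

    if min(a, b, c, d) == 0:
        orr = float("inf") if (b == 0 or c == 0) and a * d > 0 else (
            0.0 if (a == 0 or d == 0) else float("nan")
        )
        return orr, float("nan"), float("nan")
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = auc_mod.Z_975
    return orr, orr * math.exp(-z * se), orr * math.exp(z * se)


@dataclass
class ValidationReport:
    """AUC comparisons per outcome x subgroup plus positivity/OR summaries."""

    auc_table: pd.DataFrame
    positivity_table: pd.DataFrame
    margin: float


def run_validation(
    records: list[PatientRecord],
    score_a: ScoreDefinition = S_SOFA,
    score_b: ScoreDefinition = SOFA,
    outcomes: tuple[str, ...] = ("poor", "death_hospital", "death_3mo"),
    subgroups: tuple[str, ...] = ("full", "no_limitations", "icu", "non_icu"),
    margin: float = 0.06,
    config: ScoringConfig | None = None,
    baseline: str = "admission",
    window: tuple[str, ...] = ("infection_onset", "day_after_onset"),
) -> ValidationReport:
    """Paired non-inferiority AUC comparisons of two scores on one cohort.

    The predictive value of each score is its total at infection onset; the
    positivity flag uses the Delta >= 2 rule over the baseline.  Cells whose
    subgroup has no events (or no non-events) are reported as not computable.
    """
    scored = {
        defn.name: [score_patient(r, defn, config, baseline, window) for r in records]
        for defn in (score_a, score_b)
    }
    onset_a = np.array([s["onset_total"] for s in scored[score_a.name]], dtype=float)
    onset_b = np.array([s["onset_total"] for s in scored[score_b.name]], dtype=float)
    pos = {
        name: np.array([s["positive"] for s in rows], dtype=bool)
        for name, rows in scored.items()
    }

    auc_rows = []
    for subgroup in subgroups:
        mask = subgroup_mask(records, subgroup)
        for outcome in outcomes:
            y = outcome_vector(records, outcome)
            ok = mask & ~np.isnan(y) & ~np.isnan(onset_a) & ~np.isnan(onset_b)
            yy = y[ok]
            row = {
                "subgroup": subgroup,
                "outcome": outcome,
                "n": int(ok.sum()),
                "events": int(yy.sum()),
            }
            if len(yy) == 0 or yy.sum() in (0, len(yy)):
                row.update(computable=False)
                auc_rows.append(row)
                continue
            cmp = auc_mod.noninferiority_test(onset_a[ok], onset_b[ok], yy, margin=margin)
            ca, cb = cmp.auc_a.ci(), cmp.auc_b.ci()
            row.update(
                computable=True,
                auc_a=cmp.auc_a.auc, auc_a_lo=ca[0], auc_a_hi=ca[1],
                auc_b=cmp.auc_b.auc, auc_b_lo=cb[0], auc_b_hi=cb[1],
                difference=cmp.difference,
                diff_lo=cmp.ci_low, diff_hi=cmp.ci_high,
                p_one_sided=cmp.p_one_sided,
                non_inferior=cmp.non_inferior,
            )
            auc_rows.append(row)

    pos_rows = []
    y_poor = outcome_vector(records, "poor")
    for subgroup in subgroups:
        mask = subgroup_mask(records, subgroup)
        for name in (score_a.name, score_b.name):
            ok = mask & ~np.isnan(y_poor)
            p = pos[name][ok]
            yy = y_poor[ok].astype(bool)
            a = int((p & yy).sum())
            b = int((p & ~yy).sum())
            c = int((~p & yy).sum())
            d = int((~p & ~yy).sum())
            orr, lo, hi = _wald_or(a, b, c, d)
            pos_rows.append(
                {
                    "subgroup": subgroup,
                    "score": name,
                    "n": int(ok.sum()),
                    "positive": int(p.sum()),
                    "positive_pct": 100.0 * p.mean() if len(p) else float("nan"),
                    "odds_ratio": orr,
                    "or_lo": lo,
                    "or_hi": hi,
                }
            )
    return ValidationReport(
        auc_table=pd.DataFrame(auc_rows),
        positivity_table=pd.DataFrame(pos_rows),
        margin=margin,
    )


# --------------------------------------------------------------------------
# score-definition files (human-editable key/value text)
# --------------------------------------------------------------------------


def score_definition_to_text(definition: ScoreDefinition) -> str:
    cp = configparser.ConfigParser()
    cp["score"] = {
        "name": definition.name,
        "positivity_delta": str(definition.positivity_delta),
    }
    for i, item in enumerate(definition.items):
        section = f"item:{item.organ_system}:{i}"
        if isinstance(item, BandItem):
            cp[section] = {
                "kind": "bands",
                "variable": item.variable,
                "direction": item.direction,
                "thresholds": ",".join(f"{t:g}" for t in item.thresholds),
                "points": ",".join(str(p) for p in item.points),
            }
        elif isinstance(item, RespirationItem):
            cp[section] = {"kind": "respiration"}
        elif isinstance(item, CardiovascularItem):
            cp[section] = {"kind": "cardiovascular"}
        elif isinstance(item, RenalItem):
            cp[section] = {"kind": "renal"}
        else:  # pragma: no cover - no other item kinds exist
            raise TypeError(f"cannot serialize item {item!r}")
    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def score_definition_from_text(text: str) -> ScoreDefinition:
    cp = configparser.ConfigParser()
    cp.read_string(text)
    if "score" not in cp:
        raise CohortFormatError("score definition file lacks a [score] section")
    items = []
    for section in cp.sections():
        if not section.startswith("item:"):
            continue
        organ = section.split(":")[1]
        kind = cp[section].get("kind", "bands")
        if kind == "bands":
            items.append(
                BandItem(
                    organ_system=organ,
                    variable=cp[section]["variable"],
                    direction=cp[section]["direction"],
                    thresholds=tuple(
                        float(t) for t in cp[section]["thresholds"].split(",")
                    ),
                    points=tuple(int(p) for p in cp[section]["points"].split(",")),
                )
            )
        elif kind == "respiration":
            items.append(RespirationItem(organ_system=organ))
        elif kind == "cardiovascular":
            items.append(CardiovascularItem(organ_system=organ))
        elif kind == "renal":
            items.append(RenalItem(organ_system=organ))
        else:
            raise CohortFormatError(f"unknown item kind {kind!r} in {section}")
    return ScoreDefinition(
        name=cp["score"].get("name", "score"),
        items=tuple(items),
        positivity_delta=cp["score"].getint("positivity_delta", 2),
    )


def write_score_definition(definition: ScoreDefinition, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(score_definition_to_text(definition))


def read_score_definition(path) -> ScoreDefinition:
    name = str(path).lower()
    if name in ("sofa", "s-sofa", "ssofa"):
        return SOFA if name == "sofa" else S_SOFA
    with open(path, encoding="utf-8") as fh:
        return score_definition_from_text(fh.read())
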