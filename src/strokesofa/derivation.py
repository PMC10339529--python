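"""Three-step derivation of a simplified organ-dysfunction score.

Given a training cohort (one row per patient: candidate predictor values at a
fixed timepoint plus a binary poor-outcome label), the procedure is:

1. **Univariable screen** — per-predictor logistic regression of the outcome;
   predictors whose Wald 95 % CI for the odds ratio excludes 1 are carried
   forward.  Clinically mandated predictors (e.g. a blood-pressure and a renal
   marker, as hallmarks of sepsis) can be forced through regardless.
2. **Dichotomization** — each carried metric predictor is cut at the
   Youden-index-optimal ROC threshold (J = sensitivity + specificity - 1),
   rounded to the nearest whole number (nearest multiple of 5 for
   blood-pressure variables).  When the data-driven cutoff still lies inside
   the predictor's clinical normal range it is replaced by the established
   cutoff of the reference score (e.g. platelets < 150, creatinine >= 1.2).
3. **Model ranking** — every admissible combination of the dichotomized items
   (at most one per organ system) is fit by multivariable logistic regression
   and ranked by Nagelkerke's R^2; among near-ties (within a configurable R^2
   tolerance) explicit preference rules (fewer items, clinically preferred
   variables) pick the final model, which becomes a binary
   :class:`~strokesofa.scoring.ScoreDefinition` with the Delta >= 2 rule.

Logistic fits are maximum-likelihood (statsmodels); complete separation is
flagged rather than silently reported as a finite odds ratio.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtri

from .scoring import BandItem, ScoreDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariableResult",
    "CutpointResult",
    "ModelFit",
    "PredictorSpec",
    "DerivationConfig",
    "DerivationReport",
    "fit_logistic",
    "univariable_screen",
    "youden_cutpoint",
    "round_cutoff",
    "apply_normal_range_override",
    "nagelkerke_r2",
    "dichotomize",
    "enumerate_and_rank_models",
    "derive_score",
    "default_derivation_config",
]

Z_975 = float(ndtri(0.975))

#: coefficients larger than this (log-odds per unit after scaling) flag separation
_SEPARATION_BOUND = 15.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class PredictorSpec:
    """How one candidate predictor enters the derivation.

    ``direction`` is the clinical severity direction ("high_is_bad" scores
    values >= cutoff, "low_is_bad" values < cutoff); it is configured, not
    inferred from data.  ``normal_range`` (inclusive) and
    ``established_cutoff`` drive the normal-range override of step 2;
    ``forced`` carries the predictor through step 1 regardless of
    significance; ``preferred`` breaks near-ties in step 3.
    """

    name: str
    organ_system: str
    direction: str = "high_is_bad"
    is_blood_pressure: bool = False
    normal_range: tuple[float, float] | None = None
    established_cutoff: float | None = None
    forced: bool = False
    preferred: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("high_is_bad", "low_is_bad"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")


@dataclass
class DerivationConfig:
    predictors: list[PredictorSpec]
    outcome: str = "poor_outcome"
    min_n: int = 50
    r2_tolerance: float = 0.01
    max_model_size: int | None = None
    prefer_fewer_items: bool = True
    score_name: str = "derived"
    positivity_delta: int = 2

    def spec(self, name: str) -> PredictorSpec:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


def default_derivation_config(
    extra: list[PredictorSpec] | None = None,
) -> DerivationConfig:
    """Stroke-unit candidate set: one bedside predictor per organ system.

    MAP and creatinine are forced through the screen (arterial hypotension and
    renal failure are hallmarks of sepsis even when not univariably
    significant); SpO2 is preferred over the respiratory rate among near-ties
    (respiratory-rate changes after stroke are frequently non-infectious).
    """
    predictors = [
        PredictorSpec("nihss", "cns", "high_is_bad", preferred=True),
        PredictorSpec("gcs", "cns", "low_is_bad"),
        PredictorSpec("spo2", "respiration", "low_is_bad", preferred=True),
        PredictorSpec("respiratory_rate", "respiration", "high_is_bad"),
        PredictorSpec(
            "map", "cardiovascular", "low_is_bad", is_blood_pressure=True,
            established_cutoff=70.0, forced=True, preferred=True,
        ),
        PredictorSpec(
            "platelets", "coagulation", "low_is_bad",
            normal_range=(150.0, 400.0), established_cutoff=150.0,
        ),
        PredictorSpec(
            "creatinine", "renal", "high_is_bad",
            normal_range=(0.5, 1.2), established_cutoff=1.2, forced=True,
        ),
        PredictorSpec("bilirubin", "liver", "high_is_bad"),
        PredictorSpec("temperature", "inflammation", "high_is_bad"),
    ]
    if extra:
        predictors.extend(extra)
    return DerivationConfig(predictors=predictors)


# --------------------------------------------------------------------------
# step 0: logistic fitting
# --------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Maximum-likelihood logistic fit with Nagelkerke goodness of fit."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    standard_errors: dict[str, float]
    log_likelihood: float
    null_log_likelihood: float
    n: int
    nagelkerke_r2: float
    converged: bool
    separated: bool


def _null_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    m = y.sum()
    return float(m * math.log(p) + (len(y) - m) * math.log(1 - p))


def fit_logistic(x, y, names: list[str] | None = None) -> ModelFit:
    """Logit MLE of a binary outcome on a predictor matrix (intercept added).

    Complete separation is reported through ``separated`` / ``converged``
    flags (coefficients diverge) instead of failing silently.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"n={n} below the minimal fitting size of 10")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("outcome must contain both classes (0 and 1)")
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    design = sm.add_constant(x, has_constant="add")
    separated = False
    converged = True
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, method="newton")
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation raises inside statsmodels
            separated = True
            converged = False
            params = np.full(design.shape[1], np.nan)
            bse = np.full(design.shape[1], np.nan)
            llf = float(_null_loglik(y))
    scale = np.concatenate([[1.0], np.nanstd(x, axis=0) + 1e-12])
    if not separated and np.any(np.abs(params[1:] * scale[1:]) > _SEPARATION_BOUND):
        separated = True
    ll0 = _null_loglik(y)
    coefs = {"intercept": float(params[0])}
    ses = {"intercept": float(bse[0])}
    for i, name in enumerate(names):
        coefs[name] = float(params[i + 1])
        ses[name] = float(bse[i + 1])
    r2 = nagelkerke_r2(ll0, max(llf, ll0), n) if ll0 < 0 else float("nan")
    return ModelFit(
        predictors=tuple(names),
        coefficients=coefs,
        standard_errors=ses,
        log_likelihood=llf,
        null_log_likelihood=ll0,
        n=n,
        nagelkerke_r2=r2,
        converged=converged,
        separated=separated,
    )


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke's normalized Cox-Snell pseudo-R^2 for a logistic model.

    R^2 = [1 - exp(2 (ll_null - ll_model)/n)] / [1 - exp(2 ll_null / n)].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ll_model < ll_null - 1e-9:
        raise ValueError("ll_model must be >= ll_null")
    if ll_null >= 0.0:
        raise ValueError("degenerate null model (ll_null = 0): single-class outcome")
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    max_cs = 1.0 - math.exp(2.0 * ll_null / n)
    return min(max(cox_snell / max_cs, 0.0), 1.0)


# --------------------------------------------------------------------------
# step 1: univariable screen
# --------------------------------------------------------------------------


@dataclass
class UnivariableResult:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int
    significant: bool
    forced: bool
    carried_forward: bool
    separated: bool = False


def univariable_screen(
    df: pd.DataFrame, config: DerivationConfig
) -> list[UnivariableResult]:
    """Per-predictor logistic screen; carries significant-or-forced predictors.

    Significance is the Wald 95 % CI for the per-unit odds ratio excluding 1
    (no multiple-testing correction).  Complete-case analysis per predictor;
    an all-missing predictor is excluded with a warning.
    """
    y_all = df[config.outcome]
    results: list[UnivariableResult] = []
    for spec in config.predictors:
        if spec.name not in df.columns:
            logger.warning("predictor %s not in cohort; skipped", spec.name)
            continue
        mask = df[spec.name].notna() & y_all.notna()
        if not mask.any():
            logger.warning("predictor %s all-missing; excluded from screen", spec.name)
            continue
        x = df.loc[mask, spec.name].to_numpy(dtype=float)
        y = y_all[mask].to_numpy(dtype=float)
        fit = fit_logistic(x, y, names=[spec.name])
        beta = fit.coefficients[spec.name]
        se = fit.standard_errors[spec.name]
        if fit.separated or not math.isfinite(beta):
            orr, lo, hi = float("inf"), float("nan"), float("nan")
            significant = True  # separation: association is extreme by definition
        else:
            orr = math.exp(beta)
            lo = math.exp(beta - Z_975 * se)
            hi = math.exp(beta + Z_975 * se)
            significant = not (lo <= 1.0 <= hi)
        carried = significant or spec.forced
        logger.info(
            "screen %-18s OR %.3f [%.3f, %.3f] significant=%s forced=%s carried=%s",
            spec.name, orr, lo, hi, significant, spec.forced, carried,
        )
        results.append(
            UnivariableResult(
                predictor=spec.name,
                odds_ratio=orr,
                ci_low=lo,
                ci_high=hi,
                n=int(mask.sum()),
                significant=significant,
                forced=spec.forced,
                carried_forward=carried,
                separated=fit.separated,
            )
        )
    return results


# --------------------------------------------------------------------------
# step 2: Youden cutpoints
# --------------------------------------------------------------------------


@dataclass
class CutpointResult:
    predictor: str
    direction: str
    raw_cutoff: float
    youden_j: float
    rounded_cutoff: float | None = None
    overridden: bool = False
    final_cutoff: float | None = None


def youden_cutpoint(values, labels, direction: str = "high_is_bad",
                    predictor: str = "") -> CutpointResult:
    """Youden-optimal threshold over midpoints of consecutive distinct values.

    Classification is "severe side positive": value >= t for high_is_bad,
    value < t for low_is_bad.  Ties in J are broken toward the more inclusive
    (less extreme) threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    cases = np.sort(values[labels == 1])
    controls = np.sort(values[labels == 0])
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError("constant predictor: no threshold candidates")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    # P(value >= t): counts strictly below t via searchsorted on sorted arrays
    frac_case_ge = 1.0 - np.searchsorted(cases, candidates, side="left") / len(cases)
    frac_ctrl_ge = 1.0 - np.searchsorted(controls, candidates, side="left") / len(controls)
    if direction == "high_is_bad":
        j = frac_case_ge - frac_ctrl_ge  # sens - (1 - spec)
        order = np.arange(len(candidates))  # lower t = more inclusive
    elif direction == "low_is_bad":
        j = (1.0 - frac_case_ge) - (1.0 - frac_ctrl_ge)
        order = np.arange(len(candidates))[::-1]  # higher t = more inclusive
    else:
        raise ValueError(f"bad direction {direction!r}")
    jo = j[order]
    best = order[int(np.argmax(jo))]  # argmax takes the first = most inclusive
    return CutpointResult(
        predictor=predictor,
        direction=direction,
        raw_cutoff=float(candidates[best]),
        youden_j=float(j[best]),
    )


def round_cutoff(raw: float, is_blood_pressure: bool = False) -> float:
    """Round to the nearest whole number (multiple of 5 for blood pressure);
    halves round away from zero."""
    if not math.isfinite(raw):
        raise ValueError(f"raw cutoff {raw!r} not finite")
    base = 5.0 if is_blood_pressure else 1.0
    q = raw / base
    return math.copysign(math.floor(abs(q) + 0.5), q) * base


def apply_normal_range_override(
    cut: CutpointResult, spec: PredictorSpec
) -> CutpointResult:
    """Replace a rounded cutoff lying inside the clinical normal range with the
    established reference-score cutoff; otherwise keep the rounded value."""
    if cut.rounded_cutoff is None:
        raise ValueError("round the cutoff before applying the override")
    rng = spec.normal_range
    if rng is not None and rng[0] <= cut.rounded_cutoff <= rng[1]:
        if spec.established_cutoff is None:
            raise ValueError(
                f"{cut.predictor}: cutoff {cut.rounded_cutoff} inside normal range "
                f"{rng} but no established cutoff configured"
            )
        logger.info(
            "cutpoint %s: rounded %.6g inside normal range %s -> established %.6g",
            cut.predictor, cut.rounded_cutoff, rng, spec.established_cutoff,
        )
        cut.overridden = True
        cut.final_cutoff = spec.established_cutoff
    else:
        cut.overridden = False
        cut.final_cutoff = cut.rounded_cutoff
    return cut


def dichotomize(df: pd.DataFrame, cut: CutpointResult) -> pd.Series:
    """0/1 severity indicator at the final cutoff (NaN propagates)."""
    if cut.final_cutoff is None:
        raise ValueError("cutpoint not finalized")
    x = df[cut.predictor].astype(float)
    if cut.direction == "high_is_bad":
        ind = (x >= cut.final_cutoff).astype(float)
    else:
        ind = (x < cut.final_cutoff).astype(float)
    ind[x.isna()] = np.nan
    return ind


# --------------------------------------------------------------------------
# step 3: model enumeration and ranking
# --------------------------------------------------------------------------


def enumerate_and_rank_models(
    items: pd.DataFrame,
    y: pd.Series,
    config: DerivationConfig,
) -> tuple[list[ModelFit], ModelFit]:
    """Fit every admissible item combination and pick the final model.

    Admissible: non-empty subsets with at most one item per organ system
    (optionally capped in size).  Ranked by Nagelkerke R^2 descending; among
    models within ``r2_tolerance`` of the best, preference rules decide:
    fewer items first (if configured), then more clinically preferred items,
    then higher R^2.
    """
    by_organ: dict[str, list[str]] = {}
    for name in items.columns:
        by_organ.setdefault(config.spec(name).organ_system, []).append(name)
    options = [[None, *names] for names in by_organ.values()]
    combos: list[tuple[str, ...]] = []
    for pick in itertools.product(*options):
        chosen = tuple(p for p in pick if p is not None)
        if not chosen:
            continue
        if config.max_model_size is not None and len(chosen) > config.max_model_size:
            continue
        combos.append(chosen)
    if not combos:
        raise ValueError("no admissible predictor combination under the constraints")
    fits: list[ModelFit] = []
    for chosen in combos:
        sub = items[list(chosen)]
        mask = sub.notna().all(axis=1) & y.notna()
        fits.append(
            fit_logistic(
                sub[mask].to_numpy(dtype=float),
                y[mask].to_numpy(dtype=float),
                names=list(chosen),
            )
        )
    fits.sort(key=lambda f: f.nagelkerke_r2, reverse=True)
    best_r2 = fits[0].nagelkerke_r2
    tied = [f for f in fits if best_r2 - f.nagelkerke_r2 <= config.r2_tolerance]

    def preference_key(f: ModelFit):
        n_pref = sum(config.spec(p).preferred for p in f.predictors)
        size = len(f.predictors) if config.prefer_fewer_items else 0
        return (size, -n_pref, -f.nagelkerke_r2)

    selected = min(tied, key=preference_key)
    if len(tied) > 1:
        logger.info(
            "model ranking: %d models within R2 tolerance %.3g of best %.4f; "
            "selected %s (R2 %.4f) by preference rules",
            len(tied), config.r2_tolerance, best_r2,
            selected.predictors, selected.nagelkerke_r2,
        )
    return fits, selected


# --------------------------------------------------------------------------
# the full pipeline
# --------------------------------------------------------------------------


@dataclass
class DerivationReport:
    univariable: list[UnivariableResult]
    cutpoints: list[CutpointResult]
    models: list[ModelFit]
    selected: ModelFit
    definition: ScoreDefinition

    def univariable_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": r.predictor,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n": r.n,
                    "significant": r.significant,
                    "forced": r.forced,
                    "carried_forward": r.carried_forward,
                }
                for r in self.univariable
            ]
        )

    def cutpoint_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": c.predictor,
                    "direction": c.direction,
                    "raw_cutoff": c.raw_cutoff,
                    "youden_j": c.youden_j,
                    "rounded_cutoff": c.rounded_cutoff,
                    "overridden": c.overridden,
                    "final_cutoff": c.final_cutoff,
                }
                for c in self.cutpoints
            ]
        )

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "predictors": "+".join(f.predictors),
                    "n_items": len(f.predictors),
                    "nagelkerke_r2": f.nagelkerke_r2,
                    "log_likelihood": f.log_likelihood,
                    "n": f.n,
                    "selected": f is self.selected,
                }
                for i, f in enumerate(self.models)
            ]
        )


def derive_score(df: pd.DataFrame, config: DerivationConfig) -> DerivationReport:
    """Run the three derivation steps on a training frame.

    ``df`` has one row per patient with raw predictor columns and the binary
    outcome column named by ``config.outcome``.
    """
    if len(df) < config.min_n:
        raise ValueError(f"training cohort n={len(df)} below minimum {config.min_n}")
    if config.outcome not in df.columns:
        raise ValueError(f"outcome column {config.outcome!r} missing")
    uni = univariable_screen(df, config)
    carried = [r.predictor for r in uni if r.carried_forward]
    if not carried:
        raise ValueError("no predictor carried forward from the univariable screen")
    y = df[config.outcome].astype(float)
    cutpoints: list[CutpointResult] = []
    items = pd.DataFrame(index=df.index)
    for name in carried:
        spec = config.spec(name)
        mask = df[name].notna() & y.notna()
        cut = youden_cutpoint(
            df.loc[mask, name], y[mask].to_numpy(), spec.direction, predictor=name
        )
        cut.rounded_cutoff = round_cutoff(cut.raw_cutoff, spec.is_blood_pressure)
        cut = apply_normal_range_override(cut, spec)
        logger.info(
            "cutpoint %-18s raw %.4g (J=%.3f) rounded %.4g final %.4g%s",
            name, cut.raw_cutoff, cut.youden_j, cut.rounded_cutoff,
            cut.final_cutoff, " [override]" if cut.overridden else "",
        )
        cutpoints.append(cut)
        items[name] = dichotomize(df, cut)
    models, selected = enumerate_and_rank_models(items, y, config)
    cut_by_name = {c.predictor: c for c in cutpoints}
    band_items = tuple(
        BandItem(
            organ_system=config.spec(name).organ_system,
            variable=name,
            direction="ge" if cut_by_name[name].direction == "high_is_bad" else "lt",
            thresholds=(float(cut_by_name[name].final_cutoff),),
            points=(1,),
        )
        for name in selected.predictors
    )
    definition = ScoreDefinition(
        name=config.score_name,
        items=band_items,
        positivity_delta=config.positivity_delta,
    )
    return DerivationReport(
        univariable=uni,
        cutpoints=cutpoints,
        models=models,
        selected=selected,
        definition=definition,
    )
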