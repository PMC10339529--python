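"""Empirical ROC AUC, DeLong paired-AUC inference, and non-inferiority planning.

The empirical AUC is the Mann-Whitney statistic with ties counted 1/2.  For a
score evaluated on m cases and n controls, each subject carries a structural
component (the fraction of opposite-class subjects it beats); DeLong's
estimator builds the variance of a single AUC, and the covariance of two AUCs
computed on the same subjects, from the sample (co)variances of those
components:

    var(AUC)    = S10/m + S01/n
    cov(A1, A2) = S10_12/m + S01_12/n

The non-inferiority test for a difference d = AUC_a - AUC_b against margin
delta uses the normal approximation z = (d + delta)/se(d); the null
"d < -delta" is rejected when the one-sided p-value is below alpha, which is
algebraically equivalent to the 95 % CI lower bound exceeding -delta (for
alpha = 0.025).

The planner evaluates the same variance model at design-stage assumptions:
component moments come from the exponential ROC model (Hanley's
Q1 = A/(2-A), Q2 = 2A^2/(1+A)), with expected case/control counts
m = prevalence * n_total.  A Monte-Carlo mode simulates paired scores and runs
the actual test as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = [
    "AUCEstimate",
    "AUCComparison",
    "PowerDesign",
    "SampleSizeResult",
    "empirical_auc",
    "delong_cov",
    "compare_aucs",
    "noninferiority_test",
    "power_at_n",
    "monte_carlo_power",
    "solve_sample_size",
    "planned_accrual",
    "reference_design",
]

Z_975 = float(ndtri(0.975))


@dataclass
class AUCEstimate:
    """Empirical AUC with per-subject DeLong components."""

    auc: float
    n_cases: int
    n_controls: int
    case_components: np.ndarray
    control_components: np.ndarray
    variance: float

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Wald CI (not clipped to [0, 1], per the normal approximation)."""
        z = float(ndtri(0.5 + level / 2))
        return self.auc - z * self.se, self.auc + z * self.se


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def empirical_auc(scores, labels) -> AUCEstimate:
    """Mann-Whitney AUC (ties 1/2) with DeLong structural components.

    ``labels`` are binary; 1 marks cases (events).  Raises if only one class
    is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    case_mask = labels == 1
    x = scores[case_mask]  # cases
    y = scores[~case_mask]  # controls
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute an AUC")
    tx = _midrank(x)
    ty = _midrank(y)
    tz = _midrank(np.concatenate([x, y]))
    # fraction of controls each case beats (ties 1/2), and vice versa
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    return AUCEstimate(
        auc=auc,
        n_cases=m,
        n_controls=n,
        case_components=v10,
        control_components=v01,
        variance=variance,
    )


def delong_cov(est_a: AUCEstimate, est_b: AUCEstimate) -> float:
    """DeLong covariance of two AUCs computed on the identical subjects."""
    if est_a.n_cases != est_b.n_cases or est_a.n_controls != est_b.n_controls:
        raise ValueError("paired AUC estimates must share the same subjects/labels")
    m, n = est_a.n_cases, est_a.n_controls
    c10 = (
        float(np.cov(est_a.case_components, est_b.case_components, ddof=1)[0, 1])
        if m > 1
        else 0.0
    )
    c01 = (
        float(np.cov(est_a.control_components, est_b.control_components, ddof=1)[0, 1])
        if n > 1
        else 0.0
    )
    return c10 / m + c01 / n


@dataclass
class AUCComparison:
    """Paired AUC comparison with the one-sided non-inferiority decision."""

    auc_a: AUCEstimate
    auc_b: AUCEstimate
    difference: float
    se_difference: float
    ci_low: float
    ci_high: float
    margin: float
    p_one_sided: float
    non_inferior: bool
    exact_agreement: bool = False


def compare_aucs(
    est_a: AUCEstimate,
    est_b: AUCEstimate,
    margin: float = 0.06,
    alpha_one_sided: float = 0.025,
) -> AUCComparison:
    """Non-inferiority comparison of score a versus score b (paired).

    Rejects inferiority ("AUC_a - AUC_b < -margin") when the one-sided p is
    below alpha; equivalently, when the (1 - 2*alpha) CI lower bound for the
    difference exceeds -margin.
    """
    diff = est_a.auc - est_b.auc
    cov = delong_cov(est_a, est_b)
    var_diff = est_a.variance + est_b.variance - 2 * cov
    se = math.sqrt(max(var_diff, 0.0))
    if se < 1e-7:  # numerically exact agreement of the component vectors
        se = 0.0
    z_ci = float(ndtri(1 - alpha_one_sided))
    if se == 0.0:
        # degenerate: identical (or perfectly coupled) component vectors
        if diff > -margin:
            p = 0.0
        elif diff < -margin:
            p = 1.0
        else:
            p = 0.5  # exactly at the margin: boundary convention
        return AUCComparison(
            auc_a=est_a,
            auc_b=est_b,
            difference=diff,
            se_difference=0.0,
            ci_low=diff,
            ci_high=diff,
            margin=margin,
            p_one_sided=p,
            non_inferior=p < alpha_one_sided,
            exact_agreement=True,
        )
    z = (diff + margin) / se
    p = float(1.0 - ndtr(z))
    ci_low = diff - z_ci * se
    ci_high = diff + z_ci * se
    return AUCComparison(
        auc_a=est_a,
        auc_b=est_b,
        difference=diff,
        se_difference=se,
        ci_low=ci_low,
        ci_high=ci_high,
        margin=margin,
        p_one_sided=p,
        non_inferior=p < alpha_one_sided,
    )


def noninferiority_test(
    scores_a,
    scores_b,
    labels,
    margin: float = 0.06,
    alpha_one_sided: float = 0.025,
) -> AUCComparison:
    """Paired DeLong non-inferiority test from raw scores and shared labels."""
    est_a = empirical_auc(scores_a, labels)
    est_b = empirical_auc(scores_b, labels)
    return compare_aucs(est_a, est_b, margin=margin, alpha_one_sided=alpha_one_sided)


# --------------------------------------------------------------------------
# design-stage power and sample size
# --------------------------------------------------------------------------


@dataclass
class PowerDesign:
    """Assumptions for the non-inferiority power/sample-size planner.

    ``assumed_auc_a`` / ``assumed_auc_b`` are the anticipated AUCs of the new
    and reference score; ``assumed_correlation`` couples their estimators
    (0 = independent).  ``margin`` and the assumed difference
    (auc_a - auc_b) are on the AUC scale; ``outcome_prevalence`` sets the
    expected case fraction.
    """

    assumed_auc_a: float = 0.774
    assumed_auc_b: float = 0.714
    assumed_correlation: float = 0.0
    margin: float = 0.06
    alpha_one_sided: float = 0.025
    target_power: float = 0.80
    outcome_prevalence: float = 0.30

    def __post_init__(self) -> None:
        for name in ("assumed_auc_a", "assumed_auc_b"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name}={a} outside (0, 1)")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ValueError(f"outcome_prevalence={self.outcome_prevalence} outside (0, 1)")
        if not (-1.0 <= self.assumed_correlation <= 1.0):
            raise ValueError("assumed_correlation outside [-1, 1]")


def reference_design() -> PowerDesign:
    """The planner's reference design: reference-score AUC 0.714, assumed
    improvement +0.06, margin 0.06, power 80 %, one-sided alpha 2.5 %,
    30 % outcome prevalence, independent estimators."""
    return PowerDesign()


def _hanley_moments(auc: float) -> tuple[float, float]:
    """Exponential-model component variances: (S10 cases, S01 controls)."""
    q1 = auc / (2.0 - auc)  # two cases share one control
    q2 = 2.0 * auc * auc / (1.0 + auc)  # one case shares two controls
    return q2 - auc * auc, q1 - auc * auc


def _design_se(design: PowerDesign, n: float) -> float:
    """Design-stage SE of the AUC difference at total size n (expected counts)."""
    m = design.outcome_prevalence * n
    nc = n - m
    s10a, s01a = _hanley_moments(design.assumed_auc_a)
    s10b, s01b = _hanley_moments(design.assumed_auc_b)
    var_a = s10a / m + s01a / nc
    var_b = s10b / m + s01b / nc
    r = design.assumed_correlation
    cov = r * (math.sqrt(s10a * s10b) / m + math.sqrt(s01a * s01b) / nc)
    return math.sqrt(max(var_a + var_b - 2 * cov, 0.0))


def power_at_n(design: PowerDesign, n: int | float) -> float:
    """Analytic power of the non-inferiority test at total sample size n."""
    if design.outcome_prevalence * n < 5:
        raise ValueError("design requires at least 5 expected cases (n * prevalence >= 5)")
    diff = design.assumed_auc_a - design.assumed_auc_b
    se = _design_se(design, float(n))
    z_alpha = float(ndtri(1 - design.alpha_one_sided))
    return float(ndtr((diff + design.margin) / se - z_alpha))


def monte_carlo_power(
    design: PowerDesign,
    n: int,
    reps: int = 2000,
    rng: np.random.Generator | int | None = None,
    model: str = "exponential",
) -> float:
    """Monte-Carlo power: simulate paired scores, run the actual test.

    ``model`` "exponential" draws scores from the exponential ROC model (the
    same model behind the analytic component moments); "binormal" draws from
    the equal-variance binormal model.  Correlation between the two scores is
    induced through a Gaussian copula on the latent subject scale.
    """
    rng = np.random.default_rng(rng)
    m = int(round(design.outcome_prevalence * n))
    nc = n - m
    if m < 2 or nc < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    r = design.assumed_correlation
    rejections = 0
    for _ in range(reps):
        z1 = rng.standard_normal(n)
        z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
        scores = []
        for zk, auc in ((z1, design.assumed_auc_a), (z2, design.assumed_auc_b)):
            if model == "binormal":
                mu = math.sqrt(2.0) * float(ndtri(auc))
                s = zk.copy()
                s[:m] += mu
            elif model == "exponential":
                u = ndtr(zk)
                e = -np.log1p(-np.clip(u, 0.0, 1.0 - 1e-15))
                b = (1.0 - auc) / auc  # case-rate ratio giving P(case > control) = auc
                s = e.copy()
                s[:m] = e[:m] / b
            else:
                raise ValueError(f"unknown model {model!r}")
            scores.append(s)
        labels = np.zeros(n, dtype=int)
        labels[:m] = 1
        cmp = noninferiority_test(
            scores[0], scores[1], labels,
            margin=design.margin, alpha_one_sided=design.alpha_one_sided,
        )
        rejections += cmp.non_inferior
    return rejections / reps


@dataclass
class SampleSizeResult:
    n: int
    achieved_power: float
    design: PowerDesign


def solve_sample_size(design: PowerDesign, n_max: int = 10_000_000) -> SampleSizeResult:
    """Smallest total n whose analytic power reaches the target.

    Raises when the design is unachievable (assumed difference at or below
    the negative margin, where power can never exceed alpha).
    """
    diff = design.assumed_auc_a - design.assumed_auc_b
    if diff <= -design.margin and design.target_power > design.alpha_one_sided:
        raise ValueError(
            "unachievable design: assumed difference "
            f"{diff:+.4f} does not exceed -margin {-design.margin:+.4f}"
        )
    lo = max(10, math.ceil(5.0 / design.outcome_prevalence))
    if power_at_n(design, lo) >= design.target_power:
        return SampleSizeResult(lo, power_at_n(design, lo), design)
    hi = lo
    while power_at_n(design, hi) < design.target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"no n <= {n_max} reaches the target power")
    # power is monotone increasing in n (continuous expected counts)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at_n(design, mid) >= design.target_power:
            hi = mid
        else:
            lo = mid
    return SampleSizeResult(hi, power_at_n(design, hi), design)


def planned_accrual(
    patients_per_year: float = 950,
    years: float = 1.5,
    infection_rate: float = 0.30,
) -> int:
    """Expected accrual of infected stroke patients over the enrolment window."""
    return int(round(patients_per_year * years * infection_rate))
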