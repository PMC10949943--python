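"""Evaluation machinery for prognostic scores against observed survival.

Three tools mirror how point-based survival scores are validated in the
spine-oncology literature:

* **per-category prediction accuracy** — each prognosis band makes a
  survival claim (low: death before 6 months; moderate: survival >= 6
  months; good: survival >= 12 months) and is graded against the observed
  times, with a configurable policy for records censored before their
  band's threshold;
* a **Kaplan-Meier product-limit estimator** per prognosis band;
* **ordinary-least-squares regression** of observed survival on the score,
  reporting the slope, intercept, R^2 and a 95% confidence band for the
  conditional mean, used to compare the base score against the combined one.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import PrognosisCategory, ScoreValidationError

#: Survival-month threshold tested for each prognosis band; the low band
#: predicts death *before* its threshold, the others survival *past* theirs.
CATEGORY_THRESHOLDS: dict[PrognosisCategory, float] = {
    PrognosisCategory.LOW: 6.0,
    PrognosisCategory.MODERATE: 6.0,
    PrognosisCategory.GOOD: 12.0,
}


class CensorPolicy(enum.Enum):
    """How a record censored before its band's threshold enters the accuracy count.

    ``EXCLUDE`` drops it from numerator and denominator (the outcome is
    unknowable); the alternatives count it as accurate or inaccurate.
    Records censored at or after the threshold always count as having
    survived past it.
    """

    EXCLUDE = "exclude"
    COUNT_AS_ACCURATE = "count_as_accurate"
    COUNT_AS_INACCURATE = "count_as_inaccurate"


@dataclass(frozen=True)
class CategoryAccuracy:
    category: str
    n_patients: int
    n_accurate: int

    @property
    def accuracy_percent(self) -> float:
        if self.n_patients == 0:
            return float("nan")
        return 100.0 * self.n_accurate / self.n_patients


def _accuracy_outcome(
    category: PrognosisCategory, time_months: float, event: bool
) -> bool | None:
    """True/False if the band's prediction is decidable, None if censored short."""
    threshold = CATEGORY_THRESHOLDS[category]
    survived_past = time_months >= threshold
    if category is PrognosisCategory.LOW:
        if event and not survived_past:
            return True  # died before 6 months, as predicted
        if survived_past:
            return False
        return None
    if survived_past:
        return True
    if event:
        return False
    return None


def category_accuracy(
    df: pd.DataFrame,
    *,
    category_col: str = "prognosis_category",
    time_col: str = "survival_months",
    event_col: str = "event",
    censor_policy: CensorPolicy = CensorPolicy.EXCLUDE,
) -> list[CategoryAccuracy]:
    """Grade each prognosis band's survival prediction against observed times.

    Every row must carry a category, a follow-up time and an event flag.
    Bands are returned in low/moderate/good order; a band with no patients
    appears with zero counts.
    """
    for col in (category_col, time_col, event_col):
        if col not in df.columns:
            raise ScoreValidationError(f"column {col!r} missing from scored records")
    if df[time_col].isna().any() or df[event_col].isna().any():
        raise ScoreValidationError("every record needs a survival time and event flag")

    results = []
    for category in PrognosisCategory:
        sub = df[df[category_col] == category.value]
        n, accurate = 0, 0
        for time_months, event in zip(sub[time_col], sub[event_col]):
            outcome = _accuracy_outcome(category, float(time_months), bool(event))
            if outcome is None:
                if censor_policy is CensorPolicy.EXCLUDE:
                    continue
                outcome = censor_policy is CensorPolicy.COUNT_AS_ACCURATE
            n += 1
            accurate += int(outcome)
        results.append(
            CategoryAccuracy(category=category.value, n_patients=n, n_accurate=accurate)
        )
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate: step values at the distinct event times."""

    times: np.ndarray       # distinct event times, increasing
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # risk-set size just before each event time
    n_deaths: np.ndarray    # deaths at each event time
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def kaplan_meier(
    times: np.ndarray | list[float],
    events: np.ndarray | list[bool],
    groups: np.ndarray | list | None = None,
) -> KMEstimate | dict[object, KMEstimate]:
    """Product-limit estimator; with ``groups`` given, one estimate per label.

    At each distinct death time t the survival multiplies by (1 - d_t/n_t);
    censored times shrink the risk set without a step (ties between deaths
    and censorings at the same time keep the censored subjects at risk for
    that death time, the standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ScoreValidationError("times and events must have equal length")
    if np.any(times < 0):
        raise ScoreValidationError("survival times must be non-negative")
    if groups is not None:
        groups = np.asarray(groups)
        return {
            label: _km_single(times[groups == label], events[groups == label])
            for label in pd.unique(groups)
        }
    return _km_single(times, events)


def _km_single(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    n = len(times)
    if n == 0:
        warnings.warn("empty group passed to kaplan_meier; returning empty estimate")
        empty = np.array([])
        return KMEstimate(empty, empty, empty, empty, 0)
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=float)
    deaths = np.array([((times == t) & events).sum() for t in event_times], dtype=float)
    survival = np.cumprod(1.0 - deaths / at_risk) if len(event_times) else np.array([])
    return KMEstimate(event_times, survival, at_risk, deaths, n)


# ---------------------------------------------------------------------------
# Score-vs-survival regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    """A least-squares line of survival on score with its 95% mean-response band."""

    slope: float
    intercept: float
    r_squared: float
    confidence_band: pd.DataFrame  # columns: score, fit, lower, upper
    n: int


def ols_score_regression(
    scores: np.ndarray | list[int],
    survival_months: np.ndarray | list[float],
    *,
    prediction_interval: bool = False,
) -> RegressionFit:
    """Regress observed survival on the score by ordinary least squares.

    The band covers the conditional mean response at each distinct score
    value (95%); set ``prediction_interval`` for the wider per-observation
    interval instead. Observed times enter regardless of event status.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(survival_months, dtype=float)
    if x.shape != y.shape:
        raise ScoreValidationError("scores and survival_months must have equal length")
    if len(np.unique(x)) < 3:
        raise ScoreValidationError(
            "need at least 3 distinct score values for a meaningful fit"
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.unique(x)
    pred = model.get_prediction(sm.add_constant(grid))
    summary = pred.summary_frame(alpha=0.05)
    lo_col, hi_col = (
        ("obs_ci_lower", "obs_ci_upper")
        if prediction_interval
        else ("mean_ci_lower", "mean_ci_upper")
    )
    band = pd.DataFrame(
        {
            "score": grid,
            "fit": summary["mean"].to_numpy(),
            "lower": summary[lo_col].to_numpy(),
            "upper": summary[hi_col].to_numpy(),
        }
    )
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        confidence_band=band,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Score comparison and full report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreComparison:
    """Base-score vs combined-score fits and side-by-side accuracy tables."""

    rts_fit: RegressionFit
    combined_fit: RegressionFit
    r_squared_difference: float  # combined minus base
    rts_accuracy: list[CategoryAccuracy]
    combined_accuracy: list[CategoryAccuracy]


def compare_scores(
    df: pd.DataFrame,
    *,
    censor_policy: CensorPolicy = CensorPolicy.EXCLUDE,
) -> ScoreComparison:
    """Fit survival on both scores and tabulate both category accuracies.

    Expects the scored-cohort columns ``rts_total``, ``combined_score``,
    ``rts_category``, ``prognosis_category``, ``survival_months``, ``event``.
    """
    if len(df) == 0:
        raise ScoreValidationError("empty cohort")
    for col in ("rts_total", "combined_score", "survival_months", "event"):
        if col not in df.columns:
            raise ScoreValidationError(f"column {col!r} missing from scored records")
    rts_fit = ols_score_regression(df["rts_total"], df["survival_months"])
    combined_fit = ols_score_regression(df["combined_score"], df["survival_months"])
    return ScoreComparison(
        rts_fit=rts_fit,
        combined_fit=combined_fit,
        r_squared_difference=combined_fit.r_squared - rts_fit.r_squared,
        rts_accuracy=category_accuracy(
            df, category_col="rts_category", censor_policy=censor_policy
        ),
        combined_accuracy=category_accuracy(df, censor_policy=censor_policy),
    )


@dataclass
class ValidationReport:
    """Everything a score-validation run produces, serialisable to JSON/CSV."""

    n_patients: int
    accuracy_by_policy: dict[str, list[CategoryAccuracy]]
    km_by_category: dict[str, KMEstimate]
    comparison: ScoreComparison
    censor_policy: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def acc_rows(rows: list[CategoryAccuracy]) -> list[dict]:
            return [
                {
                    "category": r.category,
                    "n_patients": r.n_patients,
                    "n_accurate": r.n_accurate,
                    "accuracy_percent": None
                    if math.isnan(r.accuracy_percent)
                    else r.accuracy_percent,
                    "accuracy_percent_1dp": None
                    if math.isnan(r.accuracy_percent)
                    else round(r.accuracy_percent, 1),
                    "accuracy_percent_2dp": None
                    if math.isnan(r.accuracy_percent)
                    else round(r.accuracy_percent, 2),
                }
                for r in rows
            ]

        def fit_dict(fit: RegressionFit) -> dict:
            return {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
                "confidence_band": fit.confidence_band.to_dict(orient="list"),
            }

        return {
            "n_patients": self.n_patients,
            "censor_policy": self.censor_policy,
            "accuracy_by_policy": {
                policy: acc_rows(rows)
                for policy, rows in self.accuracy_by_policy.items()
            },
            "kaplan_meier": {
                category: {
                    "times": est.times.tolist(),
                    "survival": est.survival.tolist(),
                    "at_risk": est.at_risk.tolist(),
                    "n_deaths": est.n_deaths.tolist(),
                    "n_total": est.n_total,
                }
                for category, est in self.km_by_category.items()
            },
            "regression": {
                "rts": fit_dict(self.comparison.rts_fit),
                "combined": fit_dict(self.comparison.combined_fit),
                "r_squared_difference": self.comparison.r_squared_difference,
            },
            "rts_accuracy": acc_rows(self.comparison.rts_accuracy),
            "config": self.config,
        }


def validate_cohort(
    df: pd.DataFrame,
    *,
    censor_policy: CensorPolicy = CensorPolicy.EXCLUDE,
    config: dict | None = None,
) -> ValidationReport:
    """Run the full evaluation of a scored cohort with survival outcomes.

    Produces the combined-score accuracy table under all censoring policies,
    Kaplan-Meier estimates per combined-score prognosis band, and the
    base-vs-combined regression comparison.
    """
    comparison = compare_scores(df, censor_policy=censor_policy)
    accuracy_by_policy = {
        policy.value: category_accuracy(df, censor_policy=policy)
        for policy in CensorPolicy
    }
    km = {}
    for category in PrognosisCategory:
        sub = df[df["prognosis_category"] == category.value]
        if len(sub):
            km[category.value] = kaplan_meier(
                sub["survival_months"].to_numpy(), sub["event"].to_numpy(dtype=bool)
            )
    return ValidationReport(
        n_patients=len(df),
        accuracy_by_policy=accuracy_by_policy,
        km_by_category=km,
        comparison=comparison,
        censor_policy=censor_policy.value,
        config=config or {},
    )
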