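"""Scoring engine for the Seven-in-Seven screen exposure questionnaire.

Each of the seven items is mapped to a small integer score; the scores sum
into three subscales — screen exposure *rules* (daily time, co-viewing,
limits), screen exposure during daily *routines* (meals, bedtime), and
screen exposure *conditions* (onset age, content quality) — and a total
problematic screen exposure (PSE) score on 0–13.  Children at or above a
cutoff (default 7, the 85th percentile of the development sample) are
classed as *high* PSE.

Item scoring rubric
-------------------
===================  =========================================  =====
Item                 Levels                                     Score
===================  =========================================  =====
Daily screen time    < 1 h / 1–2 h / > 2 h                      0/1/2
Viewing with parent  always / sometimes / rarely ever           0/1/2
Setting limits       set & obeyed / not set / set, not obeyed   0/1/2
During meals         no / yes                                   0/1
Hour before bedtime  no / yes                                   0/1
Age of onset         ≥24 / 18–23 / 12–17 / <12 months           0–3
Low-quality content  none / 1 kind / ≥2 kinds                   0/1/2
===================  =========================================  =====

Boundary conventions: an average daily time of exactly 1 h or 2 h scores 1
(closed middle bin); an onset at exactly 24 completed months scores 0; the
cutoff comparison is inclusive (total ≥ cutoff ⇒ high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticalError, ValidationError
from .survey import QuestionnaireResponse, ScreenTimeReport, SurveyRecord

ITEM_NAMES = (
    "s_time",
    "s_coview",
    "s_limits",
    "s_meals",
    "s_bedtime",
    "s_onset",
    "s_content",
)

ITEM_MAX = {
    "s_time": 2,
    "s_coview": 2,
    "s_limits": 2,
    "s_meals": 1,
    "s_bedtime": 1,
    "s_onset": 3,
    "s_content": 2,
}

_COVIEW_SCORE = {"always": 0, "sometimes": 1, "rarely_ever": 2}
_LIMITS_SCORE = {"set_and_obeyed": 0, "not_set": 1, "set_not_obeyed": 2}

DEFAULT_CUTOFF = 7


@dataclass(frozen=True)
class ItemScores:
    """Rubric scores of the seven items."""

    s_time: int
    s_coview: int
    s_limits: int
    s_meals: int
    s_bedtime: int
    s_onset: int
    s_content: int

    def __post_init__(self) -> None:
        for name in ITEM_NAMES:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or not 0 <= v <= ITEM_MAX[name]:
                raise ValidationError(
                    f"{name}={v!r} outside its range 0..{ITEM_MAX[name]}"
                )

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, n) for n in ITEM_NAMES)


@dataclass(frozen=True)
class PseResult:
    """Subscale scores, total PSE score, and the low/high classification."""

    rules_score: int
    routines_score: int
    conditions_score: int
    total: int
    pse_class: str  # "low" | "high"
    cutoff_used: int


def average_daily_screen_time(report: ScreenTimeReport) -> float:
    """Weekly-weighted mean screen hours per day:
    [(tv_wd + other_wd) * 5 + (tv_we + other_we) * 2] / 7."""
    tv_wd, other_wd, tv_we, other_we = report.as_tuple()
    for v in report.as_tuple():
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"screen time hours must be >= 0, got {v!r}")
    return ((tv_wd + other_wd) * 5 + (tv_we + other_we) * 2) / 7


def _score_time(avg_hours: float) -> int:
    if avg_hours < 1:
        return 0
    if avg_hours <= 2:
        return 1
    return 2


def _score_onset(months: int) -> int:
    if months >= 24:
        return 0
    if months >= 18:
        return 1
    if months >= 12:
        return 2
    return 3


def _score_content(kinds: int) -> int:
    return min(int(kinds), 2)


def score_items(response: QuestionnaireResponse) -> ItemScores:
    """Apply the rubric to one raw questionnaire response."""
    avg = average_daily_screen_time(response.screen_time)
    try:
        s_coview = _COVIEW_SCORE[response.co_viewing]
        s_limits = _LIMITS_SCORE[response.limits]
    except KeyError as exc:
        raise ValidationError(f"unknown enumeration level {exc.args[0]!r}") from exc
    if response.onset_age_months < 0:
        raise ValidationError("onset_age_months must be >= 0")
    if response.inappropriate_content_kinds < 0:
        raise ValidationError("inappropriate_content_kinds must be >= 0")
    return ItemScores(
        s_time=_score_time(avg),
        s_coview=s_coview,
        s_limits=s_limits,
        s_meals=1 if response.meals_use == "yes" else 0,
        s_bedtime=1 if response.bedtime_use == "yes" else 0,
        s_onset=_score_onset(response.onset_age_months),
        s_content=_score_content(response.inappropriate_content_kinds),
    )


def total_pse(scores: ItemScores, cutoff: int = DEFAULT_CUTOFF) -> PseResult:
    """Subscales, total (0–13), and low/high class at the given cutoff."""
    if not 0 <= cutoff <= 13:
        raise ValidationError(f"cutoff {cutoff} outside [0, 13]")
    rules = scores.s_time + scores.s_coview + scores.s_limits
    routines = scores.s_meals + scores.s_bedtime
    conditions = scores.s_onset + scores.s_content
    total = rules + routines + conditions
    return PseResult(
        rules_score=rules,
        routines_score=routines,
        conditions_score=conditions,
        total=total,
        pse_class="high" if total >= cutoff else "low",
        cutoff_used=cutoff,
    )


def score_record(record: SurveyRecord, cutoff: int = DEFAULT_CUTOFF) -> PseResult:
    return total_pse(score_items(record.response), cutoff=cutoff)


def score_cohort(
    records: Sequence[SurveyRecord], cutoff: int = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Score every record; one row per child with item scores, subscales,
    total, and class."""
    rows = []
    for rec in records:
        items = score_items(rec.response)
        res = total_pse(items, cutoff=cutoff)
        row = dict(zip(ITEM_NAMES, items.as_tuple()))
        row.update(
            rules_score=res.rules_score,
            routines_score=res.routines_score,
            conditions_score=res.conditions_score,
            total=res.total,
            pse_class=res.pse_class,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ITEM_NAMES) + [
        "rules_score", "routines_score", "conditions_score", "total", "pse_class",
    ])


def derive_cutoff(totals: Sequence[int], percentile: float = 85.0) -> int:
    """Nearest-rank percentile: the value at rank ceil(p/100 * n) of the
    sorted totals."""
    totals = np.asarray(list(totals))
    if totals.size == 0:
        raise ValidationError("cannot derive a cutoff from an empty collection")
    if not 0 < percentile < 100:
        raise ValidationError(f"percentile {percentile} outside (0, 100)")
    rank = math.ceil(percentile / 100 * totals.size)
    return int(np.sort(totals)[rank - 1])


@dataclass(frozen=True)
class DistributionSummary:
    """Location, spread, shape, and a normality check of a score sample.

    Quartiles are nearest-rank order statistics.  The Kolmogorov–Smirnov
    statistic is the Lilliefors variant (normal with mean and sd estimated
    from the sample).  ``degenerate`` flags a constant sample, for which the
    shape statistics and the normality test are undefined (NaN).
    """

    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    ks_statistic: float
    ks_p: float
    degenerate: bool


def distribution_summary(totals: Sequence[float]) -> DistributionSummary:
    """Summarise a sample of total scores (n >= 4)."""
    x = np.asarray(list(totals), dtype=float)
    if x.size < 4:
        raise StatisticalError("distribution summary needs n >= 4")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return DistributionSummary(
            n=x.size, median=float(x[0]), q1=float(x[0]), q3=float(x[0]),
            mean=float(x[0]), sd=0.0, skewness=float("nan"),
            kurtosis=float("nan"), ks_statistic=float("nan"),
            ks_p=float("nan"), degenerate=True,
        )
    from statsmodels.stats.diagnostic import lilliefors

    ks_stat, ks_p = lilliefors(x, dist="norm")
    srt = np.sort(x)
    q1 = srt[math.ceil(0.25 * x.size) - 1]
    q3 = srt[math.ceil(0.75 * x.size) - 1]
    return DistributionSummary(
        n=int(x.size),
        median=float(np.median(x)),
        q1=float(q1),
        q3=float(q3),
        mean=float(np.mean(x)),
        sd=sd,
        skewness=float(stats.skew(x, bias=False)),
        kurtosis=float(stats.kurtosis(x, bias=False)),
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        degenerate=False,
    )


def enumerate_rubric_totals() -> np.ndarray:
    """Total for every combination of the rubric (3*3*3*2*2*4*3 = 1296)."""
    grids = np.meshgrid(*[np.arange(ITEM_MAX[n] + 1) for n in ITEM_NAMES],
                        indexing="ij")
    return np.stack([g.ravel() for g in grids]).sum(axis=0)
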