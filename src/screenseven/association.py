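"""Covariate–outcome association analysis.

Contingency tables of covariate level x PSE class, Pearson chi-square
tests, crude odds ratios with Woolf (log-method) 95% confidence
intervals, pairwise subgroup letter labels, and the multivariable
logistic model yielding adjusted odds ratios.

Conventions: no continuity correction in the chi-square (a flag restores
it); Haldane–Anscombe +0.5 on all four cells of a 2x2 only when a zero
cell occurs; uncorrected pairwise alpha = 0.05 for subgroup letters.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .errors import StatisticalError, ValidationError
from .scoring import DEFAULT_CUTOFF, score_record
from .survey import Codebook, DEFAULT_CODEBOOK, SurveyRecord

Z_975 = 1.959964  # two-sided 95% normal quantile

#: Derived categorical covariates computed from record fields.
_Z_BANDS = ("lt_m2", "m2_to_2", "gt_2", "missing")

DERIVED_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("m24_48", "m49_72"),
    "wfh_band": _Z_BANDS,
    "hfa_band": _Z_BANDS,
    "wfa_band": _Z_BANDS,
}

DERIVED_REFERENCE = {
    "age_group": "m24_48",
    "wfh_band": "lt_m2",
    "hfa_band": "lt_m2",
    "wfa_band": "lt_m2",
}

#: Covariates entering the adjusted logistic model (anthropometric bands
#: are analysed crudely only).
ADJUSTED_COVARIATES: tuple[str, ...] = (
    "maternal_age_band",
    "paternal_age_band",
    "maternal_education_band",
    "paternal_education_band",
    "maternal_occupation",
    "income",
    "family_type",
    "family_size_band",
    "settlement",
    "province",
    "age_group",
    "sex",
    "daycare",
    "n_siblings_band",
    "postponing_needs",
    "own_devices_band",
    "uses_touchscreen",
    "video_gaming_band",
)

#: Covariates of the descriptive (crude) table, in report order.
TABLE_COVARIATES: tuple[str, ...] = ADJUSTED_COVARIATES + (
    "wfh_band",
    "hfa_band",
    "wfa_band",
)


def _z_band(z: float | None) -> str:
    if z is None:
        return "missing"
    if z < -2.0:
        return "lt_m2"
    if z <= 2.0:
        return "m2_to_2"
    return "gt_2"


def covariate_value(record: SurveyRecord, name: str) -> str:
    """The level label of a (possibly derived) categorical covariate."""
    if name == "age_group":
        return "m24_48" if record.child_age_months <= 48 else "m49_72"
    if name == "wfh_band":
        return _z_band(record.wfh_z)
    if name == "hfa_band":
        return _z_band(record.hfa_z)
    if name == "wfa_band":
        return _z_band(record.wfa_z)
    if hasattr(record, name):
        return getattr(record, name)
    raise ValidationError(f"unknown covariate field {name!r}")


def covariate_levels(name: str, codebook: Codebook = DEFAULT_CODEBOOK) -> tuple[str, ...]:
    if name in DERIVED_LEVELS:
        return DERIVED_LEVELS[name]
    if name in codebook.levels:
        return codebook.levels[name]
    raise ValidationError(f"unknown covariate field {name!r}")


def covariate_reference(name: str, codebook: Codebook = DEFAULT_CODEBOOK) -> str:
    if name in DERIVED_REFERENCE:
        return DERIVED_REFERENCE[name]
    return codebook.reference[name]


@dataclass
class ContingencyTable:
    """Counts of covariate level x PSE class (columns: low, high)."""

    covariate: str
    levels: tuple[str, ...]
    counts: np.ndarray  # shape (n_levels, 2), columns (low, high)
    reference: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.levels), 2):
            raise ValidationError("counts shape must be (n_levels, 2)")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.reference not in self.levels:
            raise ValidationError(
                f"reference {self.reference!r} not among levels"
            )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def level_counts(self, level: str) -> tuple[int, int]:
        """(low, high) counts at a level."""
        i = self.levels.index(level)
        return int(self.counts[i, 0]), int(self.counts[i, 1])

    def column_pct(self) -> dict[str, float]:
        """Share of the sample at each level (the N (%) column)."""
        tot = self.counts.sum()
        return {
            lv: 100.0 * self.counts[i].sum() / tot
            for i, lv in enumerate(self.levels)
        }

    def row_pct_high(self) -> dict[str, float]:
        """High-PSE share within each level (the row % column)."""
        out = {}
        for i, lv in enumerate(self.levels):
            row = self.counts[i].sum()
            out[lv] = 100.0 * self.counts[i, 1] / row if row else float("nan")
        return out


def crosstab(
    records: Sequence[SurveyRecord],
    covariate: str,
    cutoff: int = DEFAULT_CUTOFF,
    codebook: Codebook = DEFAULT_CODEBOOK,
) -> ContingencyTable:
    """Cross-tabulate a covariate against the low/high PSE class."""
    levels = covariate_levels(covariate, codebook)
    idx = {lv: i for i, lv in enumerate(levels)}
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    for rec in records:
        lv = covariate_value(rec, covariate)
        cls = score_record(rec, cutoff=cutoff).pse_class
        counts[idx[lv], 1 if cls == "high" else 0] += 1
    return ContingencyTable(
        covariate=covariate,
        levels=tuple(levels),
        counts=counts,
        reference=covariate_reference(covariate, codebook),
    )


def chi_square(
    table: ContingencyTable | np.ndarray, corrected: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on the R x C counts; returns (chi2, df, p)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        raise StatisticalError("chi-square needs at least 2 non-empty levels")
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise StatisticalError("chi-square undefined: an expected cell is 0")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=corrected)
    return float(chi2), int(df), float(p)


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio of being high-PSE at a level versus the reference."""

    covariate: str
    level: str
    reference: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    cells: tuple[float, float, float, float]  # (a, b, c, d) after correction
    corrected: bool  # Haldane–Anscombe +0.5 applied


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, ci_level: float = 0.95
) -> tuple[float, float, float, tuple[float, float, float, float], bool]:
    """OR = (a/b)/(c/d) with the Woolf log-method CI.

    a,b = high,low counts at the exposure level; c,d = high,low at the
    reference.  A zero cell triggers the Haldane–Anscombe +0.5 correction
    on all four cells.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("cell counts must be non-negative")
    if a == 0 and c == 0:
        raise StatisticalError("odds ratio undefined: no events in either group")
    if b == 0 and d == 0:
        raise StatisticalError("odds ratio undefined: no non-events in either group")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, lo, hi, (a, b, c, d), corrected


def crude_or(
    table: ContingencyTable, level: str, ci_level: float = 0.95
) -> OrEstimate:
    """Crude odds ratio of a level against the table's reference level."""
    if level == table.reference:
        raise ValidationError("level must differ from the reference")
    b, a = table.level_counts(level)  # (low, high)
    d, c = table.level_counts(table.reference)
    or_, lo, hi, cells, corrected = odds_ratio_2x2(a, b, c, d, ci_level)
    return OrEstimate(
        covariate=table.covariate,
        level=level,
        reference=table.reference,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        cells=cells,
        corrected=corrected,
    )


def reconstruct_counts(n: int, pct: float) -> int:
    """Nearest integer to n * pct/100, ties rounded half-up.

    Used to rebuild cell counts from a printed (N, %) pair.
    """
    if not 0 <= pct <= 100:
        raise ValidationError(f"percentage {pct} outside [0, 100]")
    return int(math.floor(n * pct / 100 + 0.5))


def table_from_margins(
    covariate: str,
    margins: dict[str, tuple[int, float]],
    reference: str,
) -> ContingencyTable:
    """Build a contingency table from printed (N, high-PSE row %) margins."""
    levels = tuple(margins)
    counts = np.zeros((len(levels), 2), dtype=np.int64)
    for i, (lv, (n, high_pct)) in enumerate(margins.items()):
        high = reconstruct_counts(n, high_pct)
        counts[i] = (n - high, high)
    return ContingencyTable(
        covariate=covariate, levels=levels, counts=counts, reference=reference
    )


def pairwise_subgroup_labels(
    table: ContingencyTable, alpha: float = 0.05
) -> dict[str, str]:
    """Letter labels: levels whose high-PSE shares do not differ at the
    given alpha (pairwise uncorrected 2x2 chi-square) share a letter.

    Levels are processed in table order; existing letters are tried
    newest-first so a level joins the most recently formed group it is
    compatible with; a level incompatible with every group opens a new
    letter.  Levels with zero total are excluded with a warning.
    """
    usable = [lv for lv in table.levels if sum(table.level_counts(lv)) > 0]
    if len(usable) < len(table.levels):
        warnings.warn("levels with zero total excluded from subgroup labels",
                      stacklevel=2)
    if len(usable) < 3:
        raise ValidationError("subgroup labelling needs at least 3 levels")

    def differs(lv1: str, lv2: str) -> bool:
        b1, a1 = table.level_counts(lv1)
        b2, a2 = table.level_counts(lv2)
        try:
            _, _, p = chi_square(np.array([[b1, a1], [b2, a2]]))
        except StatisticalError:
            return False  # degenerate 2x2: no evidence of a difference
        return p < alpha

    groups: list[list[str]] = []  # newest last
    labels: dict[str, str] = {}
    for lv in usable:
        placed = False
        for grp in reversed(groups):
            if not any(differs(lv, member) for member in grp):
                grp.append(lv)
                placed = True
                break
        if not placed:
            groups.append([lv])
    for letter, grp in zip(string.ascii_lowercase, groups):
        for member in grp:
            labels[member] = letter
    return labels


@dataclass
class AdjustedModelResult:
    """Adjusted odds ratios from the multivariable logistic model."""

    estimates: pd.DataFrame  # columns: covariate, level, aor, ci_low, ci_high, reference(bool)
    converged: bool
    n_used: int
    n_events: int
    n_params: int

    def aor(self, covariate: str, level: str) -> tuple[float, float, float]:
        m = self.estimates
        row = m[(m.covariate == covariate) & (m.level == level)]
        if row.empty:
            raise KeyError((covariate, level))
        r = row.iloc[0]
        return float(r.aor), float(r.ci_low), float(r.ci_high)


def fit_adjusted_model(
    records: Sequence[SurveyRecord],
    cutoff: int = DEFAULT_CUTOFF,
    covariates: Sequence[str] = ADJUSTED_COVARIATES,
    codebook: Codebook = DEFAULT_CODEBOOK,
    ci_level: float = 0.95,
) -> AdjustedModelResult:
    """Multiple logistic regression of high PSE on dummy-coded covariates.

    Reference levels are dropped from the design matrix; adjusted ORs are
    exp(coefficient) with Wald confidence intervals.  Fitting is by
    iteratively reweighted least squares (Newton scoring) to an absolute
    score tolerance of 1e-8, at most 100 iterations.
    """
    if not records:
        raise ValidationError("no records to fit")
    y = np.array(
        [1 if score_record(r, cutoff=cutoff).pse_class == "high" else 0
         for r in records], dtype=float,
    )
    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str]] = []
    for cov in covariates:
        levels = covariate_levels(cov, codebook)
        ref = covariate_reference(cov, codebook)
        values = np.array([covariate_value(r, cov) for r in records])
        for lv in levels:
            if lv == ref:
                continue
            cols[f"{cov}[{lv}]"] = (values == lv).astype(float)
            meta.append((cov, lv))
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)

    n_events = int(y.sum())
    n_params = X.shape[1]
    epp = min(n_events, len(y) - n_events) / max(n_params - 1, 1)
    if epp < 10:
        warnings.warn(
            f"only {epp:.1f} events per parameter (< 10); estimates may be "
            "unstable", stacklevel=2,
        )

    # screen for separation: outcome constant within a dummy level drives
    # that coefficient to +/- infinity
    for name in X.columns[1:]:
        x = X[name].to_numpy()
        if x.var() == 0:
            raise StatisticalError(f"covariate column {name} is constant")
        events = ((x == 1) & (y == 1)).sum()
        nonevents = ((x == 1) & (y == 0)).sum()
        if events == 0 or nonevents == 0:
            raise StatisticalError(
                f"complete or quasi-complete separation on {name}"
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise StatisticalError(f"logistic fit failed: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))

    conf = fit.conf_int(alpha=1 - ci_level)
    rows = []
    for cov in covariates:
        ref = covariate_reference(cov, codebook)
        for lv in covariate_levels(cov, codebook):
            if lv == ref:
                rows.append(dict(covariate=cov, level=lv, aor=1.0,
                                 ci_low=np.nan, ci_high=np.nan, reference=True))
            else:
                name = f"{cov}[{lv}]"
                rows.append(dict(
                    covariate=cov, level=lv,
                    aor=float(np.exp(fit.params[name])),
                    ci_low=float(np.exp(conf.loc[name, 0])),
                    ci_high=float(np.exp(conf.loc[name, 1])),
                    reference=False,
                ))
    return AdjustedModelResult(
        estimates=pd.DataFrame(rows),
        converged=converged,
        n_used=len(y),
        n_events=n_events,
        n_params=n_params,
    )
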