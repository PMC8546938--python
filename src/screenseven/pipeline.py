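"""End-to-end pipeline: score -> distribution summary -> psychometrics ->
association table, with a reproducible report bundle on disk."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    TABLE_COVARIATES,
    chi_square,
    crosstab,
    crude_or,
    fit_adjusted_model,
    pairwise_subgroup_labels,
)
from .cohort import default_config, generate_cohort
from .errors import ScreenSevenError, StatisticalError
from .psychometrics import battery_by_age_group, item_matrix
from .scoring import distribution_summary, derive_cutoff, score_cohort
from .survey import SurveyRecord, read_survey, write_survey

log = logging.getLogger("screenseven")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_csv: str | None = None  # None -> simulate
    out_dir: str = "screenseven_report"
    simulate_n: int = 1245
    seed: int = 0
    cutoff: int = 7
    derive_cutoff_pct: float | None = None  # derive instead of fixed cutoff
    percentile: float = 85.0
    alpha: float = 0.05
    ci_level: float = 0.95
    corrected_chi2: bool = False
    n_factors: int | None = None

    def validate(self) -> None:
        from .errors import ValidationError

        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")


def analyze_records(
    records: Sequence[SurveyRecord],
    cutoff: int,
    alpha: float = 0.05,
    ci_level: float = 0.95,
    corrected_chi2: bool = False,
    covariates: Sequence[str] = TABLE_COVARIATES,
    adjusted: bool = True,
) -> pd.DataFrame:
    """One row per covariate level: N (col %), high-PSE row %, chi-square p,
    crude OR (CI), adjusted OR (CI), subgroup letter."""
    adj = None
    if adjusted:
        try:
            adj = fit_adjusted_model(records, cutoff=cutoff, ci_level=ci_level)
        except StatisticalError as exc:
            log.warning("adjusted model unavailable: %s", exc)
    rows = []
    for cov in covariates:
        table = crosstab(records, cov, cutoff=cutoff)
        col_pct = table.column_pct()
        row_pct = table.row_pct_high()
        try:
            _, _, p = chi_square(table, corrected=corrected_chi2)
        except StatisticalError:
            p = float("nan")
        letters: dict[str, str] = {}
        if len([lv for lv in table.levels
                if sum(table.level_counts(lv)) > 0]) >= 3:
            letters = pairwise_subgroup_labels(table, alpha=alpha)
        for lv in table.levels:
            low, high = table.level_counts(lv)
            entry = {
                "covariate": cov,
                "level": lv,
                "n": low + high,
                "col_pct": col_pct[lv],
                "high_pct": row_pct[lv],
                "p": p,
                "reference": lv == table.reference,
                "letter": letters.get(lv, ""),
                "crude_or": 1.0 if lv == table.reference else np.nan,
                "crude_ci_low": np.nan,
                "crude_ci_high": np.nan,
                "adj_or": np.nan,
                "adj_ci_low": np.nan,
                "adj_ci_high": np.nan,
            }
            if lv != table.reference and low + high > 0:
                try:
                    est = crude_or(table, lv, ci_level=ci_level)
                    entry.update(
                        crude_or=est.odds_ratio,
                        crude_ci_low=est.ci_low,
                        crude_ci_high=est.ci_high,
                    )
                except StatisticalError:
                    pass
            if adj is not None:
                try:
                    aor, lo, hi = adj.aor(cov, lv)
                    entry.update(adj_or=aor, adj_ci_low=lo, adj_ci_high=hi)
                except KeyError:
                    pass
            rows.append(entry)
    return pd.DataFrame(rows)


def render_table3(analysis: pd.DataFrame) -> pd.DataFrame:
    """Human-readable association table: percentages to 1 decimal, odds
    ratios to 2 decimals, reference rows printed as 1.00."""
    cols = ["covariate", "level", "N (%)", "high PSE %", "p", "OR (95% CI)",
            "AOR (95% CI)", "subgroup"]
    if analysis.empty:
        return pd.DataFrame(columns=cols)

    def fmt_or(or_, lo, hi, is_ref):
        if is_ref:
            return "1.00"
        if np.isnan(or_):
            return ""
        return f"{or_:.2f} ({lo:.2f}–{hi:.2f})"

    out = pd.DataFrame({
        "covariate": analysis.covariate,
        "level": analysis.level,
        "N (%)": [f"{n} ({c:.1f})" for n, c in zip(analysis.n, analysis.col_pct)],
        "high PSE %": [("" if np.isnan(v) else f"{v:.1f}")
                       for v in analysis.high_pct],
        "p": [("" if np.isnan(v) else f"{v:.3f}") for v in analysis.p],
        "OR (95% CI)": [
            fmt_or(o, lo, hi, r) for o, lo, hi, r in zip(
                analysis.crude_or, analysis.crude_ci_low,
                analysis.crude_ci_high, analysis.reference)
        ],
        "AOR (95% CI)": [
            ("1.00" if r and not np.isnan(o) else fmt_or(o, lo, hi, False))
            for o, lo, hi, r in zip(
                analysis.adj_or, analysis.adj_ci_low, analysis.adj_ci_high,
                analysis.reference)
        ],
        "subgroup": analysis.letter,
    }, columns=cols)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the whole pipeline and write the report bundle.

    Outputs in ``config.out_dir``: cohort.csv (if simulated), scores.csv,
    association.csv + association.json, psychometrics.json, run_log.json.
    Any stage failure removes partial outputs and re-raises.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        if config.input_csv is None:
            log.info("simulating default cohort: n=%d seed=%d",
                     config.simulate_n, config.seed)
            records = generate_cohort(
                default_config(n=config.simulate_n, seed=config.seed)
            )
            cohort_path = out_dir / "cohort.csv"
            write_survey(records, cohort_path)
            written["cohort"] = cohort_path
            input_path = cohort_path
        else:
            input_path = Path(config.input_csv)
            records, rejections = read_survey(input_path)
            if rejections:
                log.warning("rejected %d malformed rows", len(rejections))

        cutoff = config.cutoff
        scores = score_cohort(records, cutoff=cutoff)
        if config.derive_cutoff_pct is not None:
            cutoff = derive_cutoff(scores["total"], config.derive_cutoff_pct)
            log.info("derived cutoff at percentile %.1f: %d",
                     config.derive_cutoff_pct, cutoff)
            scores = score_cohort(records, cutoff=cutoff)
        scores_path = out_dir / "scores.csv"
        scores.to_csv(scores_path, index=False)
        written["scores"] = scores_path

        summary = distribution_summary(scores["total"])
        psych = {
            group: report.to_dict()
            for group, report in battery_by_age_group(
                list(records), n_factors=config.n_factors
            ).items()
        }
        psych["distribution"] = dataclasses.asdict(summary)
        psych_path = out_dir / "psychometrics.json"
        psych_path.write_text(json.dumps(psych, indent=2, allow_nan=True))
        written["psychometrics"] = psych_path

        analysis = analyze_records(
            records, cutoff=cutoff, alpha=config.alpha,
            ci_level=config.ci_level, corrected_chi2=config.corrected_chi2,
        )
        table_path = out_dir / "association.csv"
        render_table3(analysis).to_csv(table_path, index=False)
        written["association"] = table_path
        json_path = out_dir / "association.json"
        json_path.write_text(analysis.to_json(orient="records", indent=2))
        written["association_json"] = json_path

        run_log = {
            "screenseven_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": dataclasses.asdict(config),
            "cutoff_used": cutoff,
            "n_records": len(records),
            "input_sha256": _sha256(input_path),
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(run_log, indent=2))
        written["run_log"] = log_path
        return written
    except ScreenSevenError:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
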