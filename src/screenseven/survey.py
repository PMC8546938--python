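"""Survey data model for the Seven-in-Seven screen exposure study.

One record per mother–child pair: family/child/screen-use covariates,
optional anthropometric z-scores, and the raw responses to the seven
questionnaire items.  Records travel as comma-separated text with a fixed
documented header; a :class:`Codebook` pins the admissible level labels and
the reference level of every categorical field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import math

import pandas as pd
import yaml

from .errors import ValidationError

YES_NO = ("no", "yes")

#: Admissible levels per categorical field; first level is not necessarily
#: the reference — see REFERENCE_LEVELS.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "maternal_age_band": ("lt30", "ge30"),
    "paternal_age_band": ("lt30", "ge30"),
    "maternal_education_band": ("le12y", "gt12y"),
    "paternal_education_band": ("le12y", "gt12y"),
    "maternal_occupation": ("working", "not_working"),
    "income": ("high", "middle", "low"),
    "family_type": ("nuclear", "single_or_extended"),
    "family_size_band": ("lt5", "ge5"),
    "settlement": ("urban", "rural"),
    "province": ("Afyon", "Ankara", "Mersin"),
    "daycare": ("mother", "grandparent", "childminder", "kindergarten"),
    "n_siblings_band": ("0", "1", "ge2"),
    "postponing_needs": ("never", "sometimes", "frequently"),
    "own_devices_band": ("0", "1", "ge2"),
    "uses_touchscreen": YES_NO,
    "video_gaming_band": ("none", "lt1h", "ge1h"),
    "meals_use": YES_NO,
    "bedtime_use": YES_NO,
    "co_viewing": ("always", "sometimes", "rarely_ever"),
    "limits": ("set_and_obeyed", "not_set", "set_not_obeyed"),
}

#: Reference level per categorical field (the odds-ratio 1.00 rows).
REFERENCE_LEVELS: dict[str, str] = {
    "sex": "female",
    "maternal_age_band": "lt30",
    "paternal_age_band": "lt30",
    "maternal_education_band": "le12y",
    "paternal_education_band": "le12y",
    "maternal_occupation": "working",
    "income": "high",
    "family_type": "nuclear",
    "family_size_band": "lt5",
    "settlement": "urban",
    "province": "Afyon",
    "daycare": "mother",
    "n_siblings_band": "0",
    "postponing_needs": "never",
    "own_devices_band": "0",
    "uses_touchscreen": "no",
    "video_gaming_band": "none",
    "meals_use": "no",
    "bedtime_use": "no",
    "co_viewing": "always",
    "limits": "set_and_obeyed",
}

#: Fixed CSV column order.
COLUMNS: tuple[str, ...] = (
    "child_age_months",
    "sex",
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
    "daycare",
    "n_siblings_band",
    "postponing_needs",
    "own_devices_band",
    "uses_touchscreen",
    "video_gaming_band",
    "wfh_z",
    "hfa_z",
    "wfa_z",
    "tv_weekday_h",
    "other_weekday_h",
    "tv_weekend_h",
    "other_weekend_h",
    "onset_age_months",
    "meals_use",
    "bedtime_use",
    "inappropriate_content_kinds",
    "co_viewing",
    "limits",
)

HOUR_FIELDS = ("tv_weekday_h", "other_weekday_h", "tv_weekend_h", "other_weekend_h")
Z_FIELDS = ("wfh_z", "hfa_z", "wfa_z")


@dataclass
class Codebook:
    """Level labels and reference level for every categorical survey field."""

    levels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CATEGORICAL_LEVELS)
    )
    reference: dict[str, str] = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self) -> None:
        for name, ref in self.reference.items():
            if name not in self.levels:
                raise ValidationError(f"reference given for unknown field {name!r}")
            if ref not in self.levels[name]:
                raise ValidationError(
                    f"reference level {ref!r} not among levels of {name!r}"
                )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            name: {"levels": list(lv), "reference": self.reference[name]}
            for name, lv in self.levels.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        doc = yaml.safe_load(Path(path).read_text())
        levels = {k: tuple(v["levels"]) for k, v in doc.items()}
        reference = {k: v["reference"] for k, v in doc.items()}
        return cls(levels=levels, reference=reference)


DEFAULT_CODEBOOK = Codebook()


@dataclass(frozen=True)
class ScreenTimeReport:
    """Hours/day in front of a screen, split TV vs other and weekday vs weekend."""

    tv_weekday_h: float
    other_weekday_h: float
    tv_weekend_h: float
    other_weekend_h: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.tv_weekday_h,
            self.other_weekday_h,
            self.tv_weekend_h,
            self.other_weekend_h,
        )


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Raw answers to the seven questionnaire items (pre-coded, not scored)."""

    screen_time: ScreenTimeReport
    onset_age_months: int
    meals_use: str  # yes/no
    bedtime_use: str  # yes/no
    inappropriate_content_kinds: int
    co_viewing: str  # always / sometimes / rarely_ever
    limits: str  # set_and_obeyed / not_set / set_not_obeyed


@dataclass(frozen=True)
class SurveyRecord:
    """One mother–child pair: covariates plus the questionnaire response."""

    child_age_months: int
    sex: str
    maternal_age_band: str
    paternal_age_band: str
    maternal_education_band: str
    paternal_education_band: str
    maternal_occupation: str
    income: str
    family_type: str
    family_size_band: str
    settlement: str
    province: str
    daycare: str
    n_siblings_band: str
    postponing_needs: str
    own_devices_band: str
    uses_touchscreen: str
    video_gaming_band: str
    response: QuestionnaireResponse
    wfh_z: float | None = None
    hfa_z: float | None = None
    wfa_z: float | None = None


def validate_record(
    record: SurveyRecord, codebook: Codebook = DEFAULT_CODEBOOK
) -> list[str]:
    """Return the list of violated invariants; empty iff the record is valid."""
    problems: list[str] = []
    if not 24 <= record.child_age_months <= 72:
        problems.append(
            f"child_age_months {record.child_age_months} outside [24, 72]"
        )
    resp = record.response
    for name, value in zip(HOUR_FIELDS, resp.screen_time.as_tuple()):
        if not math.isfinite(value) or value < 0:
            problems.append(f"{name} negative or non-finite: {value!r}")
        elif value > 24:
            problems.append(f"{name} hours > 24: {value!r}")
    if resp.onset_age_months < 0:
        problems.append(f"onset_age_months negative: {resp.onset_age_months}")
    elif resp.onset_age_months > record.child_age_months:
        problems.append(
            f"onset_age_months {resp.onset_age_months} exceeds child age "
            f"{record.child_age_months}"
        )
    if resp.inappropriate_content_kinds < 0:
        problems.append(
            f"inappropriate_content_kinds negative: {resp.inappropriate_content_kinds}"
        )
    cat_values = {
        **{f.name: getattr(record, f.name) for f in dc_fields(SurveyRecord)
           if f.name in codebook.levels},
        "meals_use": resp.meals_use,
        "bedtime_use": resp.bedtime_use,
        "co_viewing": resp.co_viewing,
        "limits": resp.limits,
    }
    for name, value in cat_values.items():
        if value not in codebook.levels[name]:
            problems.append(
                f"{name} level {value!r} not in codebook "
                f"{list(codebook.levels[name])}"
            )
    for name in Z_FIELDS:
        z = getattr(record, name)
        if z is not None and not math.isfinite(z):
            problems.append(f"{name} non-finite: {z!r}")
    return problems


def record_to_row(record: SurveyRecord) -> dict[str, object]:
    resp = record.response
    row: dict[str, object] = {
        "child_age_months": record.child_age_months,
        "tv_weekday_h": resp.screen_time.tv_weekday_h,
        "other_weekday_h": resp.screen_time.other_weekday_h,
        "tv_weekend_h": resp.screen_time.tv_weekend_h,
        "other_weekend_h": resp.screen_time.other_weekend_h,
        "onset_age_months": resp.onset_age_months,
        "meals_use": resp.meals_use,
        "bedtime_use": resp.bedtime_use,
        "inappropriate_content_kinds": resp.inappropriate_content_kinds,
        "co_viewing": resp.co_viewing,
        "limits": resp.limits,
    }
    for f in dc_fields(SurveyRecord):
        if f.name in ("response", "child_age_months"):
            continue
        row[f.name] = getattr(record, f.name)
    return {c: row[c] for c in COLUMNS}


@dataclass
class RowRejection:
    """Why an input row was refused."""

    row_index: int
    reasons: list[str]


def _parse_row(
    idx: int, row: dict[str, str], codebook: Codebook
) -> tuple[SurveyRecord | None, RowRejection | None]:
    reasons: list[str] = []

    def as_float(name: str) -> float:
        try:
            return float(row[name])
        except (TypeError, ValueError):
            reasons.append(f"unparseable value for {name}: {row[name]!r}")
            return float("nan")

    def as_int(name: str) -> int:
        try:
            return int(float(row[name]))
        except (TypeError, ValueError):
            reasons.append(f"unparseable value for {name}: {row[name]!r}")
            return -1

    def as_opt_float(name: str) -> float | None:
        raw = row.get(name)
        if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            reasons.append(f"unparseable value for {name}: {raw!r}")
            return None

    st = ScreenTimeReport(*(as_float(n) for n in HOUR_FIELDS))
    resp = QuestionnaireResponse(
        screen_time=st,
        onset_age_months=as_int("onset_age_months"),
        meals_use=str(row["meals_use"]),
        bedtime_use=str(row["bedtime_use"]),
        inappropriate_content_kinds=as_int("inappropriate_content_kinds"),
        co_viewing=str(row["co_viewing"]),
        limits=str(row["limits"]),
    )
    record = SurveyRecord(
        child_age_months=as_int("child_age_months"),
        sex=str(row["sex"]),
        maternal_age_band=str(row["maternal_age_band"]),
        paternal_age_band=str(row["paternal_age_band"]),
        maternal_education_band=str(row["maternal_education_band"]),
        paternal_education_band=str(row["paternal_education_band"]),
        maternal_occupation=str(row["maternal_occupation"]),
        income=str(row["income"]),
        family_type=str(row["family_type"]),
        family_size_band=str(row["family_size_band"]),
        settlement=str(row["settlement"]),
        province=str(row["province"]),
        daycare=str(row["daycare"]),
        n_siblings_band=str(row["n_siblings_band"]),
        postponing_needs=str(row["postponing_needs"]),
        own_devices_band=str(row["own_devices_band"]),
        uses_touchscreen=str(row["uses_touchscreen"]),
        video_gaming_band=str(row["video_gaming_band"]),
        wfh_z=as_opt_float("wfh_z"),
        hfa_z=as_opt_float("hfa_z"),
        wfa_z=as_opt_float("wfa_z"),
        response=resp,
    )
    if not reasons:
        reasons = validate_record(record, codebook)
    if reasons:
        return None, RowRejection(row_index=idx, reasons=reasons)
    return record, None


def read_survey(
    path: str | Path, codebook: Codebook = DEFAULT_CODEBOOK
) -> tuple[list[SurveyRecord], list[RowRejection]]:
    """Read a survey CSV; return (valid records, rejected rows).

    Row order is preserved; a missing mandatory column is a hard error,
    while a malformed row is collected into the rejection report.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[SurveyRecord] = []
    rejections: list[RowRejection] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        rec, rej = _parse_row(idx, row, codebook)
        if rec is not None:
            records.append(rec)
        else:
            rejections.append(rej)  # type: ignore[arg-type]
    return records, rejections


def write_survey(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write records as CSV with the fixed column order.

    Absent z-scores become empty cells (missing, not zero); round-trips
    through :func:`read_survey`.
    """
    rows = [record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False)


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the CSV column layout."""
    return pd.DataFrame(
        [record_to_row(r) for r in records], columns=list(COLUMNS)
    )
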