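"""Coded household survey records and aggregate quality-of-life scores.

A needs-assessment interview covers one household and is stored as one row
of a coded CSV (integer codes, one column per question).  This module
decodes and validates those rows into :class:`SurveyRecord` objects and
computes the four aggregate scores used throughout the pipeline:

``wash_score`` (0-4)
    Count of favorable WASH components: indoor toilet (improved
    sanitation), indoor bathroom (improved sanitation II), piped water to
    a tap (improved water source), and secure housing (no deficient
    component among floor, walls, roof).

``wash_safe_score`` (0-4)
    Same, but the water component is the broader *safe water* flag — a
    piped tap or a private protected well.

``healthcare_score`` (0-4)
    Any immunization + no moderate/severe diarrheal event in the last
    year + access to a primary-care physician + medical insurance.

``poverty_score`` (0-3)
    Electricity in the dwelling + gas (piped or tank) + spending more
    than 2 USD per person per day.

All four scores count FAVORABLE components, so larger is always better;
the adverse orientation used for odds ratios lives in
:mod:`needscape.group_stats`.  Insecure housing is additionally kept as
the 0-3 deficiency count over floor, walls and roof, with the yes/no
"insecure housing" flag meaning at least one deficient component.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

GEOGRAPHY_CLASSES = ("rural", "suburban", "urban")
ETHNICITIES = ("roma", "non_roma")
SEXES = ("M", "F")
MARITAL = ("partnership", "single")
EMPLOYMENT = ("full_time", "unemployed_or_day_labour")
AGE_STRUCTURES = ("no_minors", "some_minors", "majority_minors")

#: boolean survey questions, coded 0/1 in the CSV
FLAG_FIELDS = (
    "literate",
    "indoor_toilet",
    "indoor_bathroom",
    "piped_tap",
    "protected_well",
    "housing_deficient_floor",
    "housing_deficient_walls",
    "housing_deficient_roof",
    "diarrhea_mod_severe",
    "immunized_any",
    "insured",
    "pcp_access",
    "electricity",
    "gas",
    "spends_over_2usd",
    "property_documents",
)

#: default integer coding of the categorical questions
DEFAULT_CODE_MAP: dict[str, dict[int, str]] = {
    "geography_class": {0: "rural", 1: "suburban", 2: "urban"},
    "ethnicity": {0: "non_roma", 1: "roma", 2: "roma"},  # 2 = Rudar, a Roma subgroup
    "respondent_sex": {0: "M", 1: "F"},
    "marital": {0: "partnership", 1: "single"},
    "employment": {0: "full_time", 1: "unemployed_or_day_labour"},
}

NUMERIC_FIELDS = (
    "respondent_age",
    "household_size",
    "n_minors",
    "education_grade",
    "time_to_water",
    "distance_to_water_km",
)

CSV_COLUMNS = (
    "community_id",
    "geography_class",
    "ethnicity",
    "respondent_age",
    "respondent_sex",
    "household_size",
    "n_minors",
    "education_grade",
    "marital",
    "employment",
    "time_to_water",
    "distance_to_water_km",
) + FLAG_FIELDS


class SurveySchemaError(ValueError):
    """The survey file is structurally unusable (e.g. a column is missing)."""


class SurveyValidationError(ValueError):
    """One or more rows failed validation.

    Attributes
    ----------
    errors : list of (row_index, message)
        1-based data row indices (header excluded).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {i}: {m}" for i, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid survey row(s): {lines}{more}")


@dataclass(slots=True)
class SurveyRecord:
    """One decoded, validated household interview."""

    community_id: str
    geography_class: str
    ethnicity: str
    respondent_age: float
    respondent_sex: str
    household_size: int
    n_minors: int
    education_grade: int
    marital: str
    employment: str
    time_to_water: int
    distance_to_water_km: float
    literate: bool
    indoor_toilet: bool
    indoor_bathroom: bool
    piped_tap: bool
    protected_well: bool
    housing_deficient_floor: bool
    housing_deficient_walls: bool
    housing_deficient_roof: bool
    diarrhea_mod_severe: bool
    immunized_any: bool
    insured: bool
    pcp_access: bool
    electricity: bool
    gas: bool
    spends_over_2usd: bool
    property_documents: bool

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty if valid)."""
        problems = []
        if self.geography_class not in GEOGRAPHY_CLASSES:
            problems.append(f"geography_class {self.geography_class!r}")
        if self.ethnicity not in ETHNICITIES:
            problems.append(f"ethnicity {self.ethnicity!r}")
        if self.respondent_sex not in SEXES:
            problems.append(f"respondent_sex {self.respondent_sex!r}")
        if self.marital not in MARITAL:
            problems.append(f"marital {self.marital!r}")
        if self.employment not in EMPLOYMENT:
            problems.append(f"employment {self.employment!r}")
        if self.household_size < 1:
            problems.append(f"household_size {self.household_size} < 1")
        if not 0 <= self.n_minors < max(self.household_size, 1):
            problems.append(
                f"n_minors {self.n_minors} outside [0, household_size)"
            )
        if not 0 <= self.education_grade <= 16:
            problems.append(f"education_grade {self.education_grade} outside 0-16")
        if self.time_to_water not in (0, 1, 2, 3, 4):
            problems.append(f"time_to_water {self.time_to_water} outside 0-4")
        if self.distance_to_water_km < 0:
            problems.append("distance_to_water_km negative")
        return problems


@dataclass(slots=True, frozen=True)
class ScoreBundle:
    """The aggregate scores of one household (all favorable-direction)."""

    insecure_housing_score: int  # 0-3 count of deficient components
    insecure_housing_flag: bool  # any deficient component
    wash_score: int  # 0-4
    wash_safe_score: int  # 0-4
    healthcare_score: int  # 0-4
    poverty_score: int  # 0-3


def safe_water(record: SurveyRecord) -> bool:
    """Household has a safe water source: piped tap or protected well."""
    return record.piped_tap or record.protected_well


def compute_scores(record: SurveyRecord) -> ScoreBundle:
    """Compute the aggregate quality-of-life scores for one household."""
    housing = (
        int(record.housing_deficient_floor)
        + int(record.housing_deficient_walls)
        + int(record.housing_deficient_roof)
    )
    secure = int(housing == 0)
    wash = (
        int(record.indoor_toilet)
        + int(record.indoor_bathroom)
        + int(record.piped_tap)
        + secure
    )
    wash_safe = (
        int(record.indoor_toilet)
        + int(record.indoor_bathroom)
        + int(safe_water(record))
        + secure
    )
    healthcare = (
        int(record.immunized_any)
        + int(not record.diarrhea_mod_severe)
        + int(record.pcp_access)
        + int(record.insured)
    )
    poverty = int(record.electricity) + int(record.gas) + int(record.spends_over_2usd)
    return ScoreBundle(
        insecure_housing_score=housing,
        insecure_housing_flag=housing >= 1,
        wash_score=wash,
        wash_safe_score=wash_safe,
        healthcare_score=healthcare,
        poverty_score=poverty,
    )


def age_structure(record: SurveyRecord) -> str:
    """Household age-structure class derived from the minor count.

    ``no_minors`` if no household member is under 18, ``majority_minors``
    if minors are a strict majority, ``some_minors`` otherwise.
    """
    if record.n_minors == 0:
        return "no_minors"
    if record.n_minors > record.household_size / 2:
        return "majority_minors"
    return "some_minors"


def load_code_map(path: str | Path) -> dict[str, dict[int, str]]:
    """Read a column -> {code: meaning} map from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {col: {int(k): str(v) for k, v in codes.items()} for col, codes in raw.items()}


def _decode_row(
    row: Mapping[str, str], code_map: Mapping[str, Mapping[int, str]]
) -> SurveyRecord:
    kwargs: dict[str, object] = {"community_id": str(row["community_id"])}
    for col, codes in code_map.items():
        code = int(row[col])
        if code not in codes:
            raise ValueError(f"column {col!r}: unmappable code {code}")
        kwargs[col] = codes[code]
    for col in ("respondent_age", "distance_to_water_km"):
        kwargs[col] = float(row[col])
    for col in ("household_size", "n_minors", "education_grade", "time_to_water"):
        kwargs[col] = int(row[col])
    for col in FLAG_FIELDS:
        code = int(row[col])
        if code not in (0, 1):
            raise ValueError(f"column {col!r}: unmappable code {code}")
        kwargs[col] = bool(code)
    return SurveyRecord(**kwargs)  # type: ignore[arg-type]


def load_survey(
    path: str | Path,
    code_map: Mapping[str, Mapping[int, str]] | None = None,
) -> list[SurveyRecord]:
    """Load and validate a coded survey CSV.

    Parameters
    ----------
    path
        CSV with one row per household, integer codes, header row.
    code_map
        column -> {code: meaning} for the categorical questions; defaults
        to :data:`DEFAULT_CODE_MAP`.

    Raises
    ------
    SurveySchemaError
        if a mandatory column is missing from the header.
    SurveyValidationError
        if any row has an unmappable code or violates a field invariant;
        ``.errors`` lists every offending (row index, message).
    """
    code_map = dict(code_map or DEFAULT_CODE_MAP)
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SurveySchemaError(
                f"missing mandatory column(s): {', '.join(missing)}"
            )
        records: list[SurveyRecord] = []
        errors: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                rec = _decode_row(row, code_map)
            except (ValueError, KeyError) as exc:
                errors.append((i, str(exc)))
                continue
            problems = rec.validate()
            if problems:
                errors.append((i, "; ".join(problems)))
            else:
                records.append(rec)
    if errors:
        raise SurveyValidationError(errors)
    # geography must be consistent within a community
    geo_by_comm: dict[str, str] = {}
    for i, rec in enumerate(records, start=1):
        seen = geo_by_comm.setdefault(rec.community_id, rec.geography_class)
        if seen != rec.geography_class:
            errors.append(
                (i, f"community {rec.community_id!r} mixes geography classes")
            )
    if errors:
        raise SurveyValidationError(errors)
    return records


def _encode_record(
    rec: SurveyRecord, inverse: Mapping[str, Mapping[str, int]]
) -> dict[str, object]:
    out: dict[str, object] = {}
    for col in CSV_COLUMNS:
        val = getattr(rec, col)
        if col in inverse:
            out[col] = inverse[col][val]
        elif col in FLAG_FIELDS:
            out[col] = int(val)
        else:
            out[col] = val
    return out


def write_survey(
    records: Sequence[SurveyRecord],
    path: str | Path,
    code_map: Mapping[str, Mapping[int, str]] | None = None,
) -> None:
    """Write records back to the coded CSV dialect (round-trips load_survey)."""
    code_map = dict(code_map or DEFAULT_CODE_MAP)
    # invert, preferring the lowest code for a meaning (Rudar re-encodes as roma)
    inverse: dict[str, dict[str, int]] = {}
    for col, codes in code_map.items():
        inv: dict[str, int] = {}
        for code in sorted(codes):
            inv.setdefault(codes[code], code)
        inverse[col] = inv
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CSV_COLUMNS))
        writer.writeheader()
        for rec in records:
            writer.writerow(_encode_record(rec, inverse))


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Decoded records as a DataFrame (one row per household)."""
    cols = [f.name for f in dc_fields(SurveyRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def score_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Aggregate scores for every record, as a DataFrame."""
    rows = []
    for rec in records:
        b = compute_scores(rec)
        rows.append(
            {
                "community_id": rec.community_id,
                "ethnicity": rec.ethnicity,
                "insecure_housing_score": b.insecure_housing_score,
                "insecure_housing_flag": b.insecure_housing_flag,
                "wash_score": b.wash_score,
                "wash_safe_score": b.wash_safe_score,
                "healthcare_score": b.healthcare_score,
                "poverty_score": b.poverty_score,
            }
        )
    return pd.DataFrame(rows)
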