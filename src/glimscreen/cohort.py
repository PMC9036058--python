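"""Patient record schema, validation, anthropometric derivations and cohort CSV I/O.

A :class:`PatientRecord` holds everything the downstream screening instruments
(NRS2002, MUST), the GLIM diagnosis and the outcome models consume: demographics,
anthropometrics (weight, height, optional fat-free mass from bioimpedance),
weight-loss history expressed as per-window percentages, dietary-intake history,
disease-severity indicators and clinical outcomes.

Weight-loss history is deliberately stored as per-window percentages rather than
raw serial weights, because that is what each instrument consumes: NRS2002 looks
at loss over the past 1/2/3 months, MUST at unplanned loss over the past 3-6
months, and GLIM at loss within / beyond 6 months. A convenience converter from
raw serial weights is provided (:func:`weight_loss_percent`) but the instruments
never see raw weights.

Heights are stored in metres. The CSV reader accepts a unit declaration (``m``
or ``cm``) and normalizes on read; clinical sources mix units and a silent
misread is catastrophic for BMI cutoffs.
"""

from __future__ import annotations

import csv
import enum
import math
from typing import Iterable, Iterator, Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class TumorSite(str, enum.Enum):
    stomach = "stomach"
    small_intestine = "small_intestine"
    colorectum = "colorectum"
    other = "other"


class RiskStratification(str, enum.Enum):
    very_low = "very_low"
    low = "low"
    medium = "medium"
    high = "high"


class DiseaseSeverity(enum.IntEnum):
    """Pre-coded NRS2002 severity-of-disease class (part 2 of the score)."""

    absent = 0
    mild = 1
    moderate = 2
    severe = 3


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates the schema invariants."""


class PatientRecord(BaseModel):
    """One inpatient's admission snapshot.

    All percent-loss fields are non-negative percentages of body weight;
    ``intake_fraction_past_week`` is the fraction of normal requirements
    consumed in the week before admission, in [0, 1]. Optional fields default
    to ``None`` (absent), never to zero.
    """

    model_config = {"validate_assignment": True}

    patient_id: str
    age: int = Field(ge=18, le=90)
    sex: Sex
    height: float = Field(gt=0, description="metres")
    weight: float = Field(gt=0, description="kilograms")
    ffm: Optional[float] = Field(default=None, gt=0, description="fat-free mass, kg")

    weight_loss_pct_1mo: float = Field(default=0.0, ge=0)
    weight_loss_pct_2mo: float = Field(default=0.0, ge=0)
    weight_loss_pct_3mo: float = Field(default=0.0, ge=0)
    weight_loss_pct_3to6mo: float = Field(default=0.0, ge=0)
    weight_loss_pct_within_6mo: float = Field(default=0.0, ge=0)
    weight_loss_pct_beyond_6mo: float = Field(default=0.0, ge=0)

    intake_fraction_past_week: float = Field(default=1.0, ge=0.0, le=1.0)
    intake_below_half_gt1wk: bool = False
    intake_reduced_ge2wk: bool = False
    gi_symptoms_impairing_assimilation: bool = False
    acutely_ill_no_intake_gt5d: bool = False

    nrs_disease_severity: DiseaseSeverity = DiseaseSeverity.absent
    planned_major_abdominal_surgery: bool = False
    impaired_general_condition: bool = False
    has_inflammatory_disease: bool = False
    surgical_admission: bool = False

    albumin: Optional[float] = Field(default=None, gt=0, description="g/L")
    hemoglobin: Optional[float] = Field(default=None, gt=0, description="g/L")
    tumor_site: Optional[TumorSite] = None
    risk_stratification: Optional[RiskStratification] = None
    targeted_therapy: Optional[bool] = None
    n_symptoms: Optional[int] = Field(default=None, ge=0)

    los_days: Optional[float] = Field(default=None, ge=0)
    postop_los_days: Optional[float] = Field(default=None, ge=0)
    complications: Optional[bool] = None

    @field_validator("height", "weight")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("must be finite")
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "PatientRecord":
        if not self.surgical_admission and self.postop_los_days is not None:
            raise ValueError(
                "postop_los_days must be absent for non-surgical admissions"
            )
        return self

    @property
    def bmi(self) -> float:
        """Body mass index, weight (kg) divided by the square of height (m)."""
        return self.weight / self.height**2

    @property
    def ffmi(self) -> Optional[float]:
        """Fat-free mass index, FFM divided by the square of height; absent without FFM."""
        if self.ffm is None:
            return None
        return self.ffm / self.height**2


def derive_anthropometrics(record: PatientRecord) -> tuple[float, Optional[float]]:
    """Return ``(bmi, ffmi)`` for a record; ``ffmi`` is ``None`` when FFM is absent.

    BMI = weight / height**2 (kg/m**2); FFMI = FFM / height**2 when fat-free
    mass was measured. Non-positive height or weight is rejected at record
    construction, naming the field.
    """
    return record.bmi, record.ffmi


def weight_loss_percent(weight_then: float, weight_now: float) -> float:
    """Percent of body weight lost between two serial weights (clamped at 0).

    Convenience converter only: instruments consume the per-window percentage
    fields on :class:`PatientRecord`, never raw weights.
    """
    if weight_then <= 0:
        raise CohortValidationError("weight_then must be positive")
    return max(0.0, 100.0 * (weight_then - weight_now) / weight_then)


class Cohort:
    """Ordered collection of validated :class:`PatientRecord` with provenance.

    ``patient_id`` is unique within a cohort.
    """

    def __init__(self, records: Iterable[PatientRecord], provenance: str = "") -> None:
        self.records: list[PatientRecord] = list(records)
        self.provenance = provenance
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise CohortValidationError(
                    f"duplicate patient_id: {rec.patient_id!r}"
                )
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def subset(self, predicate, provenance_suffix: str = "subset") -> "Cohort":
        return Cohort(
            [r for r in self.records if predicate(r)],
            provenance=f"{self.provenance}:{provenance_suffix}",
        )


# Deterministic CSV column order: identity, demographics, anthropometrics,
# weight-loss windows, intake, disease indicators, labs, tumor data, outcomes.
CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "height",
    "weight",
    "ffm",
    "weight_loss_pct_1mo",
    "weight_loss_pct_2mo",
    "weight_loss_pct_3mo",
    "weight_loss_pct_3to6mo",
    "weight_loss_pct_within_6mo",
    "weight_loss_pct_beyond_6mo",
    "intake_fraction_past_week",
    "intake_below_half_gt1wk",
    "intake_reduced_ge2wk",
    "gi_symptoms_impairing_assimilation",
    "acutely_ill_no_intake_gt5d",
    "nrs_disease_severity",
    "planned_major_abdominal_surgery",
    "impaired_general_condition",
    "has_inflammatory_disease",
    "surgical_admission",
    "albumin",
    "hemoglobin",
    "tumor_site",
    "risk_stratification",
    "targeted_therapy",
    "n_symptoms",
    "los_days",
    "postop_los_days",
    "complications",
)

MANDATORY_COLUMNS = ("patient_id", "age", "sex", "height", "weight")

_BOOL_FIELDS = {
    "intake_below_half_gt1wk",
    "intake_reduced_ge2wk",
    "gi_symptoms_impairing_assimilation",
    "acutely_ill_no_intake_gt5d",
    "planned_major_abdominal_surgery",
    "impaired_general_condition",
    "has_inflammatory_disease",
    "surgical_admission",
    "targeted_therapy",
    "complications",
}
_INT_FIELDS = {"age", "nrs_disease_severity", "n_symptoms"}
_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan"}
_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n"}


def _parse_cell(field: str, raw: str):
    raw = raw.strip()
    if raw in _MISSING_TOKENS:
        return None
    if field in _BOOL_FIELDS:
        low = raw.lower()
        if low in _TRUE_TOKENS:
            return True
        if low in _FALSE_TOKENS:
            return False
        raise CohortValidationError(f"unparsable boolean {raw!r} for {field!r}")
    if field in _INT_FIELDS:
        try:
            return int(float(raw))
        except ValueError as exc:
            raise CohortValidationError(
                f"unparsable integer {raw!r} for {field!r}"
            ) from exc
    if field in ("patient_id", "sex", "tumor_site", "risk_stratification"):
        return raw
    try:
        return float(raw)
    except ValueError as exc:
        raise CohortValidationError(f"unparsable number {raw!r} for {field!r}") from exc


def read_cohort(path, schema_config: Optional[dict] = None) -> Cohort:
    """Read a cohort from a delimited text file with a header row.

    ``schema_config`` may carry ``column_map`` ({file column -> canonical
    field}) and ``units`` (currently ``height: m|cm``). Rows failing the
    record invariants are rejected with row-number diagnostics; missing
    optional cells (empty string or ``NA``) become absent, never zero.
    """
    schema_config = schema_config or {}
    column_map: dict = schema_config.get("column_map", {})
    units: dict = schema_config.get("units", {})
    height_unit = units.get("height", "m")
    if height_unit not in ("m", "cm"):
        raise CohortValidationError(f"unknown height unit {height_unit!r}")

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = [column_map.get(c, c) for c in (reader.fieldnames or [])]
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise CohortValidationError(f"missing mandatory column(s): {missing}")
        unknown = [c for c in header if c not in CSV_COLUMNS]
        if unknown:
            raise CohortValidationError(f"unknown column(s): {unknown}")

        records: list[PatientRecord] = []
        for row_no, row in enumerate(reader, start=2):
            try:
                kwargs = {}
                for file_col, raw in row.items():
                    if file_col is None or raw is None:
                        continue
                    field = column_map.get(file_col, file_col)
                    value = _parse_cell(field, raw)
                    if value is not None:
                        kwargs[field] = value
                if height_unit == "cm" and "height" in kwargs:
                    kwargs["height"] = kwargs["height"] / 100.0
                records.append(PatientRecord(**kwargs))
            except (ValueError, CohortValidationError) as exc:
                raise CohortValidationError(f"row {row_no}: {exc}") from exc
    return Cohort(records, provenance=f"file:{path}")


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return str(value.value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV in the fixed documented column order (lossless)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in cohort:
            writer.writerow(
                [_format_cell(getattr(rec, col)) for col in CSV_COLUMNS]
            )
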