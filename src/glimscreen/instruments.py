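"""NRS2002 and MUST screening instruments as deterministic rule engines.

NRS2002 (ESPEN) totals three parts: impaired nutritional status (0-3, the
maximum over weight-loss, intake and BMI sub-rules), severity of disease as a
proxy for increased requirements (0-3), and an age point for patients 70 years
or older. Total 0-7; a total of 3 or more flags high nutritional risk.

MUST (BAPEN) totals three components: BMI band, unplanned weight loss over the
past 3-6 months, and an acute-disease effect (no nutritional intake for more
than 5 days). Overall risk is low (0), medium (1) or high (>= 2).

Both scorers are pure functions of a validated :class:`~glimscreen.cohort.PatientRecord`
and record every sub-rule that fired in ``triggered_rules`` as an audit trail.

Band conventions (the deterministic tie-breaks at printed band edges):

* NRS2002 intake fraction over the past week: [0, 0.25] -> 3, (0.25, 0.5] -> 2,
  (0.5, 0.75] -> 1, (0.75, 1] -> 0.
* NRS2002 BMI sub-rules require an impaired general condition: < 18.5 -> 3,
  18.5-20.5 (inclusive) -> 2.
* MUST BMI: > 20 -> 0; 18.5-20 inclusive -> 1; < 18.5 -> 2. Weight loss:
  < 5% -> 0; 5-10% inclusive -> 1; > 10% -> 2 (lower band edges inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import PatientRecord

NRS_HIGH_RISK_CUTOFF = 3
MUST_POSITIVE_CUTOFF = 1  # medium or high risk


@dataclass(frozen=True)
class Nrs2002Result:
    nutrition_score: int
    disease_score: int
    age_score: int
    total: int
    high_risk: bool
    triggered_rules: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assert self.total == self.nutrition_score + self.disease_score + self.age_score
        assert self.high_risk == (self.total >= NRS_HIGH_RISK_CUTOFF)
        assert 0 <= self.total <= 7


@dataclass(frozen=True)
class MustResult:
    bmi_score: int
    weight_loss_score: int
    acute_disease_score: int
    total: int
    category: str  # "low" | "medium" | "high"
    triggered_rules: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assert self.total == (
            self.bmi_score + self.weight_loss_score + self.acute_disease_score
        )
        expected = "low" if self.total == 0 else ("medium" if self.total == 1 else "high")
        assert self.category == expected

    @property
    def positive(self) -> bool:
        """Moderate/high nutritional risk (total >= 1)."""
        return self.total >= MUST_POSITIVE_CUTOFF


def _nrs_nutrition_score(record: PatientRecord) -> tuple[int, list[str]]:
    bmi = record.bmi
    rules: list[tuple[int, str]] = []

    # Weight-loss sub-rules: >5% in 1 month (~>15% in 3 months) scores 3,
    # >5% in 2 months scores 2, >5% in 3 months scores 1.
    if record.weight_loss_pct_1mo > 5 or record.weight_loss_pct_3mo > 15:
        rules.append((3, "nutrition:weight_loss>5%/1mo"))
    if record.weight_loss_pct_2mo > 5:
        rules.append((2, "nutrition:weight_loss>5%/2mo"))
    if record.weight_loss_pct_3mo > 5:
        rules.append((1, "nutrition:weight_loss>5%/3mo"))

    # Intake sub-rules, half-open bands on the fraction of requirements eaten.
    intake = record.intake_fraction_past_week
    if intake <= 0.25:
        rules.append((3, "nutrition:intake<=25%"))
    elif intake <= 0.5:
        rules.append((2, "nutrition:intake(25-50]%"))
    elif intake <= 0.75:
        rules.append((1, "nutrition:intake(50-75]%"))

    # BMI sub-rules qualified by impaired general condition.
    if record.impaired_general_condition:
        if bmi < 18.5:
            rules.append((3, "nutrition:bmi<18.5+impaired"))
        elif bmi <= 20.5:
            rules.append((2, "nutrition:bmi18.5-20.5+impaired"))

    if not rules:
        return 0, []
    score = max(s for s, _ in rules)
    return score, [name for s, name in rules if s == score]


def score_nrs2002(record: PatientRecord) -> Nrs2002Result:
    """Score a validated record with NRS2002.

    The nutrition score is the maximum over the sub-rules above; the disease
    score is the pre-coded severity class, promoted to at least 2 (moderate)
    when major abdominal surgery is planned; the age point is added at 70
    years or older.
    """
    nutrition, triggered = _nrs_nutrition_score(record)

    disease = int(record.nrs_disease_severity)
    if disease:
        triggered.append(f"disease:severity={disease}")
    if record.planned_major_abdominal_surgery and disease < 2:
        disease = 2
        triggered.append("disease:planned_major_abdominal_surgery=>2")

    age_score = 1 if record.age >= 70 else 0
    if age_score:
        triggered.append("age:>=70")

    total = nutrition + disease + age_score
    return Nrs2002Result(
        nutrition_score=nutrition,
        disease_score=disease,
        age_score=age_score,
        total=total,
        high_risk=total >= NRS_HIGH_RISK_CUTOFF,
        triggered_rules=tuple(triggered),
    )


def score_must(record: PatientRecord) -> MustResult:
    """Score a validated record with MUST."""
    bmi = record.bmi
    triggered: list[str] = []

    if bmi < 18.5:
        bmi_score = 2
        triggered.append("bmi:<18.5")
    elif bmi <= 20.0:
        bmi_score = 1
        triggered.append("bmi:18.5-20")
    else:
        bmi_score = 0

    loss = record.weight_loss_pct_3to6mo
    if loss > 10:
        loss_score = 2
        triggered.append("weight_loss:>10%/3-6mo")
    elif loss >= 5:
        loss_score = 1
        triggered.append("weight_loss:5-10%/3-6mo")
    else:
        loss_score = 0

    acute = 2 if record.acutely_ill_no_intake_gt5d else 0
    if acute:
        triggered.append("acute_disease:no_intake>5d")

    total = bmi_score + loss_score + acute
    category = "low" if total == 0 else ("medium" if total == 1 else "high")
    return MustResult(
        bmi_score=bmi_score,
        weight_loss_score=loss_score,
        acute_disease_score=acute,
        total=total,
        category=category,
        triggered_rules=tuple(triggered),
    )
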