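"""GLIM two-criterion malnutrition diagnosis.

GLIM diagnoses malnutrition when at least one phenotypic criterion (involuntary
weight loss, low BMI, reduced muscle mass) and at least one etiologic criterion
(reduced food intake or assimilation, inflammation/disease burden) are both met.

Two modes are supported:

* ``general`` — the etiologic inflammation criterion comes from the record's
  ``has_inflammatory_disease`` flag.
* ``cancer_cohort`` — every record is taken to meet the inflammation criterion,
  the operationalization appropriate for a cohort in which all patients carry a
  malignancy (cancer is associated with chronic mild-to-moderate inflammation).

Cutoffs (Asian BMI thresholds): BMI < 18.5 kg/m^2 below age 70, < 20 kg/m^2 at
70 or older; low FFMI < 15 kg/m^2 for women and < 17 kg/m^2 for men; weight
loss > 5% within 6 months or > 10% beyond 6 months. All inequalities are
strict, mirroring the criterion definitions; age exactly 70 uses the elderly
cutoff, consistent with the NRS2002 "70 years or older" age point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import PatientRecord, Sex

MODES = ("general", "cancer_cohort")

FFMI_LOW_FEMALE = 15.0
FFMI_LOW_MALE = 17.0
BMI_LOW_ADULT = 18.5
BMI_LOW_ELDERLY = 20.0
ELDERLY_AGE = 70


@dataclass(frozen=True)
class GlimAssessment:
    """Per-criterion flags and final status for one patient.

    ``phen_low_ffmi`` is ``None`` when fat-free mass was not measured: the
    muscle-mass criterion is then not assessable and contributes ``False`` to
    the phenotypic disjunction (noted in ``notes``).
    """

    phen_weight_loss: bool
    phen_low_bmi: bool
    phen_low_ffmi: Optional[bool]
    etio_reduced_intake: bool
    etio_inflammation: bool
    malnourished: bool
    mode: str
    notes: tuple[str, ...] = ()

    @property
    def any_phenotypic(self) -> bool:
        return self.phen_weight_loss or self.phen_low_bmi or bool(self.phen_low_ffmi)

    @property
    def any_etiologic(self) -> bool:
        return self.etio_reduced_intake or self.etio_inflammation


def diagnose_glim(record: PatientRecord, mode: str = "cancer_cohort") -> GlimAssessment:
    """Apply the GLIM phenotypic/etiologic conjunction to one record."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    notes: list[str] = []

    phen_weight_loss = (
        record.weight_loss_pct_within_6mo > 5.0
        or record.weight_loss_pct_beyond_6mo > 10.0
    )

    bmi_cutoff = BMI_LOW_ELDERLY if record.age >= ELDERLY_AGE else BMI_LOW_ADULT
    phen_low_bmi = record.bmi < bmi_cutoff
    if record.age == ELDERLY_AGE:
        notes.append("age exactly 70: elderly BMI cutoff (<20) applied")

    ffmi = record.ffmi
    phen_low_ffmi: Optional[bool]
    if ffmi is None:
        phen_low_ffmi = None
        notes.append("muscle mass not assessable (FFM missing)")
    else:
        cutoff = FFMI_LOW_FEMALE if record.sex == Sex.female else FFMI_LOW_MALE
        phen_low_ffmi = ffmi < cutoff

    etio_reduced_intake = (
        record.intake_below_half_gt1wk
        or record.intake_reduced_ge2wk
        or record.gi_symptoms_impairing_assimilation
    )
    if mode == "cancer_cohort":
        etio_inflammation = True
    else:
        etio_inflammation = record.has_inflammatory_disease

    any_phen = phen_weight_loss or phen_low_bmi or bool(phen_low_ffmi)
    any_etio = etio_reduced_intake or etio_inflammation

    return GlimAssessment(
        phen_weight_loss=phen_weight_loss,
        phen_low_bmi=phen_low_bmi,
        phen_low_ffmi=phen_low_ffmi,
        etio_reduced_intake=etio_reduced_intake,
        etio_inflammation=etio_inflammation,
        malnourished=any_phen and any_etio,
        mode=mode,
        notes=tuple(notes),
    )
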