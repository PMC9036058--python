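"""Synthetic cohort generation.

Two generators with different contracts:

* :func:`generate_fixture_cohort` builds deterministic *archetype* cohorts that
  hit a requested instrument-by-GLIM cross-tabulation exactly. Each joint cell
  (NRS2002 class x MUST class x GLIM status) has an archetype template whose
  decisive fields sit at safe distances from every scoring threshold, so that
  re-scoring the generated patients reproduces the requested counts
  cell-for-cell. Seeded jitter touches only non-decisive fields (identity,
  labs, tumor descriptors, outcomes) plus decisive fields *within* their safe
  bands. Packaged cell specs reproduce the published reference GIST inpatient
  cohort (n = 269; 189 surgical, 80 non-surgical).

* :func:`generate_stochastic_cohort` draws cohorts whose marginal
  distributions follow a parameter set describing the same study population
  (group-wise BMI, age, fat-free-mass index, weight-loss and intake-reduction
  probabilities, length-of-stay model). Screen positivity is *emergent* from
  the drawn features, not assigned.

The archetype mechanism exploits the fact that the three instruments read
disjoint weight-loss windows (NRS2002: 1-3 months; MUST: 3-6 months; GLIM:
within/beyond 6 months), so each can be driven independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .cohort import Cohort, PatientRecord
from .concordance import ContingencyTable2x2

NRS_CLASSES = ("high", "low")
MUST_CLASSES = ("moderate_high", "low")
GLIM_STATUSES = ("malnourished", "well")


@dataclass(frozen=True)
class CellSpec:
    """One joint cell of the (NRS2002, MUST, GLIM) cross-classification."""

    nrs_class: str
    must_class: str
    glim_status: str
    surgical: bool
    count: int

    def __post_init__(self) -> None:
        if self.nrs_class not in NRS_CLASSES:
            raise ValueError(f"nrs_class must be one of {NRS_CLASSES}")
        if self.must_class not in MUST_CLASSES:
            raise ValueError(f"must_class must be one of {MUST_CLASSES}")
        if self.glim_status not in GLIM_STATUSES:
            raise ValueError(f"glim_status must be one of {GLIM_STATUSES}")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def joint_from_marginals(
    nrs_crosstab: ContingencyTable2x2,
    must_crosstab: ContingencyTable2x2,
    surgical: bool = False,
) -> list[CellSpec]:
    """Refine two per-instrument 2x2 cross-tabs into one 8-cell joint spec.

    Published agreement tables give each instrument's cross-tab against GLIM
    separately; the instrument-by-instrument joint is unpublished. Within each
    GLIM stratum the both-instruments-positive cell is set to its Fréchet
    upper bound min(a, b) — maximal agreement between the two instruments —
    which is deterministic and always feasible when the GLIM margins match
    (the lower bound max(0, a + b - m) never exceeds it). Any joint
    consistent with both marginals reproduces every marginal statistic.
    """
    strata = {
        "malnourished": (nrs_crosstab.tp, nrs_crosstab.fn,
                         must_crosstab.tp, must_crosstab.fn),
        "well": (nrs_crosstab.fp, nrs_crosstab.tn,
                 must_crosstab.fp, must_crosstab.tn),
    }
    cells: list[CellSpec] = []
    for glim_status, (n_pos, n_neg, m_pos, m_neg) in strata.items():
        total_nrs = n_pos + n_neg
        total_must = m_pos + m_neg
        if total_nrs != total_must:
            raise ValueError(
                f"GLIM margins differ in {glim_status} stratum: "
                f"NRS total {total_nrs} vs MUST total {total_must}"
            )
        m = total_nrs
        both_pos = min(n_pos, m_pos)
        cells.append(CellSpec("high", "moderate_high", glim_status, surgical, both_pos))
        cells.append(CellSpec("high", "low", glim_status, surgical, n_pos - both_pos))
        cells.append(
            CellSpec("low", "moderate_high", glim_status, surgical, m_pos - both_pos)
        )
        cells.append(
            CellSpec("low", "low", glim_status, surgical, m - n_pos - m_pos + both_pos)
        )
    return cells


# Reference cross-tabulations from the published GIST inpatient cohort
# (screen class vs GLIM diagnosis; cells are tp, fp, fn, tn).
REFERENCE_CROSSTABS = {
    "non-surgical": {
        "nrs2002": ContingencyTable2x2(tp=40, fp=7, fn=3, tn=30),
        "must": ContingencyTable2x2(tp=42, fp=7, fn=1, tn=30),
    },
    "surgical": {
        "nrs2002": ContingencyTable2x2(tp=30, fp=46, fn=13, tn=100),
        "must": ContingencyTable2x2(tp=37, fp=24, fn=6, tn=122),
    },
}


def reference_cells(spec_name: str) -> list[CellSpec]:
    """Packaged cell specs: ``gist-nonsurgical``, ``gist-surgical``, ``gist-total``."""
    if spec_name == "gist-nonsurgical":
        t = REFERENCE_CROSSTABS["non-surgical"]
        return joint_from_marginals(t["nrs2002"], t["must"], surgical=False)
    if spec_name == "gist-surgical":
        t = REFERENCE_CROSSTABS["surgical"]
        return joint_from_marginals(t["nrs2002"], t["must"], surgical=True)
    if spec_name == "gist-total":
        return reference_cells("gist-surgical") + reference_cells("gist-nonsurgical")
    raise ValueError(
        f"unknown spec {spec_name!r}; expected gist-total, gist-surgical "
        f"or gist-nonsurgical"
    )


# --- archetype construction -------------------------------------------------
#
# Decisive-field plan (cancer-cohort GLIM mode, where the etiologic criterion
# always holds):
#   GLIM malnourished  <- low FFMI (16.0 male / 14.0 female; cutoffs 17 / 15)
#   GLIM well          <- normal FFMI (19.0 / 17.5); BMI 21.0 clears every BMI
#                         cutoff (20.5 NRS band top, 20 MUST/elderly-GLIM, 18.5)
#   NRS2002 high       <- intake in (0.5, 0.75] (nutrition 1) + disease 2
#                         (planned major abdominal surgery for surgical cells,
#                         pre-coded moderate severity for non-surgical)
#   NRS2002 low        <- full intake, severity <= 1; surgical cells keep the
#                         planned-surgery 2 points but age < 70 caps total at 2
#   MUST positive      <- 3-6-month weight loss in [6, 9]% (score 1, medium)
#   MUST low           <- no 3-6-month loss; BMI 21 scores 0; not acutely ill

_FFMI_LOW = {"male": 16.0, "female": 14.0}
_FFMI_NORMAL = {"male": 19.0, "female": 17.5}


def _archetype(cell: CellSpec, idx: int, rng: np.random.Generator) -> PatientRecord:
    sex = "male" if rng.random() < 0.483 else "female"
    nrs_high = cell.nrs_class == "high"
    must_pos = cell.must_class == "moderate_high"
    mal = cell.glim_status == "malnourished"

    # Age < 70 is required only where the NRS age point could flip a low cell
    # to high (surgical cells already carry 2 disease points).
    if cell.surgical and not nrs_high:
        age = int(rng.integers(29, 70))
    else:
        age = int(rng.integers(29, 89))

    height = float(rng.uniform(1.52, 1.60) if sex == "female" else rng.uniform(1.62, 1.82))
    bmi = 21.0
    ffmi = _FFMI_LOW[sex] if mal else _FFMI_NORMAL[sex]

    intake = float(rng.uniform(0.55, 0.70)) if nrs_high else float(rng.uniform(0.80, 1.0))
    severity = 0
    planned_surgery = False
    if cell.surgical:
        planned_surgery = True
    elif nrs_high:
        severity = 2
    else:
        severity = int(rng.integers(0, 2))  # 0 or 1: total stays below 3

    loss_3to6 = float(rng.uniform(6.0, 9.0)) if must_pos else 0.0

    albumin = float(rng.normal(35.8, 6.0) if mal else rng.normal(39.5, 5.5))
    hemoglobin = float(rng.normal(100.0, 25.0) if mal else rng.normal(113.0, 26.0))
    record = PatientRecord(
        patient_id=f"fx{idx:04d}",
        age=age,
        sex=sex,
        height=round(height, 3),
        weight=round(bmi * height**2, 2),
        ffm=round(ffmi * height**2, 2),
        weight_loss_pct_3to6mo=round(loss_3to6, 1),
        intake_fraction_past_week=round(intake, 2),
        intake_below_half_gt1wk=False,
        intake_reduced_ge2wk=bool(mal and rng.random() < 0.5),
        nrs_disease_severity=severity,
        planned_major_abdominal_surgery=planned_surgery,
        has_inflammatory_disease=True,  # GIST: chronic mild/moderate inflammation
        surgical_admission=cell.surgical,
        albumin=round(max(20.0, albumin), 1),
        hemoglobin=round(max(60.0, hemoglobin), 1),
        tumor_site=str(rng.choice(
            ["stomach", "small_intestine", "colorectum", "other"],
            p=[0.494, 0.335, 0.071, 0.100],
        )),
        risk_stratification=str(rng.choice(
            ["high", "medium", "low", "very_low"], p=[0.535, 0.171, 0.205, 0.089]
        )),
        targeted_therapy=bool(rng.random() < (0.38 if mal else 0.14)),
        n_symptoms=int(rng.choice(4, p=[0.17, 0.51, 0.27, 0.05])),
        los_days=(
            None if cell.surgical
            else float(max(1, round(rng.normal(12.21, 3.75) if mal
                                    else rng.normal(6.05, 2.50))))
        ),
        postop_los_days=(
            float(max(1, round(rng.normal(9.65, 6.0) if mal
                               else rng.normal(8.24, 4.24))))
            if cell.surgical else None
        ),
        complications=bool(rng.random() < (0.148 if cell.surgical else 0.075)),
    )
    return record


def generate_fixture_cohort(cells: Sequence[CellSpec], seed: int) -> Cohort:
    """Emit exactly ``count`` archetype patients per cell (deterministic given seed).

    Contract: scoring the output with NRS2002 and MUST and diagnosing GLIM in
    cancer-cohort mode, then rebuilding the cross-tabs, reproduces the
    requested counts cell-for-cell.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    idx = 0
    for cell in cells:
        for _ in range(cell.count):
            records.append(_archetype(cell, idx, rng))
            idx += 1
    return Cohort(records, provenance=f"fixture:seed={seed}")


# --- stochastic generation --------------------------------------------------


class StochasticParams(BaseModel):
    """Parameters of the stochastic cohort generator.

    Defaults describe the reference GIST inpatient population: malnutrition
    prevalence 86/269, surgical fraction 189/269, 51.7% women, group-wise age
    and BMI means +- SD, and a length-of-stay model in which malnutrition
    shifts the non-surgical mean stay from 6.05 +- 2.50 to 12.21 +- 3.75 days.
    Probabilities the source tables do not determine (weight-loss and
    intake-reduction rates by nutrition group, severity mix) are fixed
    clinically plausible values documented in the methods note.
    """

    n: int = Field(gt=0)
    seed: int
    prevalence: float = Field(default=86 / 269, ge=0, le=1)
    surgical_fraction: float = Field(default=189 / 269, ge=0, le=1)
    female_fraction: float = Field(default=0.517, ge=0, le=1)
    age_mean_well: float = 55.93
    age_sd_well: float = Field(default=11.34, gt=0)
    age_mean_mal: float = 59.23
    age_sd_mal: float = Field(default=13.65, gt=0)
    bmi_mean_well: float = 23.73
    bmi_sd_well: float = Field(default=2.40, gt=0)
    bmi_mean_mal: float = 19.98
    bmi_sd_mal: float = Field(default=2.62, gt=0)
    # FFMI normal(mean, sd) by sex and nutrition group
    ffmi_mean_male_well: float = 18.8
    ffmi_mean_male_mal: float = 16.2
    ffmi_mean_female_well: float = 16.8
    ffmi_mean_female_mal: float = 14.3
    ffmi_sd: float = Field(default=1.1, gt=0)
    # weight-loss / intake probabilities by nutrition group
    p_weight_loss_mal: float = Field(default=0.60, ge=0, le=1)
    p_weight_loss_well: float = Field(default=0.25, ge=0, le=1)
    p_intake_reduced_mal: float = Field(default=0.45, ge=0, le=1)
    p_intake_reduced_well: float = Field(default=0.10, ge=0, le=1)
    p_acutely_ill_mal: float = Field(default=0.05, ge=0, le=1)
    p_acutely_ill_well: float = Field(default=0.01, ge=0, le=1)
    # non-surgical disease-severity mix (classes 0, 1, 2)
    severity_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)
    # outcome model: length of stay, days (non-surgical)
    los_mean_well: float = 6.05
    los_sd_well: float = Field(default=2.50, gt=0)
    los_mean_mal: float = 12.21
    los_sd_mal: float = Field(default=3.75, gt=0)
    postop_mean_well: float = 8.24
    postop_sd_well: float = Field(default=4.24, gt=0)
    postop_mean_mal: float = 9.65
    postop_sd_mal: float = Field(default=6.0, gt=0)
    p_complication_surgical: float = Field(default=28 / 189, ge=0, le=1)
    p_complication_nonsurgical: float = Field(default=6 / 80, ge=0, le=1)


def _glim_bmi_cutoff(age: int) -> float:
    return 20.0 if age >= 70 else 18.5


def generate_stochastic_cohort(params: StochasticParams) -> Cohort:
    """Draw a reproducible cohort whose marginals follow ``params``.

    Each patient is first assigned a nutrition state (malnourished/well at the
    stated prevalence); features are then drawn group-conditionally such that,
    in cancer-cohort GLIM mode, malnourished patients meet at least one
    phenotypic criterion and well-nourished patients meet none — so observed
    GLIM prevalence is binomial around the parameter. Screening results
    emerge from the drawn features.
    """
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    for i in range(params.n):
        mal = bool(rng.random() < params.prevalence)
        surgical = bool(rng.random() < params.surgical_fraction)
        sex = "female" if rng.random() < params.female_fraction else "male"
        if mal:
            age = rng.normal(params.age_mean_mal, params.age_sd_mal)
        else:
            age = rng.normal(params.age_mean_well, params.age_sd_well)
        age = int(np.clip(round(age), 18, 90))
        height = float(
            rng.normal(1.56, 0.05) if sex == "female" else rng.normal(1.70, 0.06)
        )
        height = float(np.clip(height, 1.40, 1.95))
        cutoff = _glim_bmi_cutoff(age)

        if mal:
            bmi = float(rng.normal(params.bmi_mean_mal, params.bmi_sd_mal))
            bmi = float(np.clip(bmi, 13.0, 32.0))
            ffmi_mean = (
                params.ffmi_mean_male_mal if sex == "male"
                else params.ffmi_mean_female_mal
            )
            ffmi = float(rng.normal(ffmi_mean, params.ffmi_sd))
            loss6 = (
                float(rng.uniform(6.0, 15.0))
                if rng.random() < params.p_weight_loss_mal else 0.0
            )
            ffmi_low_cut = 17.0 if sex == "male" else 15.0
            if bmi >= cutoff and ffmi >= ffmi_low_cut and loss6 <= 5.0:
                loss6 = float(rng.uniform(6.0, 12.0))  # force >= one criterion
            intake_reduced = rng.random() < params.p_intake_reduced_mal
            acutely_ill = rng.random() < params.p_acutely_ill_mal
        else:
            bmi = float(rng.normal(params.bmi_mean_well, params.bmi_sd_well))
            bmi = float(np.clip(bmi, cutoff + 0.2, 35.0))
            ffmi_mean = (
                params.ffmi_mean_male_well if sex == "male"
                else params.ffmi_mean_female_well
            )
            ffmi_low_cut = 17.0 if sex == "male" else 15.0
            ffmi = float(
                np.clip(rng.normal(ffmi_mean, params.ffmi_sd), ffmi_low_cut + 0.2, 24.0)
            )
            loss6 = float(rng.uniform(0.0, 4.5)) if rng.random() < 0.3 else 0.0
            intake_reduced = rng.random() < params.p_intake_reduced_well
            acutely_ill = rng.random() < params.p_acutely_ill_well

        # correlated instrument-specific weight-loss windows
        loss_3mo = loss6 * float(rng.uniform(0.4, 0.9))
        loss_2mo = loss_3mo * float(rng.uniform(0.4, 0.8))
        loss_3to6 = loss6 * float(rng.uniform(0.5, 1.0))

        if intake_reduced:
            intake_fraction = float(rng.choice([0.2, 0.4, 0.6], p=[0.2, 0.4, 0.4]))
        else:
            intake_fraction = float(rng.choice([0.8, 1.0], p=[0.2, 0.8]))

        severity = 0 if surgical else int(rng.choice(3, p=list(params.severity_probs)))

        if surgical:
            postop = max(
                1.0,
                float(round(
                    rng.normal(params.postop_mean_mal, params.postop_sd_mal) if mal
                    else rng.normal(params.postop_mean_well, params.postop_sd_well)
                )),
            )
            los = None
            complication = rng.random() < params.p_complication_surgical
        else:
            los = max(
                1.0,
                float(round(
                    rng.normal(params.los_mean_mal, params.los_sd_mal) if mal
                    else rng.normal(params.los_mean_well, params.los_sd_well)
                )),
            )
            postop = None
            complication = rng.random() < params.p_complication_nonsurgical

        records.append(PatientRecord(
            patient_id=f"sim{i:05d}",
            age=age,
            sex=sex,
            height=round(height, 3),
            weight=round(bmi * height**2, 2),
            ffm=round(ffmi * height**2, 2),
            weight_loss_pct_1mo=0.0,
            weight_loss_pct_2mo=round(loss_2mo, 1),
            weight_loss_pct_3mo=round(loss_3mo, 1),
            weight_loss_pct_3to6mo=round(loss_3to6, 1),
            weight_loss_pct_within_6mo=round(loss6, 1),
            intake_fraction_past_week=intake_fraction,
            intake_below_half_gt1wk=intake_fraction <= 0.5,
            intake_reduced_ge2wk=bool(intake_reduced),
            gi_symptoms_impairing_assimilation=bool(
                rng.random() < (0.20 if mal else 0.05)
            ),
            acutely_ill_no_intake_gt5d=bool(acutely_ill),
            nrs_disease_severity=severity,
            planned_major_abdominal_surgery=surgical,
            impaired_general_condition=bool(mal and rng.random() < 0.5),
            has_inflammatory_disease=True,
            surgical_admission=surgical,
            albumin=round(max(15.0, float(
                rng.normal(35.8, 7.0) if mal else rng.normal(39.5, 6.0)
            )), 1),
            hemoglobin=round(max(40.0, float(
                rng.normal(100.4, 29.0) if mal else rng.normal(112.0, 28.0)
            )), 1),
            tumor_site=str(rng.choice(
                ["stomach", "small_intestine", "colorectum", "other"],
                p=[0.494, 0.335, 0.071, 0.100],
            )),
            risk_stratification=str(rng.choice(
                ["high", "medium", "low", "very_low"],
                p=[0.535, 0.171, 0.205, 0.089],
            )),
            targeted_therapy=bool(rng.random() < (0.38 if mal else 0.14)),
            n_symptoms=int(rng.choice(4, p=[0.17, 0.51, 0.27, 0.05])),
            los_days=los,
            postop_los_days=postop,
            complications=bool(complication),
        ))
    return Cohort(records, provenance=f"stochastic:seed={params.seed}")
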