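"""Full-cohort analysis orchestration and report rendering.

:func:`run_analysis` drives the whole pipeline over a cohort: score every
patient with NRS2002 and MUST, diagnose GLIM malnutrition, then per subgroup
(total / surgical / non-surgical by default) compute screen-positive
incidences, screen-vs-GLIM cross-tabs, the concordance panel (sensitivity,
specificity, predictive values, likelihood ratios, kappa with CI, ordinal-score
AUC), group comparisons of cohort characteristics by nutrition status, and
logistic outcome models on dichotomized length of stay and complications.

The report is a plain nested-dict structure: JSON rendering is lossless,
TSV/markdown mirror the conventional concordance-table layout (percentages to
1 d.p., kappa and AUC to 2 d.p.). Every percentage carries its numerator and
denominator. Deterministic given cohort + config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import Cohort
from .concordance import ConcordanceReport, crosstab_from_totals, full_panel
from .glim import diagnose_glim
from .instruments import score_must, score_nrs2002
from .outcomes import (
    compare_groups,
    dichotomize_outcome,
    fit_logistic,
    select_covariates,
)

logger = logging.getLogger(__name__)

INSTRUMENT_RULES = {"nrs2002": "nrs_ge3", "must": "must_ge1"}

DEFAULT_COMPARISON_VARIABLES = [
    "age", "sex", "bmi", "albumin", "hemoglobin", "tumor_site",
    "risk_stratification", "targeted_therapy", "n_symptoms",
]

DEFAULT_OUTCOME_COVARIATES = [
    "age", "sex", "bmi", "albumin", "hemoglobin", "tumor_site",
    "risk_stratification", "targeted_therapy", "n_symptoms",
    "nrs2002_positive", "must_positive", "glim_malnourished",
]


class AnalysisConfig(BaseModel):
    instruments: list[str] = Field(default=["nrs2002", "must"], min_length=1)
    glim_mode: str = "cancer_cohort"
    subgroups: dict[str, Optional[bool]] = Field(
        # name -> required value of surgical_admission (None = everyone)
        default={"total": None, "surgical": True, "non-surgical": False}
    )
    comparison_variables: list[str] = Field(
        default_factory=lambda: list(DEFAULT_COMPARISON_VARIABLES)
    )
    outcome_covariates: list[str] = Field(
        default_factory=lambda: list(DEFAULT_OUTCOME_COVARIATES)
    )
    selection_p_threshold: float = 0.05
    run_outcome_models: bool = True
    seed: int = 0

    def model_post_init(self, __context) -> None:
        unknown = set(self.instruments) - set(INSTRUMENT_RULES)
        if unknown:
            raise ValueError(f"unknown instrument(s): {sorted(unknown)}")


@dataclass
class StudyReport:
    incidence: dict = field(default_factory=dict)
    crosstabs: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    group_comparisons: dict = field(default_factory=dict)
    outcome_models: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def score_cohort(cohort: Cohort, glim_mode: str = "cancer_cohort") -> pd.DataFrame:
    """Per-patient analysis frame: instrument totals/classes, GLIM status,
    anthropometrics and outcome fields."""
    rows = []
    for rec in cohort:
        nrs = score_nrs2002(rec)
        must = score_must(rec)
        glim = diagnose_glim(rec, mode=glim_mode)
        rows.append({
            "patient_id": rec.patient_id,
            "age": rec.age,
            "sex": rec.sex.value,
            "bmi": rec.bmi,
            "ffmi": rec.ffmi,
            "albumin": rec.albumin,
            "hemoglobin": rec.hemoglobin,
            "tumor_site": rec.tumor_site.value if rec.tumor_site else None,
            "risk_stratification": (
                rec.risk_stratification.value if rec.risk_stratification else None
            ),
            "targeted_therapy": rec.targeted_therapy,
            "n_symptoms": rec.n_symptoms,
            "surgical": rec.surgical_admission,
            "nrs2002_total": nrs.total,
            "nrs2002_positive": nrs.high_risk,
            "must_total": must.total,
            "must_positive": must.positive,
            "glim_malnourished": glim.malnourished,
            "los_days": rec.los_days,
            "postop_los_days": rec.postop_los_days,
            "complications": rec.complications,
        })
    return pd.DataFrame(rows)


def _panel_dict(panel: ConcordanceReport) -> dict:
    def metric(m, scale=1.0):
        if m.defined:
            return {"value": m.value * scale}
        return {"value": None, "reason": m.reason}

    t = panel.table
    out = {
        "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "n": t.n},
        "sensitivity_pct": metric(panel.sensitivity, 100.0),
        "specificity_pct": metric(panel.specificity, 100.0),
        "ppv_pct": metric(panel.ppv, 100.0),
        "npv_pct": metric(panel.npv, 100.0),
        "lr_pos": metric(panel.lr_pos),
        "lr_neg": metric(panel.lr_neg),
        "kappa": metric(panel.kappa),
        "kappa_ci": list(panel.kappa_ci) if panel.kappa_ci else None,
        "kappa_band": panel.kappa_band,
        "auc": metric(panel.auc),
        "auc_band": panel.auc_band,
    }
    return out


def _comparison_dict(comp) -> dict:
    return {
        "variable": comp.variable,
        "test": comp.test,
        "group_summaries": comp.group_summaries,
        "statistic": comp.statistic,
        "p_value": comp.p_value,
        "reason": comp.reason,
    }


def _fit_dict(fit) -> dict:
    return {
        "covariates": fit.covariates,
        "converged": fit.converged,
        "note": fit.note,
        "reference_levels": fit.reference_levels,
        "effects": [
            {
                "term": e.term,
                "odds_ratio": e.odds_ratio,
                "ci": list(e.ci),
                "p_value": e.p_value,
            }
            for e in fit.effects
        ],
    }


def _outcome_block(df: pd.DataFrame, outcome_col: str, covariates, threshold) -> dict:
    values = df[outcome_col]
    if values.notna().sum() == 0:
        return {"absent": True, "reason": f"no non-missing {outcome_col}"}
    flags, cutoff = dichotomize_outcome(values.tolist())
    work = df.copy()
    work["_long_stay"] = pd.Series(flags, index=df.index, dtype=object)
    covs = [c for c in covariates if c in work.columns]
    uni = fit_logistic(work, "_long_stay", covs, mode="univariate")
    selected = select_covariates(uni, threshold)
    block = {
        "outcome": outcome_col,
        "dichotomization_cutoff": cutoff,
        "univariate": {f.covariates[0]: _fit_dict(f) for f in uni},
    }
    if selected:
        multi = fit_logistic(work, "_long_stay", selected, mode="multivariate")[0]
        block["multivariate"] = _fit_dict(multi)
    else:
        block["multivariate"] = {
            "absent": True, "reason": "no covariate passed univariate selection"
        }
    return block


def run_analysis(cohort: Cohort, config: Optional[AnalysisConfig] = None) -> StudyReport:
    """Run the complete screening/diagnosis/concordance/outcome analysis."""
    config = config or AnalysisConfig()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    df = score_cohort(cohort, glim_mode=config.glim_mode).sort_values(
        "patient_id", kind="stable"
    ).reset_index(drop=True)

    report = StudyReport()
    config_json = config.model_dump_json()
    report.provenance = {
        "software_version": __version__,
        "cohort_provenance": cohort.provenance,
        "n_patients": len(cohort),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest()[:16],
        "glim_mode": config.glim_mode,
    }

    for name, surgical_value in config.subgroups.items():
        sub = df if surgical_value is None else df[df["surgical"] == surgical_value]
        logger.info("subgroup %s: %d patients", name, len(sub))
        if len(sub) == 0:
            for inst in config.instruments:
                report.incidence.setdefault(inst, {})[name] = {
                    "absent": True, "reason": "subgroup has zero patients"
                }
            continue
        glim_status = sub["glim_malnourished"].tolist()
        for inst in config.instruments:
            totals = sub[f"{inst}_total"].tolist()
            positive = sub[f"{inst}_positive"]
            num = int(positive.sum())
            den = len(sub)
            report.incidence.setdefault(inst, {})[name] = {
                "numerator": num,
                "denominator": den,
                "pct": 100.0 * num / den,
            }
            if len(set(glim_status)) < 2 or den < 2:
                report.concordance.setdefault(inst, {})[name] = {
                    "absent": True,
                    "reason": "degenerate subgroup (single GLIM class or n < 2)",
                }
                continue
            table = crosstab_from_totals(
                totals, glim_status, positivity_rule=INSTRUMENT_RULES[inst]
            )
            report.crosstabs.setdefault(inst, {})[name] = {
                "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
            }
            panel = full_panel(table, scores=totals, glim_status=glim_status)
            report.concordance.setdefault(inst, {})[name] = _panel_dict(panel)

        # group comparisons by GLIM status
        if len(set(glim_status)) == 2:
            variables = [v for v in config.comparison_variables if v in sub.columns]
            try:
                comps = compare_groups(sub, "glim_malnourished", variables)
                report.group_comparisons[name] = [_comparison_dict(c) for c in comps]
            except ValueError as exc:
                report.group_comparisons[name] = {"absent": True, "reason": str(exc)}
        else:
            report.group_comparisons[name] = {
                "absent": True, "reason": "single GLIM class"
            }

        # outcome models: LOS for non-surgical-style subgroups, postoperative
        # stay for surgical ones; skipped for mixed subgroups such as total.
        if config.run_outcome_models and surgical_value is not None:
            outcome_col = "postop_los_days" if surgical_value else "los_days"
            report.outcome_models[name] = _outcome_block(
                sub, outcome_col, config.outcome_covariates,
                config.selection_p_threshold,
            )

    return report


def _fmt(x, nd=1):
    return "" if x is None else f"{x:.{nd}f}"


_TSV_HEADER = [
    "instrument", "subgroup", "tp", "fp", "fn", "tn",
    "sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct",
    "lr_pos", "lr_neg", "kappa", "kappa_ci_low", "kappa_ci_high", "auc",
]


def render_report(report: StudyReport, format: str = "json") -> str:
    """Render a report as lossless JSON, concordance-panel TSV, or markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)

    rows = []
    for inst, by_group in sorted(report.concordance.items()):
        for group, panel in sorted(by_group.items()):
            if panel.get("absent"):
                continue
            t = panel["table"]
            ci = panel.get("kappa_ci") or (None, None)
            rows.append([
                inst, group, t["tp"], t["fp"], t["fn"], t["tn"],
                _fmt(panel["sensitivity_pct"]["value"]),
                _fmt(panel["specificity_pct"]["value"]),
                _fmt(panel["ppv_pct"]["value"]),
                _fmt(panel["npv_pct"]["value"]),
                _fmt(panel["lr_pos"]["value"], 2),
                _fmt(panel["lr_neg"]["value"], 2),
                _fmt(panel["kappa"]["value"], 2),
                _fmt(ci[0], 2), _fmt(ci[1], 2),
                _fmt(panel["auc"]["value"], 2),
            ])

    if format == "tsv":
        lines = ["\t".join(_TSV_HEADER)]
        lines += ["\t".join(str(c) for c in row) for row in rows]
        return "\n".join(lines) + "\n"
    if format == "markdown":
        lines = [
            "| " + " | ".join(_TSV_HEADER) + " |",
            "|" + "---|" * len(_TSV_HEADER),
        ]
        lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")
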