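"""Diagnostic-consistency statistics: 2x2 cross-tabulation of a screening
instrument against the GLIM reference diagnosis, sensitivity/specificity/
predictive values/likelihood ratios, Cohen's kappa with a Wald confidence
interval, and ROC/AUC on the raw ordinal score totals.

Degenerate metrics (zero denominators) are reported as absent with a reason,
never as 0 — a screen with no GLIM-malnourished patients has an undefined, not
a zero, sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

# Agreement bands for kappa and accuracy bands for AUC, as conventionally
# interpreted in the diagnostic-screening literature.
KAPPA_BANDS = (
    (0.21, "none"),
    (0.40, "minimal"),
    (0.60, "weak"),
    (0.80, "moderate"),
    (0.901, "strong"),
    (np.inf, "almost_perfect"),
)


def kappa_band(kappa: float) -> str:
    """Interpretation band: 0-0.20 none, 0.21-0.39 minimal, 0.40-0.59 weak,
    0.60-0.79 moderate, 0.80-0.90 strong, above 0.9 almost perfect."""
    for upper, name in KAPPA_BANDS:
        if kappa < upper:
            return name
    return "almost_perfect"


def auc_band(auc: float) -> str:
    """Accuracy band: low 0.50-0.69, moderate 0.70-0.90, high above 0.9."""
    if auc < 0.70:
        return "low"
    if auc <= 0.90:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Screen-vs-reference agreement counts.

    ``tp``: screen-positive and malnourished; ``fp``: screen-positive and
    well-nourished; ``fn``: screen-negative and malnourished; ``tn``:
    screen-negative and well-nourished.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)


@dataclass(frozen=True)
class MetricValue:
    """A metric that is either a number or absent with a reason."""

    value: Optional[float]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class ConcordanceReport:
    """Full metric panel for one instrument against GLIM in one subgroup.

    Proportion metrics are stored as fractions in [0, 1]; rendering converts
    to percent with 1 d.p. (kappa and AUC to 2 d.p.), full precision retained
    here.
    """

    table: ContingencyTable2x2
    sensitivity: MetricValue = field(default=MetricValue(None))
    specificity: MetricValue = field(default=MetricValue(None))
    ppv: MetricValue = field(default=MetricValue(None))
    npv: MetricValue = field(default=MetricValue(None))
    lr_pos: MetricValue = field(default=MetricValue(None))
    lr_neg: MetricValue = field(default=MetricValue(None))
    kappa: MetricValue = field(default=MetricValue(None))
    kappa_ci: Optional[tuple[float, float]] = None
    kappa_band: Optional[str] = None
    auc: MetricValue = field(default=MetricValue(None))
    auc_band: Optional[str] = None
    roc_points: Optional[list[tuple[float, float, float]]] = None


POSITIVITY_RULES = ("nrs_ge3", "must_ge1")


def build_crosstab(
    screen_positive: Sequence[bool],
    glim_status: Sequence[bool],
) -> ContingencyTable2x2:
    """Cross-tabulate aligned per-patient screen positivity against GLIM status."""
    if len(screen_positive) != len(glim_status):
        raise ValueError(
            f"length mismatch: {len(screen_positive)} screens vs "
            f"{len(glim_status)} GLIM statuses"
        )
    if len(screen_positive) == 0:
        raise ValueError("empty input")
    s = np.asarray(screen_positive, dtype=bool)
    g = np.asarray(glim_status, dtype=bool)
    return ContingencyTable2x2(
        tp=int(np.sum(s & g)),
        fp=int(np.sum(s & ~g)),
        fn=int(np.sum(~s & g)),
        tn=int(np.sum(~s & ~g)),
    )


def crosstab_from_totals(
    totals: Sequence[int],
    glim_status: Sequence[bool],
    positivity_rule: str = "nrs_ge3",
    custom_threshold: Optional[int] = None,
) -> ContingencyTable2x2:
    """Cross-tabulate ordinal score totals under a positivity rule.

    ``nrs_ge3``: total >= 3 (high nutritional risk); ``must_ge1``: total >= 1
    (moderate/high risk); or a custom at-or-above threshold.
    """
    if custom_threshold is not None:
        cut = custom_threshold
    elif positivity_rule == "nrs_ge3":
        cut = 3
    elif positivity_rule == "must_ge1":
        cut = 1
    else:
        raise ValueError(
            f"unknown positivity rule {positivity_rule!r}; "
            f"expected one of {POSITIVITY_RULES} or a custom threshold"
        )
    positive = [t >= cut for t in totals]
    return build_crosstab(positive, glim_status)


def _ratio(num: float, den: float, what: str) -> MetricValue:
    if den == 0:
        return MetricValue(None, f"undefined (division by zero) for {what}")
    return MetricValue(num / den)


def diagnostic_metrics(table: ContingencyTable2x2) -> ConcordanceReport:
    """Sensitivity, specificity, PPV, NPV and likelihood ratios for a 2x2 table.

    ``lr_pos = sens / (1 - spec)`` (undefined at specificity 1);
    ``lr_neg = (1 - sens) / spec`` (undefined at specificity 0). No continuity
    correction is applied to zero cells.
    """
    t = table
    report = ConcordanceReport(table=t)
    report.sensitivity = _ratio(t.tp, t.tp + t.fn, "sensitivity (no malnourished)")
    report.specificity = _ratio(t.tn, t.tn + t.fp, "specificity (no well-nourished)")
    report.ppv = _ratio(t.tp, t.tp + t.fp, "PPV (no screen-positives)")
    report.npv = _ratio(t.tn, t.tn + t.fn, "NPV (no screen-negatives)")

    if report.sensitivity.defined and report.specificity.defined:
        sens = report.sensitivity.value
        spec = report.specificity.value
        report.lr_pos = _ratio(sens, 1.0 - spec, "LR+ (specificity = 1)")
        report.lr_neg = _ratio(1.0 - sens, spec, "LR- (specificity = 0)")
    else:
        reason = "undefined (sensitivity or specificity undefined)"
        report.lr_pos = MetricValue(None, reason)
        report.lr_neg = MetricValue(None, reason)
    return report


def _po_pe(table: ContingencyTable2x2) -> tuple[float, float]:
    n = table.n
    p_o = (table.tp + table.tn) / n
    p_e = (
        (table.tp + table.fp) * (table.tp + table.fn)
        + (table.fn + table.tn) * (table.fp + table.tn)
    ) / n**2
    return p_o, p_e


def cohens_kappa(table: ContingencyTable2x2) -> MetricValue:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement proportion and ``p_e`` the agreement
    expected from the two marginal distributions. Absent when ``p_e`` is 1
    (both raters degenerate on the same class).
    """
    if table.n < 2:
        raise ValueError("kappa requires n >= 2")
    p_o, p_e = _po_pe(table)
    if p_e == 1.0:
        return MetricValue(None, "undefined (chance agreement is 1)")
    return MetricValue((p_o - p_e) / (1.0 - p_e))


def kappa_ci(table: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval kappa +- z * SE, clipped to [-1, 1], with
    SE = sqrt[p_o (1 - p_o) / (n (1 - p_e)^2)]."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    k = cohens_kappa(table)
    if not k.defined:
        raise ValueError("kappa CI undefined: chance agreement is 1")
    p_o, p_e = _po_pe(table)
    se = np.sqrt(p_o * (1.0 - p_o) / (table.n * (1.0 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(-1.0, float(k.value - z * se))
    hi = min(1.0, float(k.value + z * se))
    return (lo, hi)


def auc_ordinal(
    scores: Sequence[float], glim_status: Sequence[bool]
) -> tuple[float, list[tuple[float, float, float]]]:
    """AUC of an ordinal score against the binary reference, with ROC points.

    The AUC is the tie-corrected rank statistic
    P(score_mal > score_well) + 0.5 * P(tie), computed from midranks — the
    Mann-Whitney U divided by n1*n0 — which equals the trapezoidal area over
    all unique thresholds. ROC points (threshold, fpr, tpr) are returned for
    every threshold of the form "score >= t", t over unique scores plus a
    sentinel above the maximum.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(glim_status, dtype=bool)
    if scores.shape != status.shape:
        raise ValueError("scores and statuses must be aligned")
    n1 = int(status.sum())
    n0 = int((~status).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one patient in each class")

    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[status].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    points: list[tuple[float, float, float]] = []
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    for t in thresholds:
        pos = scores >= t
        tpr = np.sum(pos & status) / n1
        fpr = np.sum(pos & ~status) / n0
        points.append((float(t), float(fpr), float(tpr)))
    return float(auc), points


def full_panel(
    table: ContingencyTable2x2,
    scores: Optional[Sequence[float]] = None,
    glim_status: Optional[Sequence[bool]] = None,
    ci_level: float = 0.95,
) -> ConcordanceReport:
    """Assemble the complete concordance panel for one instrument/subgroup."""
    report = diagnostic_metrics(table)
    if table.n >= 2:
        report.kappa = cohens_kappa(table)
        if report.kappa.defined:
            report.kappa_ci = kappa_ci(table, ci_level)
            report.kappa_band = kappa_band(report.kappa.value)
    else:
        report.kappa = MetricValue(None, "undefined (n < 2)")
    if scores is not None and glim_status is not None:
        try:
            auc, points = auc_ordinal(scores, glim_status)
            report.auc = MetricValue(auc)
            report.auc_band = auc_band(auc)
            report.roc_points = points
        except ValueError as exc:
            report.auc = MetricValue(None, f"undefined ({exc})")
    return report
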