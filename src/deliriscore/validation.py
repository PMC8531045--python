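"""External validation of a risk score on an independent cohort.

Produces the tie-aware ROC curve and exact AUC, a cutoff table
(positivity rule: score >= cutoff), the per-point odds ratio from a
logistic fit of the outcome on the integer score, and the no-dementia
subgroup per-point odds ratio (the score remains applicable there; with the
published weights its attainable maximum drops from 8 to 5 once the
3-point dementia component cannot fire).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort
from .errors import ValidationStageError
from .search import ExactAUC, ScoreDefinition, apply_score, exact_auc

logger = logging.getLogger(__name__)


@dataclass
class CutoffRow:
    """Classification performance of the rule 'positive iff score >= cutoff'."""

    cutoff: int
    sensitivity: float
    specificity: float
    ppv: Optional[float]  # None when no positive calls
    npv: Optional[float]  # None when no negative calls
    n_positive_calls: int


@dataclass
class EffectEstimate:
    """Odds ratio with Wald 95% CI and p from a logistic fit."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
        }


@dataclass
class ValidationReport:
    label: str
    score: ScoreDefinition
    auc: ExactAUC
    roc: list[tuple[float, float, float]]  # (fpr, tpr, cutoff)
    cutoff_table: list[CutoffRow]
    per_point_or: EffectEstimate
    subgroup_no_dementia: Optional[EffectEstimate]
    prevalence: float
    score_min: int
    score_median: float
    score_max: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "score": self.score.to_dict(),
            "auc": self.auc.to_dict(),
            "roc": [list(p) for p in self.roc],
            "cutoff_table": [
                {
                    "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "ppv": r.ppv,
                    "npv": r.npv,
                    "n_positive_calls": r.n_positive_calls,
                }
                for r in self.cutoff_table
            ],
            "per_point_or": self.per_point_or.to_dict(),
            "subgroup_no_dementia": (
                self.subgroup_no_dementia.to_dict()
                if self.subgroup_no_dementia is not None
                else None
            ),
            "prevalence": self.prevalence,
            "score_distribution": {
                "min": self.score_min,
                "median": self.score_median,
                "max": self.score_max,
            },
        }

    def to_markdown(self) -> str:
        lines = [
            f"# Validation report — {self.label}",
            "",
            f"Score components: "
            + ", ".join(f"{n} ({w} pt)" for n, w in self.score.components),
            f"Patients: {self.auc.n_pos + self.auc.n_neg} "
            f"(delirium prevalence {self.prevalence:.3f})",
            f"AUC: {self.auc.value:.3f} "
            f"({self.auc.doubled_numerator}/{2 * self.auc.n_pos * self.auc.n_neg})",
            f"Score distribution: min {self.score_min}, median {self.score_median:g}, "
            f"max {self.score_max}",
            "",
            "| cutoff | sensitivity | specificity | ppv | npv |",
            "|---|---|---|---|---|",
        ]
        for r in self.cutoff_table:
            ppv = "undefined" if r.ppv is None else f"{r.ppv:.3f}"
            npv = "undefined" if r.npv is None else f"{r.npv:.3f}"
            lines.append(
                f"| >= {r.cutoff} | {r.sensitivity:.3f} | {r.specificity:.3f} "
                f"| {ppv} | {npv} |"
            )
        e = self.per_point_or
        lines += [
            "",
            f"Per-point OR: {e.odds_ratio:.2f} "
            f"(95% CI {e.ci_low:.2f}–{e.ci_high:.2f}, p={e.p_value:.3g})",
        ]
        if self.subgroup_no_dementia is not None:
            s = self.subgroup_no_dementia
            lines.append(
                f"Per-point OR, no-dementia subgroup: {s.odds_ratio:.2f} "
                f"(95% CI {s.ci_low:.2f}–{s.ci_high:.2f}, p={s.p_value:.3g})"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray) -> None:
    if y.min() == y.max():
        raise ValidationStageError("outcome has a single class")


def cutoff_table(scores: Sequence[int], outcomes: Sequence[int]) -> list[CutoffRow]:
    """One row per integer cutoff from min(score) to max(score)+1.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); ppv/npv are None
    (undefined), never 0, when their denominator vanishes.
    """
    s = np.asarray(scores, dtype=np.int64)
    y = np.asarray(outcomes, dtype=np.int64)
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    rows = []
    for cutoff in range(int(s.min()), int(s.max()) + 2):
        pred = s >= cutoff
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        rows.append(
            CutoffRow(
                cutoff=cutoff,
                sensitivity=tp / n_pos,
                specificity=tn / n_neg,
                ppv=(tp / (tp + fp)) if (tp + fp) else None,
                npv=(tn / (tn + fn)) if (tn + fn) else None,
                n_positive_calls=tp + fp,
            )
        )
    return rows


def roc_points(scores: Sequence[int], outcomes: Sequence[int]) -> list[tuple[float, float, float]]:
    """Tie-aware ROC polygon: one vertex per distinct score threshold,
    from (0,0) (no one called positive) to (1,1) (everyone positive).

    The trapezoidal area under this polygon equals the Mann–Whitney AUC.
    """
    s = np.asarray(scores)
    y = np.asarray(outcomes, dtype=np.int64)
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    vals = np.unique(s)[::-1]
    pts = [(0.0, 0.0, float(vals[0]) + 1.0)]
    for v in vals:
        pred = s >= v
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        pts.append((fp / n_neg, tp / n_pos, float(v)))
    return pts


def trapezoid_area(roc: Sequence[tuple[float, float, float]]) -> float:
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def youden_cutoff(rows: Sequence[CutoffRow]) -> int:
    """Cutoff maximizing sensitivity + specificity - 1 (lowest cutoff wins ties)."""
    best = max(rows, key=lambda r: (r.sensitivity + r.specificity, -r.cutoff))
    return best.cutoff


def per_point_or(scores: Sequence[int], outcomes: Sequence[int]) -> EffectEstimate:
    """Logistic fit of the outcome on the integer score as one continuous
    covariate; OR per 1-point increase with Wald CI and p."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_two_classes(y.astype(int))
    if np.all(s == s[0]):
        raise ValidationStageError("degenerate score: single value")
    fit = sm.Logit(y, sm.add_constant(s)).fit(disp=0, method="newton", maxiter=200, tol=1e-10)
    ci = fit.conf_int()[1]
    return EffectEstimate(
        odds_ratio=float(np.exp(fit.params[1])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(fit.pvalues[1]),
        n_used=len(s),
    )


def subgroup_no_dementia(
    cohort: Cohort, score: ScoreDefinition, dementia_var: str = "dementia"
) -> EffectEstimate:
    """Per-point OR recomputed on the dementia-free subgroup.

    Scores are recomputed after filtering; a dementia component contributes 0
    by construction, so with the published weights the attainable maximum
    drops by the dementia points.
    """
    if not cohort.has_variable(dementia_var):
        raise ValidationStageError(f"variable {dementia_var!r} not in cohort")
    sub = cohort.subset(cohort.values(dementia_var) == 0, label_suffix="_no_dementia")
    y = sub.outcome()
    if len(y) == 0 or y.min() == y.max():
        raise ValidationStageError("no-dementia subgroup outcome has a single class")
    return per_point_or(apply_score(score, sub), y)


def build_report(
    cohort: Cohort, score: ScoreDefinition, dementia_var: str = "dementia"
) -> ValidationReport:
    """Assemble the full validation report for one cohort."""
    s = apply_score(score, cohort)
    y = cohort.outcome()
    auc = exact_auc(s, y)
    try:
        sub = subgroup_no_dementia(cohort, score, dementia_var)
    except ValidationStageError as e:
        logger.info("subgroup analysis skipped (%s): %s", cohort.label, e)
        sub = None
    return ValidationReport(
        label=cohort.label,
        score=score,
        auc=auc,
        roc=roc_points(s, y),
        cutoff_table=cutoff_table(s, y),
        per_point_or=per_point_or(s, y),
        subgroup_no_dementia=sub,
        prevalence=float(np.mean(y)),
        score_min=int(s.min()),
        score_median=float(np.median(s)),
        score_max=int(s.max()),
    )


def write_report(report: ValidationReport, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write report JSON + markdown summary + ROC points TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_dir / f"{stem}.json",
        "md": out_dir / f"{stem}.md",
        "roc": out_dir / f"{stem}_roc.tsv",
    }
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    paths["md"].write_text(report.to_markdown())
    with open(paths["roc"], "w") as fh:
        fh.write("fpr\ttpr\tcutoff\n")
        for fpr, tpr, cutoff in report.roc:
            fh.write(f"{fpr!r}\t{tpr!r}\t{cutoff:g}\n")
    return paths
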