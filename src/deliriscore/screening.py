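"""Univariate candidate screening.

Each candidate predictor is screened with an unadjusted logistic regression
of the delirium outcome on that single variable, reporting the odds ratio,
Wald 95% confidence interval, Wald p-value and the tie-aware rank AUC of the
predictor.  Candidates with p <= alpha (default 0.200) are selected; where a
continuous variable and its clinical dichotomization both pass, only the
dichotomized (binary) form is retained, since score components must be
binary flags.

Separation — a zero cell in a binary predictor's 2x2 table, or a
non-converging fit — is reported with the Haldane–Anscombe continuity
correction (0.5 added to every cell) and flagged; flagged variables stay
eligible for selection rather than being silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import BINARY, CONTINUOUS, Cohort, Dichotomization, VariableSpec
from .errors import ScreeningError
from .search import exact_auc

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.200

#: Continuous candidate -> preferred dichotomized flag, matching the
#: clinical cutoffs in the default registry.
DEFAULT_DEDUP = {
    "age": "age_ge75",
    "systolic_bp": "systolic_bp_lt120",
    "sodium": "sodium_lt135",
}

SEPARATION_FLAG = "separation_detected"
NONCONVERGENCE_FLAG = "non_convergence"


@dataclass
class ScreeningResult:
    """One screening-table row (odds ratio, 95% CI, p, AUC)."""

    variable: str
    n_used: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    auc: float
    kind: str = BINARY
    selected: bool = False
    flags: set[str] = field(default_factory=set)


def dichotomize(cohort: Cohort, variable: str, cutoff: float, direction: str) -> Cohort:
    """Add the binary flag ``<variable>_<direction><cutoff>``.

    ge: flag = 1 iff value >= cutoff; lt: flag = 1 iff value < cutoff.
    Missing values stay missing.
    """
    spec = cohort.spec(variable)
    if spec.kind != CONTINUOUS:
        raise TypeError(f"dichotomize expects a continuous variable, {variable!r} is {spec.kind}")
    d = Dichotomization(cutoff, direction)
    x = cohort.values(variable)
    flag = (x >= cutoff) if direction == "ge" else (x < cutoff)
    vals = np.where(np.isnan(x), np.nan, flag.astype(float))
    name = f"{variable}{d.flag_name_suffix}"
    return cohort.with_variable(VariableSpec(name, BINARY, role=spec.role), vals)


def dichotomize_registry(cohort: Cohort) -> tuple[Cohort, dict[str, str]]:
    """Apply every registry-declared dichotomization; returns the augmented
    cohort and the continuous->flag dedup map it induces."""
    dedup: dict[str, str] = {}
    out = cohort
    for v in cohort.registry:
        if v.dichotomization is not None:
            d = v.dichotomization
            out = dichotomize(out, v.name, d.cutoff, d.direction)
            dedup[v.name] = f"{v.name}{d.flag_name_suffix}"
    return out, dedup


def _haldane_anscombe(a: float, b: float, c: float, d: float):
    """OR, Wald CI and p from a 2x2 table with 0.5 added to each cell.

    Cells: a = exposed cases, b = exposed non-cases, c = unexposed cases,
    d = unexposed non-cases.
    """
    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * norm.sf(abs(z))
    lo, hi = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return float(np.exp(log_or)), float(lo), float(hi), float(p)


def fit_univariate_logistic(cohort: Cohort, variable: str) -> ScreeningResult:
    """Unadjusted logistic fit of the outcome on one predictor.

    For a single binary predictor the ML odds ratio equals the 2x2
    cross-product ratio; separation falls back to the Haldane–Anscombe
    corrected table with a flag.  AUC is the tie-aware Mann–Whitney rank AUC
    of the raw predictor values against the outcome.
    """
    spec = cohort.spec(variable)
    y_all = cohort.outcome().astype(float)
    x_all = cohort.values(variable)
    ok = ~(np.isnan(x_all) | np.isnan(y_all))
    x, y = x_all[ok], y_all[ok]
    n_used = int(ok.sum())
    if n_used == 0 or len(np.unique(y)) < 2:
        raise ScreeningError(f"degenerate outcome for variable {variable!r}")
    if np.all(x == x[0]):
        raise ScreeningError(f"constant predictor {variable!r}")

    auc = exact_auc(x, y.astype(int)).value
    flags: set[str] = set()

    is_binary = spec.kind == BINARY
    if is_binary:
        a = float(np.sum((x == 1) & (y == 1)))
        b = float(np.sum((x == 1) & (y == 0)))
        c = float(np.sum((x == 0) & (y == 1)))
        d = float(np.sum((x == 0) & (y == 0)))
        if min(a, b, c, d) == 0:
            flags.add(SEPARATION_FLAG)
            orr, lo, hi, p = _haldane_anscombe(a, b, c, d)
            return ScreeningResult(variable, n_used, orr, lo, hi, p, auc,
                                   kind=spec.kind, flags=flags)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(x)).fit(
                disp=0, method="newton", maxiter=200, tol=1e-10)
            converged = bool(fit.mle_retvals.get("converged", True))
            slope = float(fit.params[1])
        except Exception:
            converged, slope = False, np.inf
    if not converged or abs(slope) > 15:
        if is_binary:
            flags.add(SEPARATION_FLAG)
            orr, lo, hi, p = _haldane_anscombe(a, b, c, d)
            return ScreeningResult(variable, n_used, orr, lo, hi, p, auc,
                                   kind=spec.kind, flags=flags)
        flags.add(NONCONVERGENCE_FLAG)
        return ScreeningResult(variable, n_used, float(np.exp(slope)),
                               np.nan, np.nan, np.nan, auc, kind=spec.kind, flags=flags)

    ci = fit.conf_int()[1]
    return ScreeningResult(
        variable,
        n_used,
        float(np.exp(slope)),
        float(np.exp(ci[0])),
        float(np.exp(ci[1])),
        float(fit.pvalues[1]),
        auc,
        kind=spec.kind,
        flags=flags,
    )


def screen_candidates(
    results: Sequence[ScreeningResult],
    alpha: float = DEFAULT_ALPHA,
    dedup: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Select candidates with p <= alpha and return binary candidate names.

    The threshold is inclusive.  ``dedup`` maps a continuous variable to its
    dichotomized flag; when both pass, only the flag is kept.  Output order
    follows the input (registry) order, and only binary variables — the
    admissible score components — are returned.  ``selected`` flags on the
    result rows are updated in place.
    """
    if not results:
        raise ScreeningError("no screening results to select from")
    dedup = DEFAULT_DEDUP if dedup is None else dict(dedup)
    by_name = {r.variable: r for r in results}
    for r in results:
        r.selected = bool(r.p_value <= alpha) if np.isfinite(r.p_value) else False
    for cont, flag in dedup.items():
        if cont in by_name and flag in by_name:
            if by_name[cont].selected and by_name[flag].selected:
                by_name[cont].selected = False
    return [r.variable for r in results if r.selected and r.kind == BINARY]


def screen_cohort(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    candidates: Optional[Sequence[str]] = None,
) -> tuple[list[ScreeningResult], list[str]]:
    """Full screening stage on one cohort.

    Applies registry dichotomizations, fits every candidate univariately,
    applies the p <= alpha selection with continuous/flag deduplication, and
    returns (table rows, selected binary candidate names).
    """
    work, dedup = dichotomize_registry(cohort)
    if candidates is None:
        base = cohort.candidate_names()
        extra = [dedup[c] for c in base if c in dedup]
        candidates = base + [e for e in extra if e not in base]
    results = [fit_univariate_logistic(work, v) for v in candidates]
    selected = screen_candidates(results, alpha=alpha, dedup=dedup or None)
    logger.info("screening: %d candidates fitted, %d selected at p <= %g",
                len(results), len(selected), alpha)
    return results, selected


def screening_table(results: Sequence[ScreeningResult]):
    """Screening rows as a pandas DataFrame (the screening-report CSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "n": [r.n_used for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "auc": [r.auc for r in results],
            "kind": [r.kind for r in results],
            "selected": [r.selected for r in results],
            "flags": [";".join(sorted(r.flags)) for r in results],
        }
    )
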