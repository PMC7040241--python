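"""Diagnostic-accuracy statistics for dichotomized risk scores.

This module provides the 2x2-table machinery used to evaluate the ultrasound,
genomic and total risk scores: confusion matrices from score/label vectors,
sensitivity/specificity/PPV/NPV with Wilson score confidence intervals, the
balanced diagnostic accuracy (sensitivity + specificity)/2 — which for a
single-threshold test equals its ROC AUC — odds ratios with log-normal (Woolf)
intervals, cutoff selection, subgroup exclusion, proportion comparisons, and
exhaustive reconstruction of integer 2x2 tables from published rounded
percentages.

Undefined metrics (zero denominator) are represented by ``None``, never by a
silent 0: small-strata subgroup analyses hit empty margins routinely.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2, mcnemar
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .errors import ThyriskError, ValidationError
from .risk import SCORE_TOL, Truth, ge


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 table of a dichotomized test against histology truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError("bad-cell", f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValidationError("empty-matrix", "confusion matrix has zero total")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def malignant_margin(self) -> int:
        return self.tp + self.fn

    @property
    def benign_margin(self) -> int:
        return self.fp + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


def confusion_from_scores(
    scores: Sequence[float],
    truths: Sequence[Truth | str],
    cutoff: float,
    tol: float = SCORE_TOL,
) -> ConfusionMatrix:
    """Tally a confusion matrix, test-positive iff ``score >= cutoff``.

    The comparison uses the decimal-lattice tolerance shared with the
    management algorithm so 0.2 + 0.5 counts as >= 0.7.
    """
    if len(scores) != len(truths):
        raise ValidationError(
            "length-mismatch", f"{len(scores)} scores vs {len(truths)} truths"
        )
    if len(scores) == 0:
        raise ValidationError("empty-input", "no scores given")
    tp = fp = fn = tn = 0
    for s, t in zip(scores, truths):
        malignant = Truth(t) is Truth.MALIGNANT
        positive = ge(float(s), cutoff, tol)
        if malignant:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_ci(
    successes: int, trials: int, confidence_level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Endpoints lie in [0, 1] and the interval always contains the point
    estimate ``successes/trials``.
    """
    if trials <= 0:
        raise ValidationError("zero-trials", "Wilson interval needs trials > 0")
    if not 0 <= successes <= trials:
        raise ValidationError("bad-successes", f"successes {successes} outside [0, {trials}]")
    low, high = proportion_confint(successes, trials, alpha=1 - confidence_level, method="wilson")
    # clamp float dust at the boundaries so the [0, 1] postcondition is exact
    return (min(max(float(low), 0.0), 1.0), min(max(float(high), 0.0), 1.0))


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Point metrics and Wilson CIs of a confusion matrix.

    A metric whose denominator is empty is ``None`` together with its CI.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    balanced_accuracy: Optional[float]
    ci_sensitivity: Optional[tuple[float, float]]
    ci_specificity: Optional[tuple[float, float]]
    ci_ppv: Optional[tuple[float, float]]
    ci_npv: Optional[tuple[float, float]]
    confidence_level: float = 0.95


def _ratio_ci(k: int, n: int, level: float):
    if n == 0:
        return None, None
    return k / n, wilson_ci(k, n, level)


def performance(m: ConfusionMatrix, confidence_level: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy with Wilson CIs."""
    sens, ci_sens = _ratio_ci(m.tp, m.tp + m.fn, confidence_level)
    spec, ci_spec = _ratio_ci(m.tn, m.tn + m.fp, confidence_level)
    ppv, ci_ppv = _ratio_ci(m.tp, m.tp + m.fp, confidence_level)
    npv, ci_npv = _ratio_ci(m.tn, m.tn + m.fn, confidence_level)
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    return DiagnosticPerformance(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        balanced_accuracy=ba,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        ci_ppv=ci_ppv,
        ci_npv=ci_npv,
        confidence_level=confidence_level,
    )


def balanced_accuracy(m: ConfusionMatrix) -> float:
    """(sensitivity + specificity) / 2.

    For a dichotomized (single-threshold) test this equals the trapezoidal ROC
    AUC, which is why it serves as the "diagnostic accuracy" of each score.
    """
    if m.malignant_margin == 0 or m.benign_margin == 0:
        raise ValidationError("zero-margin", "balanced accuracy needs both margins > 0")
    return (m.tp / m.malignant_margin + m.tn / m.benign_margin) / 2


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci: tuple[float, float]
    method: str


def odds_ratio(m: ConfusionMatrix, confidence_level: float = 0.95) -> OddsRatioResult:
    """Odds ratio (tp*tn)/(fp*fn) with the log-normal (Woolf) interval.

    When any cell is zero the Haldane–Anscombe 0.5 continuity correction is
    added to all four cells, keeping the estimator and interval finite.
    """
    corrected = 0 in m.as_tuple()
    table = Table2x2(
        np.array([[m.tp, m.fp], [m.fn, m.tn]], dtype=float), shift_zeros=True
    )
    lo, hi = table.oddsratio_confint(alpha=1 - confidence_level)
    return OddsRatioResult(
        or_value=float(table.oddsratio),
        ci=(float(lo), float(hi)),
        method="woolf-lognormal" + ("-haldane" if corrected else ""),
    )


def select_cutoff(
    scores: Sequence[float],
    truths: Sequence[Truth | str],
    candidates: Sequence[float],
    specificity_tiebreak_tol: float = 0.0,
) -> tuple[float, pd.DataFrame]:
    """Pick the dichotomization cutoff with the highest balanced accuracy.

    Among candidates whose balanced accuracy is within
    ``specificity_tiebreak_tol`` of the maximum, the one with the highest
    specificity wins (ties broken by first-listed order). The full
    per-candidate table is returned for reporting.
    """
    if len(candidates) == 0:
        raise ValidationError("no-candidates", "candidate cutoff list is empty")
    labels = {Truth(t) for t in truths}
    if len(labels) < 2:
        raise ValidationError("degenerate-truths", "truth labels contain a single class")
    rows = []
    for c in candidates:
        m = confusion_from_scores(scores, truths, c)
        p = performance(m)
        rows.append(
            {
                "cutoff": c,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "tn": m.tn,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "balanced_accuracy": p.balanced_accuracy,
            }
        )
    table = pd.DataFrame(rows)
    best_ba = table["balanced_accuracy"].max()
    eligible = table[table["balanced_accuracy"] >= best_ba - specificity_tiebreak_tol]
    best = eligible.loc[eligible["specificity"].idxmax(), "cutoff"]  # idxmax: first max
    return float(best), table


class ProportionTest(str, Enum):
    TWO_PROP_Z = "TWO_PROP_Z"
    FISHER = "FISHER"


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, method: ProportionTest = ProportionTest.TWO_PROP_Z
) -> float:
    """Two-sided p-value comparing two independent binomial proportions.

    ``TWO_PROP_Z`` is the pooled two-proportion z-test; ``FISHER`` is the
    exact hypergeometric test. For paired designs see :func:`mcnemar_test`.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("zero-n", "both sample sizes must be > 0")
    method = ProportionTest(method)
    if method is ProportionTest.FISHER:
        res = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
        return float(res.pvalue)
    if k1 * n2 == k2 * n1:  # identical proportions: z = 0 exactly
        return 1.0
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def mcnemar_test(discordant_12: int, discordant_21: int, exact: bool = True) -> float:
    """Paired comparison of two tests on the same subjects (McNemar).

    ``discordant_12`` counts subjects called positive by test 1 only,
    ``discordant_21`` positive by test 2 only.
    """
    table = [[0, discordant_12], [discordant_21, 0]]
    return float(mcnemar(table, exact=exact).pvalue)


def exclude_subgroup(
    m: ConfusionMatrix,
    remove_tp: int = 0,
    remove_fp: int = 0,
    remove_fn: int = 0,
    remove_tn: int = 0,
) -> ConfusionMatrix:
    """Cellwise subtraction for subgroup exclusion (e.g. dropping MTC cases)."""
    cells = (m.tp - remove_tp, m.fp - remove_fp, m.fn - remove_fn, m.tn - remove_tn)
    if any(c < 0 for c in cells):
        raise ValidationError("negative-cell", f"removal exceeds cell counts: {cells}")
    return ConfusionMatrix(*cells)


# ---------------------------------------------------------------------------
# Reconstruction of integer 2x2 tables from printed rounded percentages.
# ---------------------------------------------------------------------------

class Rounding(str, Enum):
    """How a printed percentage is assumed to have been produced.

    ``HALF_UP`` rounds half away from zero at the stated decimals; ``FLOOR``
    truncates (some published sensitivities are truncations of the exact
    fraction); ``ANY`` accepts either, for sources that mix conventions.
    """

    HALF_UP = "half_up"
    FLOOR = "floor"
    ANY = "any"


#: printed value and its number of decimals, e.g. (84.6, 1) or (88, 0)
PrintedValue = tuple[float, int]

_METRICS = ("sensitivity", "specificity", "ppv", "npv")


def _printed_scaled(value: float, decimals: int) -> int:
    """Exact integer value*10^decimals (validates the stated precision)."""
    d = decimal.Decimal(str(value)).scaleb(decimals)
    if d != d.to_integral_value():
        raise ValidationError(
            "bad-precision", f"{value} has more than {decimals} decimals"
        )
    return int(d)


def _matches(fraction: Fraction, value: float, decimals: int, rounding: Rounding) -> bool:
    """Does the exact percentage `fraction` print as `value` at `decimals`?"""
    target = _printed_scaled(value, decimals)
    scaled = fraction * 10**decimals
    if rounding in (Rounding.HALF_UP, Rounding.ANY):
        half_up = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
        if half_up == target:
            return True
    if rounding in (Rounding.FLOOR, Rounding.ANY):
        if scaled.numerator // scaled.denominator == target:
            return True
    return False


class NoSolutionError(ThyriskError):
    """No integer 2x2 table reproduces the printed metrics.

    Raised only by callers that demand a solution; :func:`reconstruct_matrix`
    itself returns an empty list, since an empty solution set is the correct
    (and diagnostic) answer for internally inconsistent printed values.
    """

    def __init__(self, message: str):
        super().__init__("no-solution", message)


def reconstruct_matrix(
    printed: Mapping[str, PrintedValue],
    n_total: Optional[int] = None,
    margin_bounds: Optional[tuple[tuple[int, int], tuple[int, int]]] = None,
    rounding: Rounding | str = Rounding.HALF_UP,
) -> list[ConfusionMatrix]:
    """Enumerate every integer 2x2 table consistent with printed rounded metrics.

    Parameters
    ----------
    printed
        Map from metric name (subset of ``sensitivity``, ``specificity``,
        ``ppv``, ``npv``) to ``(value_percent, decimals)``.
    n_total
        If given, only tables with ``tp+fp+fn+tn == n_total`` are searched.
    margin_bounds
        ``((mal_lo, mal_hi), (ben_lo, ben_hi))`` bounds on the malignant
        (tp+fn) and benign (fp+tn) margins. Required when ``n_total`` is None;
        optional extra constraint otherwise.
    rounding
        Printing convention assumed, see :class:`Rounding`.

    Returns all solutions; the caller asserts uniqueness when claiming "the"
    table. An empty list signals that the printed values are jointly
    inconsistent (which does happen in published reports).
    """
    rounding = Rounding(rounding)
    printed = dict(printed)
    unknown = set(printed) - set(_METRICS)
    if unknown:
        raise ValidationError("bad-metric", f"unknown metric names: {sorted(unknown)}")
    for value, decimals in printed.values():
        if not 0 <= value <= 100:
            raise ValidationError("bad-printed", f"printed value {value} outside [0, 100]")
    if n_total is None and margin_bounds is None:
        raise ValidationError(
            "unbounded-search", "need n_total or margin_bounds to bound the search"
        )
    if n_total is not None and n_total <= 0:
        raise ValidationError("bad-n", "n_total must be > 0")

    if margin_bounds is not None:
        (mal_lo, mal_hi), (ben_lo, ben_hi) = margin_bounds
    else:
        mal_lo, mal_hi = 0, n_total
        ben_lo, ben_hi = 0, n_total

    def metric_ok(name: str, num: int, den: int) -> bool:
        if name not in printed:
            return True
        if den == 0:
            return False  # a printed value exists, so the margin cannot be empty
        value, decimals = printed[name]
        return _matches(Fraction(100 * num, den), value, decimals, rounding)

    solutions: list[ConfusionMatrix] = []
    for mal in range(mal_lo, mal_hi + 1):
        for tp in range(mal + 1):
            fn = mal - tp
            if not metric_ok("sensitivity", tp, mal):
                continue
            for ben in range(ben_lo, ben_hi + 1):
                if n_total is not None and mal + ben != n_total:
                    continue
                if mal + ben == 0:
                    continue
                for tn in range(ben + 1):
                    fp = ben - tn
                    if not metric_ok("specificity", tn, ben):
                        continue
                    if not metric_ok("ppv", tp, tp + fp):
                        continue
                    if not metric_ok("npv", tn, tn + fn):
                        continue
                    solutions.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    return solutions
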