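"""Reproduction of the pilot study's published summary statistics.

A published diagnostic-accuracy report typically prints rounded percentages
(sensitivity, specificity, PPV, NPV) but not the underlying integer 2x2
tables. Because the cohort size is known, the integer tables can be recovered
by exhaustive search over all tables consistent with the printed, rounded
values (:func:`thyrisk.diagnostics.reconstruct_matrix`). This module bundles
the printed values of the 47-patient pilot cohort and recomputes, from the
reconstructed tables alone, every downstream headline statistic: balanced
diagnostic accuracies, Wilson confidence intervals, the high-risk-ultrasound
odds ratio, Bayes prevalence projections and the medullary-carcinoma
exclusion sub-analysis.

Two deliberate quirks of the source report are surfaced rather than hidden:

* The histology table reports 28 malignant / 19 benign, but every printed
  metric quadruple is consistent only with 26 malignant / 21 benign margins.
  Both views are reported (``cohort_views``).
* The genomic-score PPV/NPV (92.3% / 80%) are jointly inconsistent with its
  sensitivity/specificity (80.7% / 94.7%) for any integer table; the joint
  reconstruction correctly returns no solution, and the genomic-score table
  is recovered from sensitivity/specificity alone. Those two are printed with
  mixed rounding conventions (80.7 truncates 21/26), so reconstruction uses
  the tolerant ``Rounding.ANY`` mode.
"""

from __future__ import annotations

from .diagnostics import (
    ConfusionMatrix,
    NoSolutionError,
    Rounding,
    balanced_accuracy,
    exclude_subgroup,
    odds_ratio,
    performance,
    reconstruct_matrix,
)
from .prevalence import bayes_npv, bayes_ppv

#: Cohort size entering the accuracy analysis.
N_TOTAL = 47

#: Printed rounded metrics per score: (value in percent, decimals printed).
PRINTED = {
    "x_us": {
        "cutoff": 0.9,
        "metrics": {
            "sensitivity": (34.6, 1),
            "specificity": (90, 0),
            "ppv": (81.8, 1),
            "npv": (52.8, 1),
        },
        "accuracy": 62.5,
        "odds_ratio": {"or": 5.03, "ci": (0.95, 26.6)},
        "npv_ci": (37, 68),
    },
    "x_gc": {
        "cutoff": 0.6,
        "metrics": {
            "sensitivity": (80.7, 1),
            "specificity": (94.7, 1),
            "ppv": (92.3, 1),
            "npv": (80, 0),
        },
        "accuracy": 88,
    },
    "trs": {
        "cutoff": 0.7,
        "metrics": {
            "sensitivity": (84.6, 1),
            "specificity": (85.7, 1),
            "ppv": (88, 0),
            "npv": (81.8, 1),
        },
        "accuracy": 85.2,
        "ppv_ci": (70, 95.8),
        "npv_ci": (61.5, 92.7),
        "bayes": {"ppv_at_028": 69.7, "ppv_at_006": 27, "npv_at_006": 99},
    },
}

#: Histology-table view of the cohort margins (28 carcinoma / 19 benign).
TABLE_MARGINS = {"malignant": 28, "benign": 19}

#: Upper bounds on the 2x2 margins implied by the histology table; used when
#: a score's printed sensitivity/specificity do not pin down n_total.
MARGIN_BOUNDS = ((1, 28), (1, 21))

#: The medullary-carcinoma sub-analysis removes 3 MTC patients, all of whom
#: are genomic-test true positives (RET alterations score far above cutoff).
MTC_REMOVALS = {"remove_tp": 3}


def _unique(solutions: list[ConfusionMatrix], what: str) -> ConfusionMatrix:
    if not solutions:
        raise NoSolutionError(f"no integer table reproduces the printed {what} metrics")
    if len(solutions) > 1:
        raise NoSolutionError(
            f"printed {what} metrics are ambiguous: {len(solutions)} tables match"
        )
    return solutions[0]


def reconstruct_xus_table() -> ConfusionMatrix:
    """The ultrasound-score table, unique at n=47 under half-up rounding."""
    return _unique(
        reconstruct_matrix(PRINTED["x_us"]["metrics"], n_total=N_TOTAL), "ultrasound-score"
    )


def reconstruct_trs_table() -> ConfusionMatrix:
    """The total-risk-score table, unique at n=47 under half-up rounding."""
    return _unique(
        reconstruct_matrix(PRINTED["trs"]["metrics"], n_total=N_TOTAL), "total-risk-score"
    )


def reconstruct_xgc_table() -> ConfusionMatrix:
    """The genomic-score table from sensitivity/specificity alone.

    The printed sensitivity (80.7, a truncation of 21/26) and specificity
    (94.7 = 18/19) imply margins summing to 45, so n_total cannot be fixed at
    47; the search instead bounds each margin by the histology table and
    accepts either rounding convention. The result is unique: (21, 1, 5, 18).
    """
    sens_spec = {
        k: v for k, v in PRINTED["x_gc"]["metrics"].items() if k in ("sensitivity", "specificity")
    }
    return _unique(
        reconstruct_matrix(sens_spec, margin_bounds=MARGIN_BOUNDS, rounding=Rounding.ANY),
        "genomic-score sensitivity/specificity",
    )


def xgc_joint_reconstruction() -> list[ConfusionMatrix]:
    """Joint reconstruction of all four printed genomic-score metrics.

    Returns the (empty) solution set: the printed PPV/NPV are inconsistent
    with the printed sensitivity/specificity for every integer table, even
    under the tolerant rounding mode.
    """
    return reconstruct_matrix(
        PRINTED["x_gc"]["metrics"], n_total=N_TOTAL, rounding=Rounding.ANY
    )


def _score_block(name: str, matrix: ConfusionMatrix, confidence_level: float = 0.95) -> dict:
    perf = performance(matrix, confidence_level)
    orr = odds_ratio(matrix, confidence_level)
    return {
        "cutoff": PRINTED[name]["cutoff"],
        "matrix": {"tp": matrix.tp, "fp": matrix.fp, "fn": matrix.fn, "tn": matrix.tn},
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "ppv": perf.ppv,
        "npv": perf.npv,
        "ci_sensitivity": perf.ci_sensitivity,
        "ci_specificity": perf.ci_specificity,
        "ci_ppv": perf.ci_ppv,
        "ci_npv": perf.ci_npv,
        "balanced_accuracy": balanced_accuracy(matrix),
        "odds_ratio": {"or": orr.or_value, "ci": orr.ci, "method": orr.method},
    }


def reproduce(confidence_level: float = 0.95) -> dict:
    """Recompute every reproducible headline statistic from scratch.

    Reconstructs the three score tables by exhaustive search, then derives
    metrics, Wilson CIs, the odds ratio, balanced accuracies, the Bayes
    prevalence projections and the MTC-exclusion sub-analysis. Nothing in the
    output is copied from the printed report except the inputs in
    :data:`PRINTED` (the printed values themselves, which are the puzzle, and
    the expected values recorded alongside each recomputation for comparison).
    """
    xus = reconstruct_xus_table()
    trs = reconstruct_trs_table()
    xgc = reconstruct_xgc_table()

    trs_sens = trs.tp / trs.malignant_margin
    trs_spec = trs.tn / trs.benign_margin
    report: dict = {
        "n_total": N_TOTAL,
        "scores": {
            "x_us": _score_block("x_us", xus, confidence_level),
            "x_gc": _score_block("x_gc", xgc, confidence_level),
            "trs": _score_block("trs", trs, confidence_level),
        },
        "bayes_trs": {
            "ppv_at_028": bayes_ppv(trs_sens, trs_spec, 0.28),
            "ppv_at_006": bayes_ppv(trs_sens, trs_spec, 0.06),
            "npv_at_006": bayes_npv(trs_sens, trs_spec, 0.06),
            "ppv_at_059": bayes_ppv(trs_sens, trs_spec, 0.59),
            "npv_at_059": bayes_npv(trs_sens, trs_spec, 0.59),
        },
        "mtc_exclusion": {},
        "xgc_joint_reconstruction": {
            "solutions": [m.as_tuple() for m in xgc_joint_reconstruction()],
            "consistent": False,
        },
        "cohort_views": {
            "histology_table": TABLE_MARGINS,
            "reconstructed_margins": {
                "malignant": trs.malignant_margin,
                "benign": trs.benign_margin,
            },
            "note": (
                "the histology table reports 28/19 but all printed metric "
                "quadruples imply 26/21 margins; both views are retained"
            ),
        },
    }
    report["xgc_joint_reconstruction"]["consistent"] = bool(
        report["xgc_joint_reconstruction"]["solutions"]
    )

    trs_sub = exclude_subgroup(trs, **MTC_REMOVALS)
    xgc_sub = exclude_subgroup(xgc, **MTC_REMOVALS)
    report["mtc_exclusion"] = {
        "trs": {
            "matrix": trs_sub.as_tuple(),
            "sensitivity": trs_sub.tp / trs_sub.malignant_margin,
            "specificity": trs_sub.tn / trs_sub.benign_margin,
        },
        "x_gc": {
            "matrix": xgc_sub.as_tuple(),
            "sensitivity": xgc_sub.tp / xgc_sub.malignant_margin,
            "specificity": xgc_sub.tn / xgc_sub.benign_margin,
        },
    }
    return report
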