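"""End-to-end runs: simulate, score, evaluate, project, reconstruct, reproduce.

Each ``run_*`` function is a thin orchestration over the library modules: it
reads versioned text inputs, executes one pipeline stage, and writes a
versioned text output embedding the :class:`RunManifest` so any run is
reproducible from its own output. The command-line interface in
:mod:`thyrisk.cli` maps one subcommand onto each function.
"""

from __future__ import annotations

import dataclasses
import decimal
import logging

import pandas as pd
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .cohort import CohortConfig, default_study_config, generate_cohort
from .diagnostics import (
    Rounding,
    balanced_accuracy,
    confusion_from_scores,
    odds_ratio,
    performance,
    reconstruct_matrix,
    select_cutoff,
)
from .errors import ValidationError
from .genomics import compute_xgc, default_weight_table, load_weight_table
from .io import (
    read_cohort,
    read_scored,
    read_variants_tsv,
    write_cohort,
    write_report_json,
    write_scored,
)
from .prevalence import curve_frame, plot_prevalence_curves, prevalence_curve
from .risk import TRS_CUTOFF, XGC_CUTOFF, XUS_CUTOFF, score_nodule
from . import study

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration.

    Recognized keys: ``cutoffs`` (mapping with x_us/x_gc/trs), ``weights``
    (path), ``confidence_level``, ``seed``. Unknown keys are rejected so a
    typo cannot silently fall back to defaults.
    """
    import yaml

    path = Path(path)
    if not path.exists():
        raise ValidationError("missing-file", f"config file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValidationError("bad-config", "config YAML must be a mapping")
    allowed = {"cutoffs", "weights", "confidence_level", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError("bad-config", f"unknown config keys: {sorted(unknown)}")
    cutoffs = data.get("cutoffs", {})
    if not isinstance(cutoffs, dict) or set(cutoffs) - {"x_us", "x_gc", "trs"}:
        raise ValidationError("bad-config", "cutoffs must map x_us/x_gc/trs to numbers")
    return data


@dataclass
class RunManifest:
    """Everything needed to rerun a pipeline stage byte-identically."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    cutoffs: dict[str, float] = field(
        default_factory=lambda: {"x_us": XUS_CUTOFF, "x_gc": XGC_CUTOFF, "trs": TRS_CUTOFF}
    )
    confidence_level: float = 0.95
    seed: Optional[int] = None
    tool_version: str = __version__

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_simulate(
    out_path: str | Path,
    n_patients: int = 47,
    seed: int = 0,
    config: Optional[CohortConfig] = None,
) -> list:
    """Generate a synthetic cohort and write it as cohort CSV."""
    if config is None:
        config = default_study_config(n_patients=n_patients, seed=seed)
    nodules = generate_cohort(config)
    write_cohort(nodules, out_path)
    return nodules


def run_score(
    cohort_path: str | Path,
    weights_path: Optional[str | Path],
    out_path: str | Path,
    variants_path: Optional[str | Path] = None,
    trs_cutoff: float = TRS_CUTOFF,
) -> list:
    """Score every nodule of a cohort file and write the scored CSV.

    Alterations come from the cohort file's ``alterations`` column, optionally
    replaced per nodule by an explicit variants TSV. Without a weights path
    the bundled default table is used (a logged notice, since its values are
    illustrative).
    """
    nodules = read_cohort(cohort_path)
    if weights_path is not None:
        weights = load_weight_table(weights_path)
    else:
        logger.info("no weight table given: using bundled illustrative defaults")
        weights = default_weight_table()
    variants = read_variants_tsv(variants_path) if variants_path is not None else {}
    scored = []
    for n in nodules:
        alterations = variants.get(n.nodule_id, list(n.alterations))
        profile = compute_xgc(alterations, weights, nodule_id=n.nodule_id)
        scored.append(
            score_nodule(
                nodule_id=n.nodule_id,
                x_us=n.x_us,
                x_gc=profile.x_gc,
                truth=n.truth,
                trs_cutoff=trs_cutoff,
            )
        )
    write_scored(scored, out_path)
    return scored


def run_evaluate(
    scored_path: str | Path,
    out_path: str | Path,
    cutoffs: Optional[dict[str, float]] = None,
    confidence_level: float = 0.95,
) -> dict:
    """Evaluate the three scores of a scored cohort against histology truth.

    Produces, per score: the confusion matrix at the configured cutoff, point
    metrics with Wilson CIs, balanced accuracy, the odds ratio, and the
    per-candidate cutoff-selection table over all observed score values.
    """
    scored = read_scored(scored_path)
    if any(s.truth is None for s in scored):
        raise ValidationError("missing-truth", "evaluation needs a truth label per nodule")
    truths = [s.truth for s in scored]
    if len(set(truths)) < 2:
        raise ValidationError("degenerate-truths", "cohort has a single truth class")
    cutoffs = cutoffs or {"x_us": XUS_CUTOFF, "x_gc": XGC_CUTOFF, "trs": TRS_CUTOFF}
    manifest = RunManifest(
        stage="evaluate",
        inputs={"scored": str(scored_path)},
        cutoffs=dict(cutoffs),
        confidence_level=confidence_level,
    )
    report: dict = {"manifest": manifest.as_dict(), "scores": {}}
    values = {
        "x_us": [s.x_us for s in scored],
        "x_gc": [s.x_gc for s in scored],
        "trs": [s.trs for s in scored],
    }
    for name, scores in values.items():
        m = confusion_from_scores(scores, truths, cutoffs[name])
        perf = performance(m, confidence_level)
        orr = odds_ratio(m, confidence_level)
        candidates = sorted(set(round(v, 9) for v in scores))
        best, table = select_cutoff(scores, truths, candidates)
        report["scores"][name] = {
            "cutoff": cutoffs[name],
            "matrix": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn},
            "metrics": {
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "ppv": perf.ppv,
                "npv": perf.npv,
                "balanced_accuracy": perf.balanced_accuracy,
            },
            "cis": {
                "sensitivity": perf.ci_sensitivity,
                "specificity": perf.ci_specificity,
                "ppv": perf.ci_ppv,
                "npv": perf.ci_npv,
            },
            "odds_ratio": {"or": orr.or_value, "ci": orr.ci, "method": orr.method},
            "cutoff_selection": {
                "best": best,
                "table": table.to_dict(orient="records"),
            },
        }
    write_report_json(report, out_path)
    # CSV mirror of the per-candidate cutoff tables, next to the JSON report
    mirror = Path(out_path).with_suffix(".cutoffs.csv")
    frames = []
    for name in values:
        frame = pd.DataFrame(report["scores"][name]["cutoff_selection"]["table"])
        frame.insert(0, "score", name)
        frames.append(frame)
    with mirror.open("w", encoding="utf-8") as fh:
        fh.write("# format_version: 1\n")
        pd.concat(frames, ignore_index=True).to_csv(
            fh, index=False, float_format="%.6f", lineterminator="\n"
        )
    return report


def run_project(
    out_path: str | Path,
    sens: float,
    spec: float,
    grid: Optional[Sequence[float]] = None,
    plot_path: Optional[str | Path] = None,
    label: str = "score",
) -> "object":
    """Write the Bayes prevalence projection CSV (and optional plot)."""
    frame = curve_frame(prevalence_curve(sens, spec, grid))
    out_path = Path(out_path)
    with out_path.open("w", encoding="utf-8") as fh:
        fh.write("# format_version: 1\n")
        frame.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
    if plot_path is not None:
        plot_prevalence_curves({label: (sens, spec)}, str(plot_path), grid)
    return frame


def run_reconstruct(
    printed: dict[str, tuple[float, int]],
    out_path: str | Path,
    n_total: Optional[int] = None,
    margin_bounds: Optional[tuple[tuple[int, int], tuple[int, int]]] = None,
    rounding: Rounding | str = Rounding.HALF_UP,
) -> dict:
    """Reconstruct integer 2x2 tables from printed rounded metrics."""
    solutions = reconstruct_matrix(
        printed, n_total=n_total, margin_bounds=margin_bounds, rounding=rounding
    )
    report = {
        "manifest": RunManifest(stage="reconstruct").as_dict(),
        "printed": {k: list(v) for k, v in printed.items()},
        "n_total": n_total,
        "rounding": Rounding(rounding).value,
        "solutions": [m.as_tuple() for m in solutions],
        "unique": len(solutions) == 1,
    }
    write_report_json(report, out_path)
    return report


def _round_pct(value: float, decimals: int) -> float:
    """Round a percentage half-up at the printed number of decimals."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def run_reproduce_study(out_path: Optional[str | Path] = None) -> dict:
    """Recompute the pilot study's headline numbers and check each one.

    Fully self-contained: reconstructs the integer tables from the bundled
    printed metrics, recomputes accuracies, CIs, the odds ratio, Bayes
    projections and the MTC sub-analysis, and records pass/fail of each
    recomputed value against its printed counterpart at printed precision.
    """
    rep = study.reproduce()
    s = rep["scores"]
    checks: list[dict] = []

    def check(name: str, computed: float, printed: float, decimals: int, scale: float = 100.0):
        got = _round_pct(computed * scale, decimals) if scale else computed
        checks.append({"name": name, "computed": got, "printed": printed, "pass": got == printed})

    check("x_us.balanced_accuracy", s["x_us"]["balanced_accuracy"], 62.5, 1)
    checks.append(
        {
            "name": "x_us.odds_ratio",
            "computed": round(s["x_us"]["odds_ratio"]["or"], 2),
            "printed": 5.03,
            "pass": round(s["x_us"]["odds_ratio"]["or"], 2) == 5.03,
        }
    )
    or_lo, or_hi = s["x_us"]["odds_ratio"]["ci"]
    checks.append(
        {
            "name": "x_us.odds_ratio_ci",
            "computed": [round(or_lo, 2), round(or_hi, 1)],
            "printed": [0.95, 26.6],
            "pass": round(or_lo, 2) == 0.95 and round(or_hi, 1) == 26.6,
        }
    )
    check("x_us.npv_ci_low", s["x_us"]["ci_npv"][0], 37, 0)
    check("x_us.npv_ci_high", s["x_us"]["ci_npv"][1], 68, 0)
    check("trs.balanced_accuracy", s["trs"]["balanced_accuracy"], 85.2, 1)
    check("trs.ppv_ci_low", s["trs"]["ci_ppv"][0], 70, 0)
    check("trs.ppv_ci_high", s["trs"]["ci_ppv"][1], 95.8, 1)
    check("trs.npv_ci_low", s["trs"]["ci_npv"][0], 61.5, 1)
    check("trs.npv_ci_high", s["trs"]["ci_npv"][1], 92.7, 1)
    check("bayes.trs_ppv_at_0.28", rep["bayes_trs"]["ppv_at_028"], 69.7, 1)
    check("bayes.trs_ppv_at_0.06", rep["bayes_trs"]["ppv_at_006"], 27, 0)
    check("bayes.trs_npv_at_0.06", rep["bayes_trs"]["npv_at_006"], 99, 0)
    check("mtc_exclusion.trs_sensitivity", rep["mtc_exclusion"]["trs"]["sensitivity"], 82.6, 1)
    check("x_gc.balanced_accuracy", s["x_gc"]["balanced_accuracy"], 88, 0)
    checks.append(
        {
            "name": "x_gc.joint_reconstruction_has_no_solution",
            "computed": not rep["xgc_joint_reconstruction"]["consistent"],
            "printed": True,
            "pass": not rep["xgc_joint_reconstruction"]["consistent"],
        }
    )

    rep["checks"] = checks
    rep["all_pass"] = all(c["pass"] for c in checks)
    rep["manifest"] = RunManifest(stage="reproduce-study").as_dict()
    if out_path is not None:
        write_report_json(rep, out_path)
    return rep
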