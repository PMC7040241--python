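"""Bayes-theorem projection of predictive values across disease prevalence.

Sensitivity and specificity are intrinsic to a test, but PPV and NPV depend on
how common the disease is in the tested population. Given a test's (sens,
spec) estimated in one cohort, Bayes' theorem gives the predictive values the
same test would show at any prevalence p:

    PPV(p) = sens * p / (sens * p + (1 - spec) * (1 - p))
    NPV(p) = spec * (1 - p) / (spec * (1 - p) + (1 - sens) * p)

PPV increases and NPV decreases monotonically in p (strictly, for
0 < sens, spec < 1). Surgical case series of indeterminate thyroid nodules
are referral-biased toward high prevalence (around 0.55-0.6), whereas
population screening settings sit nearer 0.06; the band 0.06-0.59 is
highlighted in reports for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Prevalence band typical of indeterminate-nodule populations (screening to
#: surgical-referral settings), highlighted in reports.
STUDY_PREVALENCE_BAND = (0.06, 0.59)


def _check_args(sens: float, spec: float, prevalence: float) -> None:
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("bad-rate", f"{name} must be in [0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise ValidationError("bad-prevalence", f"prevalence must be in (0, 1), got {prevalence}")


def bayes_ppv(sens: float, spec: float, prevalence: float) -> Optional[float]:
    """Positive predictive value at the given prevalence; None if undefined
    (a test that never calls positive: sens = 0 and spec = 1)."""
    _check_args(sens, spec, prevalence)
    denom = sens * prevalence + (1 - spec) * (1 - prevalence)
    if denom == 0:
        return None
    return sens * prevalence / denom


def bayes_npv(sens: float, spec: float, prevalence: float) -> Optional[float]:
    """Negative predictive value at the given prevalence; None if undefined
    (a test that never calls negative: sens = 1 and spec = 0)."""
    _check_args(sens, spec, prevalence)
    denom = spec * (1 - prevalence) + (1 - sens) * prevalence
    if denom == 0:
        return None
    return spec * (1 - prevalence) / denom


@dataclass(frozen=True)
class PrevalencePoint:
    prevalence: float
    ppv: Optional[float]
    npv: Optional[float]


def default_grid() -> np.ndarray:
    """Prevalence grid 0.01..0.99 in steps of 0.01."""
    return np.round(np.arange(0.01, 1.0, 0.01), 2)


def prevalence_curve(
    sens: float, spec: float, grid: Optional[Sequence[float]] = None
) -> list[PrevalencePoint]:
    """Evaluate PPV and NPV on a prevalence grid (default 0.01..0.99)."""
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if len(grid) == 0:
        raise ValidationError("empty-grid", "prevalence grid is empty")
    return [
        PrevalencePoint(prevalence=float(p), ppv=bayes_ppv(sens, spec, p), npv=bayes_npv(sens, spec, p))
        for p in grid
    ]


def curve_frame(points: Sequence[PrevalencePoint]) -> pd.DataFrame:
    """Tabulate a prevalence curve as columns ``prevalence, ppv, npv``."""
    return pd.DataFrame(
        {
            "prevalence": [p.prevalence for p in points],
            "ppv": [p.ppv for p in points],
            "npv": [p.npv for p in points],
        }
    )


def plot_prevalence_curves(
    curves: dict[str, tuple[float, float]],
    path: str,
    grid: Optional[Sequence[float]] = None,
    band: tuple[float, float] = STUDY_PREVALENCE_BAND,
) -> None:
    """Plot PPV/NPV vs prevalence, one panel per score.

    ``curves`` maps a score label to its (sens, spec). The highlighted band
    marks the prevalence range typical of indeterminate-nodule populations.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), squeeze=False)
    for ax, (label, (sens, spec)) in zip(axes[0], curves.items()):
        frame = curve_frame(prevalence_curve(sens, spec, grid))
        ax.plot(frame["prevalence"], frame["ppv"], color="tab:blue", label="PPV")
        ax.plot(frame["prevalence"], frame["npv"], color="tab:red", label="NPV")
        ax.axvspan(*band, color="0.9", zorder=0)
        ax.set_title(label)
        ax.set_xlabel("cancer prevalence")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="center right", fontsize=8)
    axes[0][0].set_ylabel("predictive value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
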