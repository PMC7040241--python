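"""Recover the pilot study's integer 2x2 tables from its printed percentages.

A published report gives rounded sensitivity/specificity/PPV/NPV but not the
underlying integer tables. With the cohort size known (47), exhaustive search
over all 2x2 tables finds every table consistent with the printed rounding —
here a unique one per score — after which exact accuracies, Wilson intervals
and the odds ratio drop out.
"""

from thyrisk import balanced_accuracy, odds_ratio, performance
from thyrisk.study import (
    reconstruct_trs_table,
    reconstruct_xgc_table,
    reconstruct_xus_table,
    xgc_joint_reconstruction,
)

for name, table in [
    ("ultrasound score X_US (cutoff 0.9)", reconstruct_xus_table()),
    ("genomic score X_GC (cutoff 0.6)", reconstruct_xgc_table()),
    ("total risk score TRS (cutoff 0.7)", reconstruct_trs_table()),
]:
    p = performance(table)
    print(f"{name}: tp={table.tp} fp={table.fp} fn={table.fn} tn={table.tn}")
    print(
        f"  sens {p.sensitivity:.1%}  spec {p.specificity:.1%}"
        f"  ppv {p.ppv:.1%} (CI {p.ci_ppv[0]:.1%}-{p.ci_ppv[1]:.1%})"
        f"  npv {p.npv:.1%} (CI {p.ci_npv[0]:.1%}-{p.ci_npv[1]:.1%})"
    )
    print(f"  balanced accuracy {balanced_accuracy(table):.1%}")

orr = odds_ratio(reconstruct_xus_table())
print(
    f"\nhigh-suspicion ultrasound vs lower patterns: OR {orr.or_value:.2f}"
    f" (95% CI {orr.ci[0]:.2f}-{orr.ci[1]:.1f})"
)
print(
    "joint reconstruction of all four printed genomic-score metrics finds"
    f" {len(xgc_joint_reconstruction())} tables — the printed PPV/NPV are"
    " internally inconsistent, so that table is recovered from"
    " sensitivity/specificity alone."
)
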