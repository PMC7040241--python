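"""Score three indeterminate nodules and apply the management algorithm.

Builds a minimal in-memory cohort — a high-suspicion nodule without molecular
results, an intermediate-suspicion nodule carrying BRAF V600E, and a
low-suspicion mutation-negative nodule — and prints each nodule's scores and
recommendation. The high-suspicion nodule goes to surgery on ultrasound
alone; the BRAF-positive nodule crosses the TRS 0.7 threshold; the last one
is watched.
"""

from thyrisk import (
    AlterationClass,
    AtaPattern,
    GenomicAlteration,
    compute_xgc,
    default_weight_table,
    score_nodule,
    xus_from_pattern,
)

weights = default_weight_table()
braf = GenomicAlteration("BRAF", AlterationClass.SNV, "p.Val600Glu")

nodules = [
    ("high-suspicion, panel negative", AtaPattern.HIGH, []),
    ("intermediate, BRAF V600E", AtaPattern.INTERMEDIATE, [braf]),
    ("low-suspicion, panel negative", AtaPattern.LOW, []),
]

print(f"{'nodule':35} {'X_US':>5} {'X_GC':>5} {'TRS':>5}  recommendation")
for label, pattern, alterations in nodules:
    x_us = xus_from_pattern(pattern)
    x_gc = compute_xgc(alterations, weights).x_gc
    s = score_nodule(label, x_us=x_us, x_gc=x_gc)
    print(f"{label:35} {s.x_us:5.2f} {s.x_gc:5.2f} {s.trs:5.2f}  {s.recommendation.value}")

print(
    "\nTRS = X_US + X_GC; surgery when X_US = 0.9 (ultrasound alone suffices)\n"
    "or when TRS >= 0.7; surveillance otherwise."
)
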