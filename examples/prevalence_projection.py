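"""Project predictive values of the total risk score across cancer prevalence.

Surgical case series are referral-biased toward high malignancy prevalence,
so the PPV/NPV observed in such a cohort do not transfer to other settings.
Bayes' theorem projects the score's exact sensitivity and specificity onto
any prevalence: this prints the projection at a screening-like 6%, the 28%
typical of unselected indeterminate-nodule populations, and the 59%
referral-cohort figure.
"""

from thyrisk import bayes_npv, bayes_ppv
from thyrisk.study import reconstruct_trs_table

table = reconstruct_trs_table()
sens = table.tp / table.malignant_margin
spec = table.tn / table.benign_margin
print(f"TRS operating point: sensitivity {sens:.1%}, specificity {spec:.1%}\n")

print(f"{'prevalence':>10} {'PPV':>7} {'NPV':>7}")
for prev in (0.06, 0.28, 0.59):
    print(
        f"{prev:>10.0%} {bayes_ppv(sens, spec, prev):>7.1%}"
        f" {bayes_npv(sens, spec, prev):>7.1%}"
    )

print(
    "\nAt low prevalence a negative test is near-definitive (NPV ~99%) but a"
    "\npositive one is mostly false (PPV ~27%); the ranking reverses as"
    "\nprevalence rises toward surgical-referral levels."
)
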