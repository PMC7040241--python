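# thyrisk

Risk stratification for **cytologically indeterminate thyroid nodules**
(Bethesda III/IV). Between a fifth and a tenth of thyroid fine-needle
aspirations come back indeterminate, leaving clinicians to choose between
diagnostic surgery (often unnecessary) and surveillance (occasionally missing
a cancer). `thyrisk` implements, as a tested reusable library, a combined
ultrasound + molecular risk-scoring system for these nodules together with
the full diagnostic-accuracy toolkit needed to evaluate it.

## The model

Each nodule receives three scores:

* **X_US** — the annotated ultrasound score: the five ATA sonographic
  patterns map to the upper bound of their guideline malignancy-risk band,
  `benign/very-low → 0, low → 0.1, intermediate → 0.2, high → 0.9`.
* **X_GC** — the additive genomic classifier score. Every somatic alteration
  found by a targeted panel is annotated with a weight in [0, 1] expressing
  its strength of association with thyroid cancer, and

  `X_GC = Σ w(SNV/INDEL) + Σ w(fusion) + Σ w(CNV)`

  summed over all detected alterations (uncapped: multi-hit nodules can
  exceed 1).
* **TRS** — the total risk score, `TRS = X_US + X_GC`.

Management follows a sequential algorithm: a high-suspicion ultrasound
pattern (X_US = 0.9) is referred to surgery without molecular testing (the
panel adds no specificity in that stratum); otherwise surgery when
TRS ≥ 0.7, surveillance below.

Around the scores the package provides, in `thyrisk.diagnostics` and
`thyrisk.prevalence`:

* confusion matrices of dichotomized scores (test-positive iff score ≥ cutoff),
  sensitivity/specificity/PPV/NPV with **Wilson 95% CIs**, odds ratios with
  log-normal (Woolf) intervals and Haldane–Anscombe correction,
  **balanced diagnostic accuracy** (sens+spec)/2 — the ROC AUC of a
  single-threshold test — cutoff selection, subgroup exclusion, and
  two-proportion / Fisher / McNemar comparisons;
* **reconstruction of integer 2×2 tables from published rounded
  percentages** by exhaustive search, so a printed report's underlying
  tables (and everything downstream of them) can be recovered and audited;
* **Bayes-theorem projection** of PPV/NPV across the whole prevalence
  spectrum, `PPV(p) = sens·p / (sens·p + (1−spec)(1−p))` and its NPV
  counterpart — essential because surgical case series are referral-biased
  toward high prevalence;
* a **synthetic cohort generator** (`thyrisk.cohort`) calibrated to a
  47-patient pilot cohort: ~60% malignancy, histology-conditional alteration
  spectra (BRAF V600E in papillary carcinoma, RAS hotspots in
  follicular-variant/poorly-differentiated/Hürthle tumors, RET in medullary
  carcinoma, PAX8–PPARG in NIFTP, sparse RAS/GNAS/ESR1/ATM/TET2 variants in
  benign adenomas) and malignancy-conditional ultrasound patterns.

## Worked example

`examples/reconstruct_published_tables.py` recovers a pilot study's integer
tables from its printed rounded percentages and recomputes its statistics:

```
ultrasound score X_US (cutoff 0.9): tp=9 fp=2 fn=17 tn=19
  sens 34.6%  spec 90.5%  ppv 81.8% (CI 52.3%-94.9%)  npv 52.8% (CI 37.0%-68.0%)
  balanced accuracy 62.5%
genomic score X_GC (cutoff 0.6): tp=21 fp=1 fn=5 tn=18
  sens 80.8%  spec 94.7%  ppv 95.5% (CI 78.2%-99.2%)  npv 78.3% (CI 58.1%-90.3%)
  balanced accuracy 87.8%
total risk score TRS (cutoff 0.7): tp=22 fp=3 fn=4 tn=18
  sens 84.6%  spec 85.7%  ppv 88.0% (CI 70.0%-95.8%)  npv 81.8% (CI 61.5%-92.7%)
  balanced accuracy 85.2%

high-suspicion ultrasound vs lower patterns: OR 5.03 (95% CI 0.95-26.6)
```

Reading: ultrasound alone is specific but misses two thirds of cancers in
this stratum; adding the molecular score raises sensitivity to ~85% at a
small specificity cost, and a high-suspicion pattern alone carries five-fold
cancer odds. `examples/prevalence_projection.py` then shows why the
cohort-observed predictive values do not transfer: at 6% prevalence the same
TRS operating point gives NPV 98.9% but PPV only 27.4%, versus 69.7% PPV at
28% prevalence.

The other examples (`score_nodules.py`, `simulate_and_evaluate.py`) apply
the management algorithm to individual nodules and exercise the synthetic
cohort generator end to end. The same stages are available from a shell:

```bash
thyrisk simulate --n 47 --seed 1 --out cohort.csv
thyrisk score --cohort cohort.csv --out scored.csv
thyrisk evaluate --scored scored.csv --out report.json
thyrisk project --sens 0.846 --spec 0.857 --out curve.csv
thyrisk reconstruct --metric sensitivity=84.6:1 --metric specificity=85.7:1 \
        --metric ppv=88:0 --metric npv=81.8:1 --n 47 --out tables.json
thyrisk reproduce-study --out reproduction.json
```

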