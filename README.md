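# cellloss

Analysis pipeline for a serum-biomarker **cell-loss metric** used to predict,
early during neoadjuvant chemotherapy, which breast-cancer patients will reach
pathologic complete response (pCR) at surgery.

Thymidine kinase 1 (TK1) is a cell-cycle enzyme released into blood when
proliferating cells are disrupted. Relating its serum concentration to the
tumour volume gives a per-volume measure of tumour cell loss,

```
M = sTK1 / V          [ng·ml⁻¹·cm⁻³]
ΔM = M_t − M_0        (baseline-subtracted; may be negative)
```

where `V = πd³/6` is the sphere-equivalent volume from the largest tumour
diameter. The on-treatment metric divides the sTK1 level 48 h after the 2nd
chemotherapy cycle by the tumour volume measured between the 2nd and 3rd
cycle. Patients are stratified into quartiles of the baseline metric; the
pipeline then runs the complete inferential battery: exact Fisher /
Freeman–Halton contingency tests of pathologic outcome by quartile, Wilcoxon
comparisons of pCR vs non-pCR at each timepoint, covariate ANOVAs, ROC
analysis with Youden cut-off selection and predictive values (PPV/NPV), and
the rank correlation between the on-treatment metric and residual tumour
volume.

Patient-level data for this design are not publicly deposited, so the package
ships a first-class synthetic-cohort generator whose per-quartile lognormal
profiles are calibrated to the published descriptive tables (medians and
interquartile ranges of the baseline metric, baseline tumour volume and the
baseline-subtracted 48 h metric, plus quartile pCR rates 3/26, 3/26, 6/26,
12/26). Every pipeline stage is therefore testable end to end.

Intended users: biostatisticians and translational-oncology researchers who
want to reproduce, stress-test or extend this class of early-response
biomarker analysis.

## Worked example

```bash
cellloss simulate --seed 1 --out cohort.csv --labels-out labels.json
cellloss analyze cohort.csv --out report.json --tables-dir tables/
```

which logs

```
INFO wrote 104-patient cohort to cohort.csv (seed 1)
INFO analyzed 104 patients (104 complete, 57 with pre-cycle-2): AUC 48h = 0.643
```

`report.json` then contains, among other things, the quartile sizes
(`[26, 26, 26, 26]`), the pCR-by-quartile contingency table with its exact
2×4 Fisher p-value, the per-quartile descriptive statistics of the raw and
baseline-subtracted metrics, the empirical ROC curve with the Youden-optimal
cut-off and its confusion summary (sensitivity, specificity, PPV, NPV), and
the pre-cycle-2 subset analysis. The AUC of 0.643 for this seed says the 48 h
baseline-subtracted metric ranks a randomly chosen pCR patient above a
randomly chosen non-pCR patient about 64% of the time in this simulated
cohort.

Rebuilding a published confusion matrix from rounded summary rates:

```bash
cellloss reconstruct --pos 24 --neg 80 --sens 0.71 --fpr 0.31
# tp=17 fp=25 fn=7 tn=55  sens 70.8% spec 68.8% PPV 40.5% NPV 88.7%
```

The same operations are available as a library
(`cellloss.run_analysis`, `cellloss.generate`, `cellloss.fisher_exact_2xk`,
`cellloss.reconstruct_confusion`, ...).

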