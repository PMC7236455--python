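"""End-to-end analysis: from a cohort table to the full result set.

``run_analysis`` executes the whole pipeline deterministically: per-patient
metrics, quartile stratification on the baseline metric, descriptive
tables (both the baseline-subtracted and the raw 48 h metric variants are
always computed; quartile membership is identical because quartiles are
defined on the baseline metric), outcome-by-quartile contingency analyses
(overall 2x4 Fisher, all pairwise quartile comparisons both as pCR/non-pCR
2x2 and as 3-category pathologic status), pCR vs non-pCR Wilcoxon
comparisons of volume, sTK1 and metric at each timepoint, covariate
ANOVAs with the pCR indicator as response, ROC/cut-off/predictive-value
analysis at 48 h (all complete cases) and pre-cycle-2 (the subset with
that sample), and the rank correlation between the 48 h metric and
residual tumour volume among incomplete responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .cohort import CohortTable, Outcome, Timepoint, validate_cohort
from .exact_tests import (
    ContingencyTable,
    TestResult,
    anova_oneway,
    fisher_exact_2xk,
    spearman_correlation,
    wilcoxon_test,
)
from .metric import CellLossMetrics, compute_metrics
from .roc import ConfusionSummary, RocCurve, evaluate_cutoff, roc_curve, youden_cutoff
from .stratify import QuartileGrouping, assign_quartiles, group_summaries

__all__ = ["AnalysisOptions", "AnalysisReport", "run_analysis", "format_p"]


def format_p(p: float) -> str:
    """Report-style p formatting: 3 decimals below 0.01, else 2."""
    return f"{p:.2f}" if p >= 0.01 else f"{p:.3f}"


@dataclass(frozen=True)
class AnalysisOptions:
    """Pipeline switches.

    ``use_raw_metric`` makes the ROC block score on the raw (not
    baseline-subtracted) 48 h metric.  ``cutoff_48h``/``cutoff_pre2``
    evaluate a fixed cut-off instead of the Youden-optimal one.
    """

    use_raw_metric: bool = False
    cutoff_48h: float | None = None
    cutoff_pre2: float | None = None


@dataclass
class AnalysisReport:
    n_total: int
    n_complete: int
    n_pre2: int
    metrics: dict[str, CellLossMetrics]
    grouping: QuartileGrouping
    descriptive: dict[str, dict]
    outcome_by_quartile: ContingencyTable
    pcr_percent_by_quartile: list[float]
    tests: dict[str, TestResult]
    roc_48h: RocCurve
    cutoff_48h: float
    confusion_48h: ConfusionSummary
    roc_pre2: RocCurve | None = None
    cutoff_pre2: float | None = None
    confusion_pre2: ConfusionSummary | None = None
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_dict(self) -> dict:
        def conf(c):
            return c.to_dict() if c is not None else None

        return {
            "n_total": self.n_total,
            "n_complete": self.n_complete,
            "n_pre2": self.n_pre2,
            "quartile_sizes": self.grouping.sizes(),
            "quartile_boundaries": list(self.grouping.boundaries),
            "descriptive": self.descriptive,
            "outcome_by_quartile": {
                "rows": [list(r) for r in self.outcome_by_quartile.counts],
                "row_labels": list(self.outcome_by_quartile.row_labels),
                "col_labels": list(self.outcome_by_quartile.col_labels or []),
            },
            "pcr_percent_by_quartile": self.pcr_percent_by_quartile,
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
            "roc_48h": {
                "auc": self.roc_48h.auc,
                "points": [list(p) for p in self.roc_48h.points],
            },
            "cutoff_48h": self.cutoff_48h,
            "confusion_48h": conf(self.confusion_48h),
            "roc_pre2": None
            if self.roc_pre2 is None
            else {"auc": self.roc_pre2.auc, "points": [list(p) for p in self.roc_pre2.points]},
            "cutoff_pre2": self.cutoff_pre2,
            "confusion_pre2": conf(self.confusion_pre2),
        }


def _volume_at(record, tp):
    v = record.tumour_volume.get(tp)
    if v is not None:
        return v
    d = record.tumour_diameter.get(tp)
    if d is not None:
        from .metric import sphere_volume

        return sphere_volume(d)
    return None


_OUTCOME_3CAT = {
    Outcome.PCR: "pCR",
    Outcome.PT1: "pT1",
    Outcome.PT2: "pT2+pT3",
    Outcome.PT3: "pT2+pT3",
}


def run_analysis(cohort: CohortTable, options: AnalysisOptions | None = None) -> AnalysisReport:
    """Run the full pipeline on a cohort.  Pure function of its inputs."""
    options = options or AnalysisOptions()
    if len(cohort) < 8:
        raise ValueError("cohort must have >= 8 records for a quartile analysis")
    errors = [f for f in validate_cohort(cohort) if f.severity == "error"]
    if errors:
        raise ValueError(f"cohort fails validation: {errors[0].patient_id}/{errors[0].field}")

    # complete-case set for the main analysis: metrics computable + outcome known
    metrics: dict[str, CellLossMetrics] = {}
    complete = []
    for r in cohort:
        if r.outcome is None:
            continue
        try:
            metrics[r.patient_id] = compute_metrics(r)
        except ValueError:
            continue
        complete.append(r)
    if len(complete) < 8:
        raise ValueError("fewer than 8 complete-case records")
    by_id = {r.patient_id: r for r in complete}

    grouping = assign_quartiles(
        {pid: m.m_baseline for pid, m in metrics.items() if pid in by_id},
        stratifier="baseline cell-loss metric",
    )

    # descriptive tables: both metric variants plus the measured quantities
    variables = {
        "m_baseline": {pid: metrics[pid].m_baseline for pid in by_id},
        "m_post2": {pid: metrics[pid].m_post2 for pid in by_id},
        "dm_post2": {pid: metrics[pid].dm_post2 for pid in by_id},
        "vol_baseline": {pid: _volume_at(by_id[pid], Timepoint.BASELINE) for pid in by_id},
        "vol_intercycle": {
            pid: _volume_at(by_id[pid], Timepoint.POST_CYCLE2_48H) for pid in by_id
        },
        "stk1_baseline": {pid: by_id[pid].stk1[Timepoint.BASELINE] for pid in by_id},
        "stk1_post2": {pid: by_id[pid].stk1[Timepoint.POST_CYCLE2_48H] for pid in by_id},
    }
    pre2_ids = [pid for pid in by_id if metrics[pid].m_pre2 is not None]
    if pre2_ids:
        variables["m_pre2"] = {pid: metrics[pid].m_pre2 for pid in pre2_ids}
        variables["dm_pre2"] = {pid: metrics[pid].dm_pre2 for pid in pre2_ids}
    descriptive = {
        name: {col: s.to_dict() for col, s in cols.items()}
        for name, cols in group_summaries(variables, grouping).items()
    }

    # outcome by quartile
    col_labels = ("q1", "q2", "q3", "q4")
    pcr_row = []
    non_row = []
    for g in (1, 2, 3, 4):
        ids = grouping.group_ids(g)
        n_pcr = sum(1 for pid in ids if by_id[pid].outcome is Outcome.PCR)
        pcr_row.append(n_pcr)
        non_row.append(len(ids) - n_pcr)
    outcome_tab = ContingencyTable.from_rows(
        pcr_row, non_row, row_labels=("pCR", "non-pCR"), col_labels=col_labels
    )
    sizes = grouping.sizes()
    pcr_percent = [100.0 * a / s for a, s in zip(pcr_row, sizes)]

    tests: dict[str, TestResult] = {}
    tests["pcr_by_quartile_fisher_2x4"] = fisher_exact_2xk(outcome_tab)
    for ga, gb in combinations((1, 2, 3, 4), 2):
        ia, ib = ga - 1, gb - 1
        tests[f"pcr_q{ga}_vs_q{gb}_fisher_2x2"] = fisher_exact_2xk(
            ContingencyTable.from_rows(
                (pcr_row[ia], pcr_row[ib]),
                (non_row[ia], non_row[ib]),
                row_labels=("pCR", "non-pCR"),
                col_labels=(f"q{ga}", f"q{gb}"),
            )
        )
        # 3-category pathologic status: rows = the two quartiles
        cats = ("pCR", "pT1", "pT2+pT3")
        rows = []
        for g in (ga, gb):
            ids = grouping.group_ids(g)
            rows.append(
                tuple(
                    sum(1 for pid in ids if _OUTCOME_3CAT[by_id[pid].outcome] == c)
                    for c in cats
                )
            )
        tests[f"outcome3_q{ga}_vs_q{gb}_fisher_2x3"] = fisher_exact_2xk(
            ContingencyTable.from_rows(
                rows[0], rows[1], row_labels=(f"q{ga}", f"q{gb}"), col_labels=cats
            )
        )

    # pCR vs non-pCR comparisons of volume, sTK1 and metric per timepoint
    pcr_ids = [pid for pid in by_id if by_id[pid].outcome is Outcome.PCR]
    non_ids = [pid for pid in by_id if by_id[pid].outcome is not Outcome.PCR]
    comparisons = {
        "baseline_volume": variables["vol_baseline"],
        "baseline_stk1": variables["stk1_baseline"],
        "baseline_metric": variables["m_baseline"],
        "post2_volume": variables["vol_intercycle"],
        "post2_stk1": variables["stk1_post2"],
        "post2_metric": variables["m_post2"],
        "post2_metric_baseline_subtracted": variables["dm_post2"],
    }
    if pre2_ids:
        comparisons["pre2_stk1"] = {
            pid: by_id[pid].stk1[Timepoint.PRE_CYCLE2] for pid in pre2_ids
        }
        comparisons["pre2_metric"] = variables["m_pre2"]
        comparisons["pre2_metric_baseline_subtracted"] = variables["dm_pre2"]
    for name, mapping in comparisons.items():
        x = [mapping[pid] for pid in pcr_ids if pid in mapping]
        y = [mapping[pid] for pid in non_ids if pid in mapping]
        if x and y:
            tests[f"pcr_vs_nonpcr_{name}_wilcoxon"] = wilcoxon_test(x, y, paired=False)

    # covariate ANOVAs: pCR indicator as 0/1 response, grouped by covariate level
    def _anova_by(name, level_of):
        groups: dict = {}
        for pid in by_id:
            lev = level_of(by_id[pid])
            if lev is None:
                continue
            groups.setdefault(lev, []).append(
                1.0 if by_id[pid].outcome is Outcome.PCR else 0.0
            )
        usable = [g for g in groups.values() if g]
        if len(usable) >= 2 and sum(len(g) for g in usable) > len(usable):
            tests[f"pcr_vs_{name}_anova"] = anova_oneway(usable)

    _anova_by("stage", lambda r: r.covariates.stage)
    _anova_by("menopause", lambda r: r.covariates.menopause)
    _anova_by("er_status", lambda r: r.covariates.er_positive)
    _anova_by("pr_status", lambda r: r.covariates.pr_positive)
    _anova_by("histology", lambda r: r.covariates.histology)
    _anova_by("nodal_status", lambda r: r.covariates.node_positive)
    _anova_by("subtype", lambda r: r.covariates.subtype)
    ki = {pid: by_id[pid].covariates.ki67_percent for pid in by_id}
    ki = {pid: v for pid, v in ki.items() if v is not None}
    if len(ki) >= 8:
        ki_grouping = assign_quartiles(ki, stratifier="ki67")
        _anova_by("ki67_quartile", lambda r: ki_grouping.labels.get(r.patient_id))

    # ROC / cut-off / predictive values
    score_attr = "m_post2" if options.use_raw_metric else "dm_post2"
    scores48 = {pid: getattr(metrics[pid], score_attr) for pid in by_id}
    labels = {
        pid: "positive" if by_id[pid].outcome is Outcome.PCR else "negative" for pid in by_id
    }
    roc48 = roc_curve(scores48, labels)
    tests["roc_48h_mann_whitney"] = wilcoxon_test(
        [scores48[pid] for pid in pcr_ids], [scores48[pid] for pid in non_ids], paired=False
    )
    if options.cutoff_48h is not None:
        cut48 = options.cutoff_48h
        conf48 = evaluate_cutoff(scores48, labels, cut48)
    else:
        cut48, conf48 = youden_cutoff(scores48, labels)

    roc_pre2 = cut_pre2 = conf_pre2 = None
    pre_attr = "m_pre2" if options.use_raw_metric else "dm_pre2"
    scores_pre2 = {
        pid: getattr(metrics[pid], pre_attr) for pid in pre2_ids
    }
    labels_pre2 = {pid: labels[pid] for pid in pre2_ids}
    if scores_pre2 and len(set(labels_pre2.values())) == 2:
        roc_pre2 = roc_curve(scores_pre2, labels_pre2)
        if options.cutoff_pre2 is not None:
            cut_pre2 = options.cutoff_pre2
            conf_pre2 = evaluate_cutoff(scores_pre2, labels_pre2, cut_pre2)
        else:
            cut_pre2, conf_pre2 = youden_cutoff(scores_pre2, labels_pre2)

    # residual tumour volume vs 48 h metric among incomplete responders
    resid_ids = [
        pid
        for pid in non_ids
        if by_id[pid].residual_volume is not None and by_id[pid].residual_volume > 0
    ]
    if len(resid_ids) >= 3:
        dm = [metrics[pid].dm_post2 for pid in resid_ids]
        rv = [by_id[pid].residual_volume for pid in resid_ids]
        try:
            tests["residual_volume_vs_dm_post2_spearman"] = spearman_correlation(dm, rv)
        except ValueError:
            pass
        # transparency: OLS of log residual volume on log metric
        from scipy.stats import linregress

        fit = linregress(np.log(np.maximum(np.asarray(dm), 1e-6)), np.log(np.asarray(rv)))
        tests["residual_volume_loglog_ols"] = TestResult(
            p_value=float(fit.pvalue),
            method="ols_loglog_slope",
            n_used=len(resid_ids),
            statistic=float(fit.slope),
            extra={"intercept": float(fit.intercept)},
        )

    return AnalysisReport(
        n_total=len(cohort),
        n_complete=len(complete),
        n_pre2=len(pre2_ids),
        metrics=metrics,
        grouping=grouping,
        descriptive=descriptive,
        outcome_by_quartile=outcome_tab,
        pcr_percent_by_quartile=pcr_percent,
        tests=tests,
        roc_48h=roc48,
        cutoff_48h=cut48,
        confusion_48h=conf48,
        roc_pre2=roc_pre2,
        cutoff_pre2=cut_pre2,
        confusion_pre2=conf_pre2,
        options=options,
    )
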