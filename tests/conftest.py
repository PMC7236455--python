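import pytest

from cellloss.cohort import CohortTable, Covariates, Outcome, PatientRecord, Timepoint
from cellloss.simulate import default_config, generate


@pytest.fixture(scope="session")
def reference_cohort() -> CohortTable:
    """The reference synthetic cohort: default profiles, n=104, fixture seed."""
    return generate(default_config())


def make_record(
    pid: str,
    stk1_baseline: float,
    stk1_post2: float,
    vol_baseline: float,
    vol_intercycle: float,
    outcome: Outcome = Outcome.PT2,
    residual: float = 10.0,
    stk1_pre2: float | None = None,
    **cov,
) -> PatientRecord:
    """Hand-built patient record for micro-examples."""
    stk1 = {Timepoint.BASELINE: stk1_baseline, Timepoint.POST_CYCLE2_48H: stk1_post2}
    if stk1_pre2 is not None:
        stk1[Timepoint.PRE_CYCLE2] = stk1_pre2
    return PatientRecord(
        patient_id=pid,
        stk1=stk1,
        tumour_volume={
            Timepoint.BASELINE: vol_baseline,
            Timepoint.POST_CYCLE2_48H: vol_intercycle,
        },
        outcome=outcome,
        residual_volume=0.0 if outcome is Outcome.PCR else residual,
        covariates=Covariates(
            age=cov.get("age", 50.0),
            menopause=cov.get("menopause", "pre"),
            stage=cov.get("stage", 2),
            histology=cov.get("histology", "ductal"),
            subtype=cov.get("subtype", "lumA"),
            er_positive=cov.get("er_positive", True),
            pr_positive=cov.get("pr_positive", True),
            ki67_percent=cov.get("ki67_percent", 30.0),
            node_positive=cov.get("node_positive", False),
        ),
    )
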