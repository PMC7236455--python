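"""The cell-loss metric: sTK1 per unit tumour volume.

Thymidine kinase 1 is released into blood when proliferating cells are
disrupted, so the ratio of its serum concentration to the tumour volume,

    M = sTK1 / V        (ng ml^-1 cm^-3)

estimates the per-volume rate of tumour cell loss.  The on-treatment
metric uses the sTK1 level 48 h after the 2nd chemotherapy cycle divided
by the tumour volume measured between the 2nd and 3rd cycle; subtracting
the pre-treatment (baseline) metric isolates the treatment-induced part,

    dM = M_t - M_0,

which may legitimately be negative.  Tumour volumes are derived from the
largest diameter d under a spherical model, V = pi d^3 / 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import PatientRecord, Timepoint

__all__ = [
    "CellLossMetrics",
    "sphere_volume",
    "cell_loss_metric",
    "baseline_subtract",
    "compute_metrics",
]


@dataclass(frozen=True)
class CellLossMetrics:
    """Per-patient metric values (raw and baseline-subtracted).

    All values are in ng·ml^-1·cm^-3.  ``m_pre2``/``dm_pre2`` are ``None``
    for patients without a pre-cycle-2 sample.
    """

    m_baseline: float
    m_post2: float
    dm_post2: float
    m_pre2: float | None = None
    dm_pre2: float | None = None


def sphere_volume(largest_diameter: float) -> float:
    """Sphere-equivalent tumour volume (cm^3) from the largest diameter (cm)."""
    if not largest_diameter > 0:
        raise ValueError(f"diameter must be positive, got {largest_diameter}")
    return math.pi * largest_diameter**3 / 6.0


def cell_loss_metric(stk1: float, volume: float) -> float:
    """Cell-loss metric M = sTK1 / V.

    A measured volume of zero is rejected rather than producing infinity.
    """
    if stk1 < 0:
        raise ValueError(f"sTK1 concentration must be non-negative, got {stk1}")
    if not volume > 0:
        raise ValueError(f"tumour volume must be positive, got {volume}")
    return stk1 / volume


def baseline_subtract(m_t: float, m_0: float) -> float:
    """Baseline-corrected metric dM = M_t - M_0; negative results preserved."""
    if not (math.isfinite(m_t) and math.isfinite(m_0)):
        raise ValueError("metric values must be finite")
    return m_t - m_0


def _volume_at(record: PatientRecord, tp: Timepoint) -> float | None:
    v = record.tumour_volume.get(tp)
    if v is not None:
        return v
    d = record.tumour_diameter.get(tp)
    if d is not None:
        return sphere_volume(d)
    return None


def compute_metrics(record: PatientRecord) -> CellLossMetrics:
    """Assemble the per-timepoint metrics for one patient.

    Requires baseline sTK1 + baseline volume and 48 h sTK1 + inter-cycle
    volume.  The pre-cycle-2 metric, when the sample exists, divides by the
    same inter-cycle volume (the only on-treatment volume measurement).
    Volumes are derived from diameters via :func:`sphere_volume` when no
    measured volume is present.
    """
    s0 = record.stk1.get(Timepoint.BASELINE)
    if s0 is None:
        raise ValueError(f"{record.patient_id}: missing baseline sTK1")
    v0 = _volume_at(record, Timepoint.BASELINE)
    if v0 is None:
        raise ValueError(f"{record.patient_id}: missing baseline tumour volume/diameter")
    s2 = record.stk1.get(Timepoint.POST_CYCLE2_48H)
    if s2 is None:
        raise ValueError(f"{record.patient_id}: missing 48 h post-cycle-2 sTK1")
    v1 = _volume_at(record, Timepoint.POST_CYCLE2_48H)
    if v1 is None:
        raise ValueError(f"{record.patient_id}: missing inter-cycle tumour volume/diameter")

    m0 = cell_loss_metric(s0, v0)
    m2 = cell_loss_metric(s2, v1)
    out = {
        "m_baseline": m0,
        "m_post2": m2,
        "dm_post2": baseline_subtract(m2, m0),
    }
    s1 = record.stk1.get(Timepoint.PRE_CYCLE2)
    if s1 is not None:
        m1 = cell_loss_metric(s1, v1)
        out["m_pre2"] = m1
        out["dm_pre2"] = baseline_subtract(m1, m0)
    return CellLossMetrics(**out)
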