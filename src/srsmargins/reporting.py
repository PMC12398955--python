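"""Plan evaluation and paired GMC-vs-OMC comparison reports."""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .dosimetry import (
    cumulative_dvh,
    dose_at_volume,
    efficiency_index_12,
    gradient_index,
    paddick_ci,
    v12_healthy_brain,
)
from .plan_model import MarginVector, Plan
from .synthetic import (
    DEFAULT_BRAIN_SEMIAXES,
    DoseModelParams,
    brain_mask,
    generate_dose,
    grid_geometry,
    lesion_masks,
    ptv_masks,
)

__all__ = ["evaluate_plan", "compare_criteria", "quality_flags"]

log = logging.getLogger("srsmargins")

#: Plan-quality thresholds: PCI > 0.5 is a hard requirement; the GI
#: band 3-6 and V12 < 10 cm^3 are advisory, with a hard note at 15 cm^3.
PCI_MIN = 0.5
GI_BAND = (3.0, 6.0)
V12_ADVISORY = 10.0
V12_HARD = 15.0


def evaluate_plan(
    plan: Plan,
    margins: list[MarginVector],
    dose_params: DoseModelParams | None = None,
    brain_semiaxes=DEFAULT_BRAIN_SEMIAXES,
    spie: float = 0.0,
) -> dict:
    """Quality indices of a synthetic-dose plan under given margins.

    Builds the radial-falloff dose for the margins, then reports
    plan-level D99, PCI (targets = PTV union), GI, EI12Gy and
    healthy-brain V12, plus per-lesion PCI.
    """
    from .radiobiology import flickinger_injury, ntcp_milano

    dose_params = dose_params or DoseModelParams()
    geometry = grid_geometry(plan, margins, dose_params)
    dose = generate_dose(plan, margins, dose_params, geometry=geometry)
    shape, spacing, origin = geometry
    ptvs = ptv_masks(plan, margins, shape, spacing, origin)
    gtvs = lesion_masks(plan, shape, spacing, origin)
    brain = brain_mask(shape, spacing, origin, brain_semiaxes)
    rx = plan.lesions[0].prescription

    union = ptvs[0].values.copy()
    for m in ptvs[1:]:
        union |= m.values
    union_mask = type(ptvs[0])(union, spacing, origin)

    dvh = cumulative_dvh(dose, union_mask)
    v12 = v12_healthy_brain(dose, brain, gtvs=gtvs)
    out = {
        "patient_id": plan.patient_id,
        "n_metastases": plan.n_metastases,
        "d99": dose_at_volume(dvh, 0.99),
        "pci": paddick_ci(dose, ptvs, rx),
        "gi": gradient_index(dose, rx),
        "ei12": efficiency_index_12(dose, ptvs),
        "v12": v12,
        "ntcp": ntcp_milano(v12),
        "p_injury": flickinger_injury(spie, v12),
        "pci_per_lesion": [paddick_ci(dose, m, les.prescription) for m, les in zip(ptvs, plan.lesions)],
    }
    return out


def quality_flags(metrics: dict) -> dict:
    """Threshold flags for one evaluated plan."""
    return {
        "pci_ok": metrics["pci"] > PCI_MIN,
        "gi_in_band": GI_BAND[0] < metrics["gi"] < GI_BAND[1],
        "v12_advisory_ok": metrics["v12"] < V12_ADVISORY,
        "v12_hard_ok": metrics["v12"] < V12_HARD,
    }


def _paired_stats(a: np.ndarray, b: np.ndarray) -> dict:
    # identical paired lists: t = 0, p = 1; correlation of identical
    # series reported as 1 (undefined for a constant series)
    if np.allclose(a, b):
        corr = float(stats.pearsonr(a, b)[0]) if np.std(a) > 0 else 1.0
        return {"t": 0.0, "p": 1.0, "pearson_r": corr}
    t, p = stats.ttest_rel(a, b)
    if math.isnan(t):
        t, p = 0.0, 1.0
    if np.std(a) > 0 and np.std(b) > 0:
        corr = float(stats.pearsonr(a, b)[0])
    else:
        corr = float("nan")
    return {"t": float(t), "p": float(p), "pearson_r": corr}


def compare_criteria(evaluations: dict[str, tuple[list, list]]) -> dict:
    """Paired comparison of per-plan metrics under two margin criteria.

    ``evaluations`` maps a metric name to the (reference, optimized)
    paired per-plan lists — conventionally (GMC, OMC).  Per metric:
    mean +/- sd for both criteria, paired t statistic and p-value,
    and Pearson correlation.  With fewer than 3 pairs the inferential
    statistics are suppressed with a warning.
    """
    report: dict = {"metrics": {}}
    for name, (ref, opt) in evaluations.items():
        a = np.asarray(ref, dtype=float)
        b = np.asarray(opt, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"metric {name!r}: paired lists must have equal length")
        entry = {
            "n": int(a.size),
            "reference_mean": float(a.mean()),
            "reference_sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
            "optimized_mean": float(b.mean()),
            "optimized_sd": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        }
        if a.size < 3:
            log.warning("metric %s: fewer than 3 pairs, statistics suppressed", name)
            entry["statistics"] = None
        else:
            entry["statistics"] = _paired_stats(a, b)
        report["metrics"][name] = entry
    return report
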