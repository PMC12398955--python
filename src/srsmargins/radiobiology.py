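"""Radionecrosis risk models.

Two logistic dose-response models of symptomatic brain injury after
radiosurgery, both driven by the healthy-brain volume receiving at
least 12 Gy (V12):

* the NTCP model of any radionecrosis,
  ``NTCP = logistic(4 * gamma50 * (Vx / Vx50 - 1))`` with
  ``Vx50 = 63.2 cm^3`` (the volume at 50% risk) and slope
  ``gamma50 = 0.87``;
* the permanent-symptomatic-injury model,
  ``P = logistic(-7.8713 + 0.7506 * SPIE + 0.0734 * V12)``, where
  SPIE is a location-based risk score.  SPIE must be supplied by the
  caller from the cited clinical literature — its per-location score
  table is not reproduced here.

Probabilities are returned as fractions; convert to percent only at
the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NTCPParams",
    "InjuryModelParams",
    "ntcp_milano",
    "flickinger_injury",
    "risk_report",
]


@dataclass(frozen=True)
class NTCPParams:
    """Logistic NTCP parameters: V at 50% risk (cm^3) and slope."""

    v_x50: float = 63.2
    gamma50: float = 0.87

    def __post_init__(self) -> None:
        if self.v_x50 <= 0 or self.gamma50 <= 0:
            raise ValueError("v_x50 and gamma50 must be > 0")


@dataclass(frozen=True)
class InjuryModelParams:
    """Permanent-injury logistic coefficients (intercept, SPIE, V12)."""

    intercept: float = -7.8713
    spie_coef: float = 0.7506
    v12_coef: float = 0.0734


def _logistic(z: float) -> float:
    # symmetric formulation, stable for large |z|
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def ntcp_milano(v_x: float, params: NTCPParams | None = None) -> float:
    """Probability of any radionecrosis at irradiated volume ``v_x`` (cm^3)."""
    if v_x < 0:
        raise ValueError("v_x must be >= 0")
    params = params or NTCPParams()
    z = 4.0 * params.gamma50 * (v_x / params.v_x50 - 1.0)
    return _logistic(z)


def flickinger_injury(spie: float, v12: float, params: InjuryModelParams | None = None) -> float:
    """Probability of permanent symptomatic post-radiosurgery injury."""
    if v12 < 0:
        raise ValueError("v12 must be >= 0")
    params = params or InjuryModelParams()
    z = params.intercept + params.spie_coef * spie + params.v12_coef * v12
    return _logistic(z)


def risk_report(
    v12: float,
    spie: float = 0.0,
    reference_v12: float | None = None,
    ntcp_params: NTCPParams | None = None,
    injury_params: InjuryModelParams | None = None,
) -> dict:
    """Per-plan risk summary from a V12 evaluation.

    When a ``reference_v12`` is supplied (e.g. the geometric-criterion
    plan paired with an optimized one), both model ratios
    (evaluated / reference) are included.
    """
    if v12 is None:
        raise ValueError("V12 is required")
    ntcp = ntcp_milano(v12, ntcp_params)
    injury = flickinger_injury(spie, v12, injury_params)
    report = {"v12_cm3": float(v12), "spie": float(spie), "ntcp": ntcp, "p_injury": injury}
    if reference_v12 is not None:
        ref_ntcp = ntcp_milano(reference_v12, ntcp_params)
        ref_injury = flickinger_injury(spie, reference_v12, injury_params)
        report["ntcp_ratio"] = ntcp / ref_ntcp
        report["p_injury_ratio"] = injury / ref_injury
    return report
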