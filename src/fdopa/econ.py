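"""Illustrative screening economics for biomarker-guided clozapine fast-tracking.

Closed-form expected-value model over a screened cohort:

    TP = prevalence * sensitivity * N          FN = prevalence * (1-sens) * N
    FP = (1-prevalence) * (1-specificity) * N  TN = (1-prevalence) * spec * N
    benefit = TP * response_prob * annual_saving * delay_years
    cost    = N * scan_cost
              + (TP+FP) * (clozapine_annual_cost * delay_years
                           + neutropenia_rate * neutropenia_cost)
              + FP * false_positive_penalty
    net per screened patient = (benefit - cost) / N

Every quantity is a named parameter. The published analyses behind the
clozapine treatment cost and any false-positive harm give no single number,
so those default to zero and should be set explicitly for realistic runs.
Currency is GBP throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["EconScenario", "EconOutcome", "econ_outcome", "breakeven_sensitivity", "savings_surface"]

#: annual active-psychosis minus remitted healthcare cost (GBP)
DERIVED_ANNUAL_SAVING = 39141.0 - 15086.0  # 24055


@dataclass(frozen=True)
class EconScenario:
    cohort_size: float = 1000.0
    scan_cost: float = 3000.0
    prevalence: float = 0.33  # fraction not responding to first-line drugs
    annual_active_cost: float = 39141.0
    annual_remitted_cost: float = 15086.0
    annual_saving: float = DERIVED_ANNUAL_SAVING
    delay_years_avoided: float = 4.0
    clozapine_response_prob: float = 0.5
    clozapine_annual_cost: float = 0.0  # no published value; set explicitly
    neutropenia_rate: float = 0.03
    neutropenia_cost: float = 0.0  # no published value; set explicitly
    false_positive_penalty: float = 0.0
    sensitivity: float = 0.5
    specificity: float = 0.95

    def __post_init__(self) -> None:
        for name in ("prevalence", "clozapine_response_prob", "neutropenia_rate",
                     "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("cohort_size", "scan_cost", "annual_active_cost",
                     "annual_remitted_cost", "delay_years_avoided",
                     "clozapine_annual_cost", "neutropenia_cost",
                     "false_positive_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be > 0")


@dataclass(frozen=True)
class EconOutcome:
    true_positives: float
    false_positives: float
    true_negatives: float
    false_negatives: float
    total_benefit: float
    total_cost: float
    net_saving_per_patient: float


def econ_outcome(scenario: EconScenario) -> EconOutcome:
    """Evaluate the closed-form model at the scenario's operating point."""
    n = scenario.cohort_size
    tp = scenario.prevalence * scenario.sensitivity * n
    fn = scenario.prevalence * (1.0 - scenario.sensitivity) * n
    fp = (1.0 - scenario.prevalence) * (1.0 - scenario.specificity) * n
    tn = (1.0 - scenario.prevalence) * scenario.specificity * n
    benefit = (
        tp * scenario.clozapine_response_prob
        * scenario.annual_saving * scenario.delay_years_avoided
    )
    per_positive = (
        scenario.clozapine_annual_cost * scenario.delay_years_avoided
        + scenario.neutropenia_rate * scenario.neutropenia_cost
    )
    cost = (
        n * scenario.scan_cost
        + (tp + fp) * per_positive
        + fp * scenario.false_positive_penalty
    )
    return EconOutcome(tp, fp, tn, fn, benefit, cost, (benefit - cost) / n)


def _net(scenario: EconScenario, sensitivity: float, specificity: float) -> float:
    return econ_outcome(
        replace(scenario, sensitivity=sensitivity, specificity=specificity)
    ).net_saving_per_patient


def breakeven_sensitivity(
    scenario: EconScenario, specificity: float, tol: float = 1e-6
) -> float | None:
    """Sensitivity at which net saving crosses zero, by bisection to ``tol``.

    Returns None when the model never breaks even on [0, 1]; 0.0 when it is
    already favourable at zero sensitivity. Requires net saving strictly
    increasing in sensitivity.
    """
    lo, hi = _net(scenario, 0.0, specificity), _net(scenario, 1.0, specificity)
    if hi == lo:  # sensitivity has no effect (e.g. zero benefit channel)
        return 0.0 if lo >= 0 else None
    if hi < lo:
        raise ValueError(
            "net saving is not increasing in sensitivity under this scenario; "
            "use savings_surface for a grid scan"
        )
    if lo >= 0:
        return 0.0
    if hi < 0:
        return None
    a, b = 0.0, 1.0
    while b - a > tol:
        m = 0.5 * (a + b)
        if _net(scenario, m, specificity) < 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def savings_surface(
    scenario: EconScenario,
    sensitivity_grid=np.linspace(0.0, 1.0, 21),
    specificity_grid=np.linspace(0.0, 1.0, 21),
) -> pd.DataFrame:
    """Net saving per screened patient over a sensitivity x specificity grid."""
    sens = np.asarray(sensitivity_grid, dtype=float)
    spec = np.asarray(specificity_grid, dtype=float)
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise ValueError("grids must lie in [0, 1]")
    rows = [
        {"sensitivity": s, "specificity": q,
         "net_saving_per_patient_gbp": _net(scenario, s, q)}
        for s in sens for q in spec
    ]
    return pd.DataFrame(rows)
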