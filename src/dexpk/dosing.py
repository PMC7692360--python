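"""Dose-rate simulation: loading doses, maintenance rates and demographic tables.

Translates individual clearance and volumes into infusion regimens that
achieve and hold a target plasma concentration (1 µg/L by default for
sedation outside intensive care). The steady-state maintenance rate is
CL·Css scaled to µg/kg/h; the loading dose is the 30-minute infusion that
reaches the target at end of infusion; the stepped maintenance schedule
tracks the target while the peripheral compartments fill.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    CovariateRecord,
    DoseEvent,
    PKParameters,
    ThetaSet,
    DEFAULT_THETA,
    concentrations,
    individual_parameters,
    simulate_profile,
)

__all__ = [
    "DoseRecommendation",
    "steady_state_rate",
    "loading_dose",
    "maintenance_schedule",
    "dose_table",
    "TABLE_DEMOGRAPHICS",
]


@dataclass
class DoseRecommendation:
    """Dosing summary for one subject at a target plasma concentration."""

    age_label: str
    age_years: float
    weight_kg: float
    height_cm: float
    clearance_L_min: float
    loading_ug_kg: float  # delivered over 30 min
    maintenance_ug_kg_h: float  # steady-state rate
    target_ug_L: float


#: Demographic rows of the simulated dosing table: label, age (y), weight (kg), height (cm).
TABLE_DEMOGRAPHICS: tuple[tuple[str, float, float, float], ...] = (
    ("Term neonate", 0.0, 3.6, 50.0),
    ("3 months", 0.25, 6.0, 62.0),
    ("6 months", 0.5, 7.8, 67.0),
    ("1 year", 1.0, 10.0, 75.0),
    ("3 years", 3.0, 14.0, 95.0),
    ("6 years", 6.0, 21.0, 115.0),
    ("12 years", 12.0, 40.0, 149.0),
    ("20 years", 20.0, 70.0, 175.0),
)


def steady_state_rate(cl_L_min: float, css_ug_L: float, weight_kg: float) -> float:
    """Maintenance infusion rate (µg/kg/h) holding Css at steady state.

    At steady state input balances elimination: rate = CL·Css, converted to
    per-kg per-hour units.
    """
    if cl_L_min <= 0 or weight_kg <= 0 or css_ug_L < 0:
        raise ValueError("clearance and weight must be positive; target non-negative")
    return cl_L_min * css_ug_L * 60.0 / weight_kg


def loading_dose(
    params: PKParameters,
    target_ug_L: float,
    weight_kg: float,
    duration_min: float = 30.0,
) -> float:
    """Loading dose (µg/kg) as a constant-rate infusion reaching the target.

    Solves for the dose whose simulated concentration at the end of the
    infusion equals the target. The system is linear, so concentration is
    proportional to dose and the root is found by direct scaling refined to
    the solver tolerance.
    """
    if target_ug_L <= 0:
        raise ValueError("target must be positive")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    end = np.array([duration_min])

    def conc_at_end(dose_ug: float) -> float:
        return concentrations(params, [DoseEvent.infusion(0.0, duration_min, dose_ug)], end)[0]

    hi_per_kg = 100.0
    c_hi = conc_at_end(hi_per_kg * weight_kg)
    if c_hi < target_ug_L:
        raise ValueError("target not reachable within 100 µg/kg")
    dose = brentq(
        lambda d: conc_at_end(d) - target_ug_L,
        0.0,
        hi_per_kg * weight_kg,
        xtol=1e-6,
    )
    return dose / weight_kg


def maintenance_schedule(
    params: PKParameters,
    target_ug_L: float,
    horizon_min: float,
    step_min: float = 5.0,
    loading_duration_min: float = 30.0,
    weight_kg: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stepped plasma-targeting infusion rates after a 30-min loading phase.

    Returns (step start times min, rates µg/min). At each step the rate
    balances elimination at the target plus the current net flux from the
    central into the not-yet-equilibrated peripheral compartments, recomputed
    from the simulated state; rates decay towards the steady-state CL·target
    as the peripheral compartments fill.
    """
    if target_ug_L <= 0:
        raise ValueError("target must be positive")
    if horizon_min <= loading_duration_min:
        raise ValueError("horizon must exceed the loading duration")
    wt = weight_kg if weight_kg is not None else 1.0
    load = loading_dose(params, target_ug_L, wt, loading_duration_min) * wt
    events = [DoseEvent.infusion(0.0, loading_duration_min, load)]

    starts = np.arange(loading_duration_min, horizon_min, step_min)
    rates = np.empty(len(starts))
    for i, t0 in enumerate(starts):
        prof = simulate_profile(params, events, np.array([t0]))
        a2, a3 = prof.amounts[0, 1], prof.amounts[0, 2]
        # hold central at target: elimination + net peripheral uptake
        rate = (
            params.cl * target_ug_L
            + params.q2 * (target_ug_L - a2 / params.v2)
            + params.q3 * (target_ug_L - a3 / params.v3)
        )
        rate = max(rate, 0.0)
        rates[i] = rate
        end = min(t0 + step_min, horizon_min)
        events.append(DoseEvent(start=float(t0), duration=float(end - t0), rate=float(rate)))
    return starts, rates


def dose_table(
    theta: ThetaSet = DEFAULT_THETA,
    demographic_rows: Sequence[tuple[str, float, float, float]] = TABLE_DEMOGRAPHICS,
    target_ug_L: float = 1.0,
    sex: str = "male",
) -> list[DoseRecommendation]:
    """Simulated dosing table across the age range.

    Per row the individual clearance and volumes come from the covariate
    model (sex defaults to male, matching the standardisation subject), the
    loading dose from the 30-minute targeting solve, and the maintenance
    rate from the steady-state balance on the computed clearance.
    """
    out = []
    for label, age, wt, ht in demographic_rows:
        cov = CovariateRecord(age=age, weight_tbw=wt, height=ht, sex=sex)
        params = individual_parameters(theta, cov)
        out.append(
            DoseRecommendation(
                age_label=label,
                age_years=age,
                weight_kg=wt,
                height_cm=ht,
                clearance_L_min=params.cl,
                loading_ug_kg=loading_dose(params, target_ug_L, wt),
                maintenance_ug_kg_h=steady_state_rate(params.cl, target_ug_L, wt),
                target_ug_L=target_ug_L,
            )
        )
    return out
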