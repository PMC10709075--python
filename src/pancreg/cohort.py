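"""Deterministic cohort engine.

Single 30-day decision cycle: the incident cohort is funneled to the
operated cohort, operations are split between high- and low-volume
centers, and each center class contributes 30-day deaths, complications
and complication costs.  Deaths and complications are independent
marginal counts — no joint distribution or overlap is modelled.

Two rounding policies are supported:

``"half-up"``
    Expected counts are rounded half-away-from-zero to whole patients at
    every funnel/allocation/outcome step.  This is the reporting
    convention: published cohort tables print integer patients, and this
    policy reproduces them exactly.
``"off"``
    Fractional expected counts are carried through every step (costs are
    then computed on fractional complication counts).  Used internally
    by sweeps, threshold solving and probabilistic sensitivity analysis,
    where rounding would introduce staircase artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CenterRates, ModelParameters, validate

ROUNDING_MODES = ("half-up", "off")

HVC = "HVC"
LVC = "LVC"


def round_half_up(x: float) -> int:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Python's ``round`` uses banker's rounding, which does not match how
    the published cohort counts were produced.
    """
    if x >= 0:
        return math.floor(x + 0.5)
    return math.ceil(x - 0.5)


def _round(x: float, rounding: str) -> float:
    if rounding == "half-up":
        return round_half_up(x)
    if rounding == "off":
        return x
    raise ValueError(f"rounding must be one of {ROUNDING_MODES}, got {rounding!r}")


@dataclass(frozen=True)
class CohortCounts:
    """Incidence -> resectable -> resected patient funnel."""

    n_incident: float
    n_resectable: float
    n_resected: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_resected <= self.n_resectable <= self.n_incident:
            raise ValueError(
                f"funnel must be monotone: {self.n_incident} >= "
                f"{self.n_resectable} >= {self.n_resected} >= 0"
            )


@dataclass(frozen=True)
class CenterOutcome:
    """30-day outcomes of one center class under one policy state."""

    center_class: str
    n_surgeries: float
    n_deaths: float
    n_complications: float
    complication_cost: float


@dataclass(frozen=True)
class StateResult:
    """Per-center outcomes and totals for one policy state."""

    label: str
    outcomes: tuple[CenterOutcome, ...]

    @property
    def total_surgeries(self) -> float:
        return sum(o.n_surgeries for o in self.outcomes)

    @property
    def total_deaths(self) -> float:
        return sum(o.n_deaths for o in self.outcomes)

    @property
    def total_complications(self) -> float:
        return sum(o.n_complications for o in self.outcomes)

    @property
    def total_cost(self) -> float:
        return sum(o.complication_cost for o in self.outcomes)


@dataclass(frozen=True)
class Differential:
    """Current-minus-future deltas: positive = saved by regionalizing."""

    delta_deaths: float
    delta_complications: float
    delta_cost: float


def derive_cohort(
    annual_incidence: float,
    p_resectable: float,
    p_resection: float,
    rounding: str = "half-up",
) -> CohortCounts:
    """Apply the incidence -> resectable -> resected funnel."""
    n_incident = _round(annual_incidence, rounding)
    n_resectable = _round(n_incident * p_resectable, rounding)
    n_resected = _round(n_resectable * p_resection, rounding)
    return CohortCounts(n_incident, n_resectable, n_resected)


def allocate(
    n_resected: float, p_hvc: float, rounding: str = "half-up"
) -> tuple[float, float]:
    """Split the operated cohort into (n_hvc, n_lvc).

    The LVC count is the remainder, not an independent rounding, so
    patients are conserved exactly.
    """
    if not 0.0 <= p_hvc <= 1.0:
        raise ValueError(f"p_hvc must be in [0, 1], got {p_hvc}")
    n_hvc = _round(n_resected * p_hvc, rounding)
    return n_hvc, n_resected - n_hvc


def center_outcomes(
    center_class: str,
    n_surgeries: float,
    rates: CenterRates,
    unit_cost: float,
    rounding: str = "half-up",
) -> CenterOutcome:
    """30-day deaths, complications and complication cost of one class.

    The cost is the exact product of the complication count and the unit
    cost — no further rounding, so integer inputs give integer dollars.
    """
    if n_surgeries < 0:
        raise ValueError(f"n_surgeries must be >= 0, got {n_surgeries}")
    n_deaths = _round(n_surgeries * rates.mortality_30d, rounding)
    n_complications = _round(n_surgeries * rates.complication_30d, rounding)
    return CenterOutcome(
        center_class=center_class,
        n_surgeries=n_surgeries,
        n_deaths=n_deaths,
        n_complications=n_complications,
        complication_cost=n_complications * unit_cost,
    )


def run_state(
    params: ModelParameters,
    hvc_fraction: float,
    label: str = "",
    rounding: str = "half-up",
) -> StateResult:
    """Evaluate one policy state end to end.

    ``hvc_fraction`` is the HVC allocation under the policy (it may
    differ from ``params.p_hvc``, which describes the current state).
    Outcomes are reported LVC first to mirror the published table; a
    class with zero surgeries is reported as zeros.
    """
    validate(params)
    cohort = derive_cohort(
        params.annual_incidence, params.p_resectable, params.p_resection, rounding
    )
    n_hvc, n_lvc = allocate(cohort.n_resected, hvc_fraction, rounding)
    outcomes = (
        center_outcomes(LVC, n_lvc, params.lvc_rates,
                        params.cost_per_complication_lvc, rounding),
        center_outcomes(HVC, n_hvc, params.hvc_rates,
                        params.cost_per_complication_hvc, rounding),
    )
    return StateResult(label=label, outcomes=outcomes)


def compare_states(current: StateResult, future: StateResult) -> Differential:
    """Current-minus-future differential in deaths, complications, cost.

    Both states must describe the same operated cohort.
    """
    cs, fs = current.total_surgeries, future.total_surgeries
    if not math.isclose(cs, fs, rel_tol=1e-12, abs_tol=1e-9):
        raise ValueError(
            f"states are not comparable: {cs} vs {fs} total surgeries"
        )
    return Differential(
        delta_deaths=current.total_deaths - future.total_deaths,
        delta_complications=current.total_complications - future.total_complications,
        delta_cost=current.total_cost - future.total_cost,
    )
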