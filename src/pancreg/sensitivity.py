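"""Deterministic sweeps, threshold solving, and probabilistic SA.

All three tools evaluate the same headline quantity: the differential
between the current state (the parameter set's own HVC fraction) and a
regionalized future state (100 % HVC unless stated otherwise).  They run
the engine in rounding-off mode — fractional expected counts — so sweep
curves are smooth and threshold solving is well-posed; whole-patient
reporting is a presentation concern left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Differential, compare_states, run_state
from .parameters import (
    PARAM_FIELDS,
    ModelParameters,
    ParameterRange,
    default_parameters,
    get_value,
    parameter_ranges,
    with_value,
)
from .synthetic import SamplingSpec, default_sampling_spec, sample_parameters

_METRICS = ("deaths", "complications", "cost")


@dataclass(frozen=True)
class SweepRow:
    """Differential at one tested value of one parameter."""

    parameter: str
    value: float
    delta_deaths: float
    delta_complications: float
    delta_cost: float


@dataclass(frozen=True)
class PsaSummary:
    """Monte-Carlo summary of the regionalization differential."""

    n_draws: int
    seed: int
    mean_delta_deaths: float
    lo95_delta_deaths: float
    hi95_delta_deaths: float
    mean_delta_complications: float
    lo95_delta_complications: float
    hi95_delta_complications: float
    mean_delta_cost: float
    lo95_delta_cost: float
    hi95_delta_cost: float
    frac_cost_saving: float


def regionalization_differential(
    params: ModelParameters,
    future_fraction: float = 1.0,
    rounding: str = "off",
) -> Differential:
    """Current state (at ``params.p_hvc``) minus the regionalized state."""
    current = run_state(params, params.p_hvc, "current", rounding)
    future = run_state(params, future_fraction, "future", rounding)
    return compare_states(current, future)


def one_way_sweep(
    param_name: str,
    prange: ParameterRange | None = None,
    n_points: int = 11,
    base: ModelParameters | None = None,
    future_fraction: float = 1.0,
) -> list[SweepRow]:
    """Evaluate the differential at evenly spaced values of one parameter.

    Endpoints are included; a degenerate range repeats its single value.
    All other parameters stay at ``base`` (defaults if omitted).
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if prange is None:
        prange = parameter_ranges()[param_name]
    elif prange.name != param_name:
        raise ValueError(f"range is for {prange.name!r}, not {param_name!r}")
    base = base if base is not None else default_parameters()
    rows = []
    for value in np.linspace(prange.low, prange.high, n_points):
        params = with_value(base, param_name, float(value))
        diff = regionalization_differential(params, future_fraction)
        rows.append(SweepRow(param_name, float(value), diff.delta_deaths,
                             diff.delta_complications, diff.delta_cost))
    return rows


def sweep_table(rows: list[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def tornado(
    ranges: Mapping[str, ParameterRange] | None = None,
    base: ModelParameters | None = None,
    metric: str = "cost",
) -> pd.DataFrame:
    """Differential at each parameter's range endpoints, widest span first.

    The classic one-way tornado summary: one row per non-degenerate
    parameter with the differential at its low and high bound.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    ranges = ranges if ranges is not None else parameter_ranges()
    attr = f"delta_{metric}"
    rows = []
    for name, prange in ranges.items():
        if prange.is_degenerate:
            continue
        ends = one_way_sweep(name, prange, n_points=2, base=base)
        at_low, at_high = getattr(ends[0], attr), getattr(ends[1], attr)
        rows.append({"parameter": name, "low": prange.low, "high": prange.high,
                     f"{attr}_at_low": at_low, f"{attr}_at_high": at_high,
                     "span": abs(at_high - at_low)})
    df = pd.DataFrame(rows)
    return df.sort_values("span", ascending=False, ignore_index=True)


def threshold_fraction(
    params: ModelParameters,
    metric: str,
    target: float,
    tol: float = 1e-6,
) -> float | None:
    """Smallest future HVC fraction whose differential reaches ``target``.

    Searches [params.p_hvc, 1] by bisection in rounding-off mode, where
    the differential is linear (hence monotone) in the fraction.
    Returns None if the target is unattainable even at complete
    regionalization.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    attr = f"delta_{metric}"

    def diff_at(fraction: float) -> float:
        return getattr(regionalization_differential(params, fraction), attr)

    lo, hi = params.p_hvc, 1.0
    if diff_at(hi) < target:
        return None
    if diff_at(lo) >= target:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if diff_at(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def psa_draws(
    spec: SamplingSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    dist: str = "uniform",
    future_fraction: float = 1.0,
) -> pd.DataFrame:
    """Per-draw parameter values and differentials.

    Either pass a full :class:`SamplingSpec`, or let one be built over
    every literature range (``dist`` as in
    :func:`~pancreg.synthetic.default_sampling_spec`).
    """
    if spec is None:
        spec = default_sampling_spec(seed=seed, n=n_draws, kind=dist)
    records = []
    for params in sample_parameters(spec):
        diff = regionalization_differential(params, future_fraction)
        rec = {name: get_value(params, name) for name in PARAM_FIELDS}
        rec.update(delta_deaths=diff.delta_deaths,
                   delta_complications=diff.delta_complications,
                   delta_cost=diff.delta_cost)
        records.append(rec)
    return pd.DataFrame(records)


def run_psa(
    spec: SamplingSpec | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    dist: str = "uniform",
    future_fraction: float = 1.0,
) -> PsaSummary:
    """Monte-Carlo propagation of parameter uncertainty.

    Samples parameter sets within their literature ranges, evaluates the
    regionalization differential for each, and summarizes with means and
    central 95 % intervals.  Identical seeds give identical summaries.
    """
    if spec is None:
        spec = default_sampling_spec(seed=seed, n=n_draws, kind=dist)
    df = psa_draws(spec=spec)
    def p(col, q):
        return float(np.percentile(df[col], q))
    return PsaSummary(
        n_draws=spec.n,
        seed=spec.seed,
        mean_delta_deaths=float(df["delta_deaths"].mean()),
        lo95_delta_deaths=p("delta_deaths", 2.5),
        hi95_delta_deaths=p("delta_deaths", 97.5),
        mean_delta_complications=float(df["delta_complications"].mean()),
        lo95_delta_complications=p("delta_complications", 2.5),
        hi95_delta_complications=p("delta_complications", 97.5),
        mean_delta_cost=float(df["delta_cost"].mean()),
        lo95_delta_cost=p("delta_cost", 2.5),
        hi95_delta_cost=p("delta_cost", 97.5),
        frac_cost_saving=float((df["delta_cost"] > 0).mean()),
    )
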