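"""Model parameter set: baseline values and literature ranges.

The model is driven by a small set of cohort-level inputs: the annual
statewide incidence of pancreatic cancer, the fraction of incident cases
with localized/regional (resectable) disease, the fraction of resectable
patients who actually undergo surgery, the split of operations between
high-volume centers (HVC, >=20 resections/year) and low-volume centers
(LVC), per-center 30-day mortality and complication rates, and a unit
cost per postoperative complication.

All proportions are stored as fractions in [0, 1]; percent values from
the literature are divided by 100 on entry.  The LVC allocation fraction
is never stored: it is always ``1 - p_hvc``, so the two allocation
probabilities sum to one by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Mapping


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants.

    ``fields`` lists every offending field path, so callers can report
    all violations at once instead of the first one found.
    """

    def __init__(self, fields: list[str], messages: list[str]):
        self.fields = list(fields)
        self.messages = list(messages)
        super().__init__("invalid parameters: " + "; ".join(messages))


@dataclass(frozen=True)
class CenterRates:
    """30-day outcome rates for one center class (HVC or LVC)."""

    mortality_30d: float
    complication_30d: float


@dataclass(frozen=True)
class ModelParameters:
    """Complete input set for the regionalization model.

    Attributes
    ----------
    annual_incidence : float
        New pancreatic cancer cases per year (persons).
    p_resectable : float
        Fraction of incident cases with localized/regional disease.
    p_resection : float
        Fraction of resectable patients who undergo surgery.
    p_hvc : float
        Fraction of operations performed at high-volume centers in the
        current state.  The low-volume fraction is ``1 - p_hvc``.
    hvc_rates, lvc_rates : CenterRates
        30-day mortality and complication rates per center class.
    cost_per_complication_hvc, cost_per_complication_lvc : float
        Cost (USD) attributed to each postoperative complication.  Equal
        at baseline; kept separate so differential-cost scenarios need
        no structural change.
    """

    annual_incidence: float
    p_resectable: float
    p_resection: float
    p_hvc: float
    hvc_rates: CenterRates
    lvc_rates: CenterRates
    cost_per_complication_hvc: float
    cost_per_complication_lvc: float

    @property
    def p_lvc(self) -> float:
        return 1.0 - self.p_hvc


@dataclass(frozen=True)
class ParameterRange:
    """Published low/high bound for one parameter.

    A parameter with a single published value gets ``low == high``.
    """

    name: str
    low: float
    high: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.name}: low {self.low} > high {self.high}")

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    def __contains__(self, value: float) -> bool:
        return self.low <= value <= self.high


# Flat field paths used by config files, overrides, sweeps and sampling.
PARAM_FIELDS: tuple[str, ...] = (
    "annual_incidence",
    "p_resectable",
    "p_resection",
    "p_hvc",
    "hvc_mortality_30d",
    "hvc_complication_30d",
    "lvc_mortality_30d",
    "lvc_complication_30d",
    "cost_per_complication_hvc",
    "cost_per_complication_lvc",
)

_NONNEGATIVE_FIELDS = frozenset(
    ("annual_incidence", "cost_per_complication_hvc", "cost_per_complication_lvc")
)


def default_parameters() -> ModelParameters:
    """Baseline parameter set (California, projected 2021 cohort).

    Mortality of 1.8 % (HVC) / 5.2 % (LVC) is the midpoint of the
    published per-class ranges; complication rates of 34.3 % / 39.8 %
    come from the statewide registry analysis; $16,815 is the published
    mean cost per postoperative complication, applied identically to
    both center classes at baseline.
    """
    return ModelParameters(
        annual_incidence=5958,
        p_resectable=0.41,
        p_resection=0.40,
        p_hvc=0.466,
        hvc_rates=CenterRates(mortality_30d=0.018, complication_30d=0.343),
        lvc_rates=CenterRates(mortality_30d=0.052, complication_30d=0.398),
        cost_per_complication_hvc=16815,
        cost_per_complication_lvc=16815,
    )


def parameter_ranges() -> dict[str, ParameterRange]:
    """Literature ranges per parameter, keyed by flat field path.

    Parameters with a single published value get a degenerate range
    (``low == high``).  Every baseline value lies inside its own range.
    """
    ranges = [
        ParameterRange("annual_incidence", 5958, 5958,
                       "projected statewide incidence, single registry estimate"),
        ParameterRange("p_resectable", 0.41, 0.41,
                       "localized/regional fraction, single registry estimate"),
        ParameterRange("p_resection", 0.21, 0.41,
                       "population-based resection rates across four registries"),
        ParameterRange("p_hvc", 0.466, 0.466,
                       "observed statewide allocation, single source"),
        ParameterRange("hvc_mortality_30d", 0.017, 0.021,
                       "national database analyses, high-volume centers"),
        ParameterRange("hvc_complication_30d", 0.337, 0.343,
                       "registry vs national inpatient sample, high-volume centers"),
        ParameterRange("lvc_mortality_30d", 0.045, 0.061,
                       "national database analyses, low-volume centers"),
        ParameterRange("lvc_complication_30d", 0.398, 0.413,
                       "registry vs national inpatient sample, low-volume centers"),
        ParameterRange("cost_per_complication_hvc", 9101, 17947,
                       "per-complication cost estimates across four sources"),
        ParameterRange("cost_per_complication_lvc", 9101, 17947,
                       "per-complication cost estimates across four sources"),
    ]
    return {r.name: r for r in ranges}


def get_value(params: ModelParameters, field: str) -> float:
    """Read one parameter by its flat field path."""
    _check_field(field)
    if field.startswith(("hvc_", "lvc_")):
        rates = params.hvc_rates if field.startswith("hvc_") else params.lvc_rates
        return getattr(rates, field[4:])
    return getattr(params, field)


def with_value(params: ModelParameters, field: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one flat field replaced."""
    _check_field(field)
    if field.startswith(("hvc_", "lvc_")):
        which = field[:3] + "_rates"
        rates = dataclasses.replace(getattr(params, which), **{field[4:]: value})
        return dataclasses.replace(params, **{which: rates})
    return dataclasses.replace(params, **{field: value})


def _check_field(field: str) -> None:
    if field not in PARAM_FIELDS:
        raise KeyError(
            f"unknown parameter field {field!r}; expected one of {', '.join(PARAM_FIELDS)}"
        )


def iter_fields(params: ModelParameters) -> Iterator[tuple[str, float]]:
    """Yield ``(flat field path, value)`` pairs in canonical order."""
    for field in PARAM_FIELDS:
        yield field, get_value(params, field)


def from_mapping(mapping: Mapping[str, float]) -> ModelParameters:
    """Build a validated parameter set from a flat field-path mapping.

    Unknown and missing keys are both errors.
    """
    unknown = sorted(set(mapping) - set(PARAM_FIELDS))
    if unknown:
        raise KeyError(f"unknown parameter keys: {', '.join(unknown)}")
    missing = [f for f in PARAM_FIELDS if f not in mapping]
    if missing:
        raise KeyError(f"missing parameter keys: {', '.join(missing)}")
    params = default_parameters()
    for field in PARAM_FIELDS:
        value = float(mapping[field])
        # keep whole-dollar costs and counts exact integers
        if value.is_integer():
            value = int(value)
        params = with_value(params, field, value)
    return validate(params)


def validate(params: ModelParameters) -> ModelParameters:
    """Check every invariant; return ``params`` unchanged if all hold.

    Raises
    ------
    ParameterError
        Naming every violated field: proportions outside [0, 1],
        negative incidence or costs.
    """
    bad_fields: list[str] = []
    messages: list[str] = []
    for field, value in iter_fields(params):
        if field in _NONNEGATIVE_FIELDS:
            if not value >= 0:
                bad_fields.append(field)
                messages.append(f"{field} must be >= 0, got {value}")
        else:
            if not 0.0 <= value <= 1.0:
                bad_fields.append(field)
                messages.append(f"{field} must be in [0, 1], got {value}")
    if bad_fields:
        raise ParameterError(bad_fields, messages)
    return params
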