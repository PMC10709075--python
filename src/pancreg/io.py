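"""Config reading/writing and the comparison report table.

Config files are flat ``key: value`` text, one parameter per line, keys
exactly the flat field paths of :data:`~pancreg.parameters.PARAM_FIELDS`.
Proportions must be fractions — percent strings like ``46.6%`` are
rejected — and unknown or missing keys are errors, not warnings.

The report is the model's headline table: per-center and total
surgeries, deaths, complications and complication costs for the current
and future states, plus a differential footer.  Machine output is plain
integers; ``pretty=True`` formats dollars for reading.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .cohort import StateResult, compare_states
from .parameters import ModelParameters, from_mapping, iter_fields

REPORT_COLUMNS = (
    "state", "center_class", "surgeries", "deaths",
    "complications", "complication_costs_usd",
)

DEFAULT_CONFIG_RESOURCE = "defaults.cfg"


class ConfigError(ValueError):
    """Malformed config file (syntax, unknown/missing keys, bad values)."""


def read_config(path: str | Path) -> ModelParameters:
    """Parse and validate a flat ``key: value`` parameter file."""
    with open(path) as fh:
        return _parse_config(fh.read(), str(path))


def read_default_config() -> ModelParameters:
    """The packaged baseline config (identical to ``default_parameters()``)."""
    text = (resources.files("pancreg") / "data" / DEFAULT_CONFIG_RESOURCE).read_text()
    return _parse_config(text, DEFAULT_CONFIG_RESOURCE)


def _parse_config(text: str, origin: str) -> ModelParameters:
    mapping: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise ConfigError(f"{origin}:{lineno}: expected 'key: value', got {raw!r}")
        key, value = key.strip(), value.strip()
        try:
            mapping[key] = float(value)
        except ValueError:
            raise ConfigError(
                f"{origin}:{lineno}: {key}: {value!r} is not a number "
                "(proportions must be fractions, not percent strings)"
            ) from None
    try:
        return from_mapping(mapping)
    except KeyError as exc:
        raise ConfigError(f"{origin}: {exc.args[0]}") from None


def write_config(params: ModelParameters, path: str | Path) -> None:
    """Serialize parameters in the flat config dialect, canonical order."""
    with open(path, "w") as fh:
        for field, value in iter_fields(params):
            fh.write(f"{field}: {value!r}\n")


def _fmt(value: float, pretty: bool, currency: bool = False) -> str:
    whole = int(value) if float(value).is_integer() else value
    if pretty and currency:
        return f"${whole:,}"
    return str(whole)


def write_report(
    current: StateResult,
    future: StateResult,
    path: str | Path,
    pretty: bool = False,
) -> None:
    """Write the two-state comparison table as CSV.

    Layout: per-center rows, then a TOTAL row per state, then a
    ``differential`` footer (current minus future).  Deterministic:
    identical inputs give byte-identical files.
    """
    diff = compare_states(current, future)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for state in (current, future):
            for oc in state.outcomes:
                writer.writerow([
                    state.label, oc.center_class,
                    _fmt(oc.n_surgeries, pretty),
                    _fmt(oc.n_deaths, pretty),
                    _fmt(oc.n_complications, pretty),
                    _fmt(oc.complication_cost, pretty, currency=True),
                ])
            writer.writerow([
                state.label, "TOTAL",
                _fmt(state.total_surgeries, pretty),
                _fmt(state.total_deaths, pretty),
                _fmt(state.total_complications, pretty),
                _fmt(state.total_cost, pretty, currency=True),
            ])
        writer.writerow([
            "differential", "TOTAL",
            _fmt(current.total_surgeries - future.total_surgeries, pretty),
            _fmt(diff.delta_deaths, pretty),
            _fmt(diff.delta_complications, pretty),
            _fmt(diff.delta_cost, pretty, currency=True),
        ])


def validate_report(path: str | Path) -> None:
    """Re-parse an (unformatted) report and check its arithmetic.

    Verifies that each state's TOTAL row equals the column sums of its
    center rows and that the differential footer equals current totals
    minus future totals.  Raises ``ValueError`` on any mismatch.
    """
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    states: dict[str, dict[str, list[float]]] = {}
    totals: dict[str, list[float]] = {}
    differential: list[float] | None = None
    numeric = REPORT_COLUMNS[2:]
    for row in rows:
        values = [float(row[c]) for c in numeric]
        if row["state"] == "differential":
            differential = values
        elif row["center_class"] == "TOTAL":
            totals[row["state"]] = values
        else:
            states.setdefault(row["state"], {})[row["center_class"]] = values
    for label, centers in states.items():
        sums = [sum(vals) for vals in zip(*centers.values())]
        if sums != totals.get(label):
            raise ValueError(f"{path}: TOTAL row of {label!r} does not sum")
    if differential is not None:
        labels = [lbl for lbl in totals if lbl != "differential"]
        if len(labels) != 2:
            raise ValueError(f"{path}: expected two states, got {labels}")
        cur, fut = totals[labels[0]], totals[labels[1]]
        expected = [c - f for c, f in zip(cur, fut)]
        if differential != expected:
            raise ValueError(
                f"{path}: differential row {differential} != {expected}"
            )
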