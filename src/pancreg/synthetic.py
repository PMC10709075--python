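"""Seeded generation of plausible parameter sets within literature ranges.

The published evidence gives, for most inputs, a point estimate and a
low/high range across sources but no distribution.  This module turns
those ranges into reproducible parameter draws for sweeps, probabilistic
sensitivity analysis and property tests:

* ``uniform`` — uniform on [low, high]; the least-assumptive reading of
  a literature range (the default).
* ``beta`` / ``gamma`` — method-of-moments fits with the mean at the
  selected value and the range treated as an approximate central 95 %
  interval, then truncated to [low, high] by rejection so every draw
  respects its bounds.  Standard practice for proportions (beta) and
  costs (gamma) when only a point and a range are published.
* ``point`` — the selected value, repeated.

Seeding: each parameter draws from its own substream derived from the
root seed and the parameter's name, so adding a parameter to a spec does
not perturb the draws of the others.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .parameters import (
    PARAM_FIELDS,
    ModelParameters,
    default_parameters,
    get_value,
    parameter_ranges,
    validate,
    with_value,
)

DIST_KINDS = ("uniform", "beta", "gamma", "point")

# Treat the published range as an approximate central 95% interval when
# fitting beta/gamma moments: sd = (high - low) / (2 * 1.96).
_Z95_WIDTH = 2 * 1.959963984540054


@dataclass(frozen=True)
class Distribution:
    """Sampling distribution for one parameter."""

    kind: str
    low: float
    high: float
    center: float

    def __post_init__(self) -> None:
        if self.kind not in DIST_KINDS:
            raise ValueError(f"kind must be one of {DIST_KINDS}, got {self.kind!r}")
        if not self.low <= self.center <= self.high:
            raise ValueError(
                f"center {self.center} outside [{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class SamplingSpec:
    """Which parameters to sample, how, and with what seed."""

    distributions: Mapping[str, Distribution]
    seed: int
    n: int

    def __post_init__(self) -> None:
        unknown = sorted(set(self.distributions) - set(PARAM_FIELDS))
        if unknown:
            raise ValueError(f"unknown parameter fields: {', '.join(unknown)}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def default_sampling_spec(
    seed: int, n: int, kind: str = "uniform"
) -> SamplingSpec:
    """Spec over every literature range, centered on the baseline values.

    Degenerate ranges (single published value) become ``point``
    distributions regardless of ``kind``.  With ``kind="beta-gamma"``,
    proportions get beta and costs gamma distributions.
    """
    base = default_parameters()
    dists = {}
    for name, rng in parameter_ranges().items():
        center = get_value(base, name)
        if rng.is_degenerate:
            dist_kind = "point"
        elif kind == "uniform":
            dist_kind = "uniform"
        elif kind == "beta-gamma":
            dist_kind = "gamma" if name.startswith("cost_") else "beta"
        else:
            raise ValueError(f"kind must be 'uniform' or 'beta-gamma', got {kind!r}")
        dists[name] = Distribution(dist_kind, rng.low, rng.high, center)
    return SamplingSpec(distributions=dists, seed=seed, n=n)


def _substream(seed: int, name: str) -> np.random.Generator:
    # Per-parameter substream keyed on the parameter name, stable across
    # additions/removals of other parameters.
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _truncated(draw, low: float, high: float, n: int) -> np.ndarray:
    """Rejection-sample ``draw(k)`` into [low, high]."""
    out = np.empty(0)
    while out.size < n:
        batch = draw(max(n, 128))
        out = np.concatenate([out, batch[(batch >= low) & (batch <= high)]])
    return out[:n]


def _sample_one(dist: Distribution, rng: np.random.Generator, n: int) -> np.ndarray:
    if dist.kind == "point" or dist.low == dist.high:
        return np.full(n, dist.center, dtype=float)
    if dist.kind == "uniform":
        return rng.uniform(dist.low, dist.high, n)
    sd = (dist.high - dist.low) / _Z95_WIDTH
    m = dist.center
    if dist.kind == "beta":
        # Moment match on (0,1): concentration from mean/sd, floor at 2
        # to keep the density unimodal even for wide ranges.
        k = max(m * (1 - m) / sd**2 - 1, 2.0)
        a, b = m * k, (1 - m) * k
        return _truncated(lambda size: rng.beta(a, b, size), dist.low, dist.high, n)
    if dist.kind == "gamma":
        shape = (m / sd) ** 2
        scale = sd**2 / m
        return _truncated(
            lambda size: rng.gamma(shape, scale, size), dist.low, dist.high, n
        )
    raise AssertionError(dist.kind)


def sample_parameters(spec: SamplingSpec) -> list[ModelParameters]:
    """Draw ``spec.n`` validated parameter sets.

    Identical seeds give identical output sequences.  Parameters absent
    from the spec keep their baseline values.
    """
    columns: dict[str, np.ndarray] = {}
    for name in PARAM_FIELDS:  # canonical order, but streams are name-keyed
        if name in spec.distributions:
            rng = _substream(spec.seed, name)
            columns[name] = _sample_one(spec.distributions[name], rng, spec.n)
    base = default_parameters()
    sets = []
    for i in range(spec.n):
        params = base
        for name, values in columns.items():
            params = with_value(params, name, float(values[i]))
        sets.append(validate(params))
    return sets


def write_fixture(spec: SamplingSpec, path: str | Path) -> list[ModelParameters]:
    """Write sampled sets as CSV plus a sidecar recording the spec.

    The CSV has one row per parameter set and one column per flat field;
    floats are written with ``repr`` so a read-back is bit-exact.  The
    sidecar (``<path>.spec``, flat ``key: value``) holds the seed, n and
    per-parameter distributions — enough to regenerate the CSV
    byte-identically via :func:`read_sampling_spec` + ``write_fixture``.
    """
    path = Path(path)
    sets = sample_parameters(spec)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PARAM_FIELDS)
        for params in sets:
            writer.writerow([repr(get_value(params, f)) for f in PARAM_FIELDS])
    with open(path.with_name(path.name + ".spec"), "w") as fh:
        fh.write(f"seed: {spec.seed}\n")
        fh.write(f"n: {spec.n}\n")
        for name in PARAM_FIELDS:
            if name not in spec.distributions:
                continue
            d = spec.distributions[name]
            fh.write(f"{name}.kind: {d.kind}\n")
            fh.write(f"{name}.low: {d.low!r}\n")
            fh.write(f"{name}.high: {d.high!r}\n")
            fh.write(f"{name}.center: {d.center!r}\n")
    return sets


def read_fixture(path: str | Path) -> list[ModelParameters]:
    """Read parameter sets written by :func:`write_fixture`."""
    sets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            params = default_parameters()
            for name in PARAM_FIELDS:
                params = with_value(params, name, float(row[name]))
            sets.append(validate(params))
    return sets


def read_sampling_spec(path: str | Path) -> SamplingSpec:
    """Read a sidecar spec written by :func:`write_fixture`."""
    flat: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            flat[key.strip()] = value.strip()
    grouped: dict[str, dict[str, str]] = {}
    for key, value in flat.items():
        if key in ("seed", "n"):
            continue
        name, _, attr = key.rpartition(".")
        grouped.setdefault(name, {})[attr] = value
    dists = {
        name: Distribution(
            kind=attrs["kind"],
            low=float(attrs["low"]),
            high=float(attrs["high"]),
            center=float(attrs["center"]),
        )
        for name, attrs in grouped.items()
    }
    return SamplingSpec(distributions=dists, seed=int(flat["seed"]), n=int(flat["n"]))
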