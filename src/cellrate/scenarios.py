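"""Synthetic count timelines with known ground truth.

Generates observation series through the full forward model — exact
deterministic growth curve, then nested-Poisson sampling and counting
noise — from a known rate curve, so that inference can be scored
against the truth.  The three built-in scenarios mirror the canonical
demonstration set-up: a constant, an increasing and a decreasing rate
over an 8-day window, observed every other day through a two-stage
haemocytometer scheme (fractions 0.01 x 0.02) with 5% counting error,
in a culture seeded at ~9.5e4 cells with carrying capacity 3e6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .growth import CultureModel, RateCurve, solve_deterministic
from .io import CountSeries, write_counts
from .noise import CountingNoiseSpec, CountRecord, SamplingScheme, simulate_counts

__all__ = ["Scenario", "generate_scenario", "builtin_scenarios", "write_scenario"]

_DEFAULT_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0)
_DEFAULT_SCHEME = SamplingScheme((0.01, 0.02))
_DEFAULT_MODEL = CultureModel(carrying_capacity=3e6, initial_population=9.5e4)


@dataclass(frozen=True)
class Scenario:
    """One synthetic experiment: truth plus observation design."""

    label: str
    curve: RateCurve
    model: CultureModel = _DEFAULT_MODEL
    times: tuple[float, ...] = _DEFAULT_TIMES
    scheme: SamplingScheme = _DEFAULT_SCHEME
    noise: CountingNoiseSpec = field(default_factory=CountingNoiseSpec)
    seed: int = 0

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


def generate_scenario(scenario: Scenario) -> tuple[CountSeries, RateCurve]:
    """Simulate one observed series; returns (series, ground-truth curve).

    Deterministic under the scenario seed.  The truth curve is returned
    alongside so recovery tests never have to re-derive it.
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.asarray(scenario.times, dtype=float)
    sizes = solve_deterministic(scenario.model, scenario.curve, times, t_ref=times[0]).sizes
    counts = simulate_counts(sizes, scenario.scheme, scenario.noise, rng)
    records = tuple(CountRecord(scenario.label, float(t), int(c), scenario.scheme)
                    for t, c in zip(times, counts))
    return CountSeries(scenario.label, records), scenario.curve


def builtin_scenarios() -> dict[str, Scenario]:
    """The three demonstration scenarios over days 0-8.

    constant: r = 1.0 throughout; increasing: 0.2 -> 1.2; decreasing:
    1.2 -> 0.2 (all divisions/cell/day, inside the default prior range).

    The constant scenario uses the 1 mL / K = 3e6 set-up of the worked
    example.  The trending scenarios place the same inoculum in a larger
    culture (K = 3e7, e.g. a 10 mL flask at the same density ceiling):
    near carrying capacity the population carries almost no information
    about the rate, so a demonstration of a *changing* rate must keep
    the culture below saturation for the whole observation window.
    """
    t0, t1 = _DEFAULT_TIMES[0], _DEFAULT_TIMES[-1]
    big = CultureModel(carrying_capacity=3e7, initial_population=9.5e4)
    return {
        "constant": Scenario("constant", RateCurve((1.0,), t0, t1)),
        "increasing": Scenario("increasing", RateCurve((0.2, 1.2), t0, t1), model=big),
        "decreasing": Scenario("decreasing", RateCurve((1.2, 0.2), t0, t1), model=big),
    }


def write_scenario(scenario: Scenario, csv_path, truth_path=None) -> CountSeries:
    """Write a scenario's counts as a data CSV plus a JSON truth sidecar."""
    series, curve = generate_scenario(scenario)
    write_counts([series], csv_path)
    if truth_path is None:
        truth_path = str(csv_path) + ".truth.json"
    truth = {
        "label": scenario.label,
        "control_values": list(curve.control_values),
        "t_start": curve.t_start,
        "t_end": curve.t_end,
        "carrying_capacity": scenario.model.carrying_capacity,
        "initial_population": scenario.model.initial_population,
        "seed": scenario.seed,
    }
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return series
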