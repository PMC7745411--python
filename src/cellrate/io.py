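"""Input handling: the count table and the run configuration.

Counts arrive as a CSV with columns ``name, time, count`` plus one or
more sampling-fraction columns (``sample1, sample2, ...``); the config
is a TOML file whose only required key is the carrying capacity.
Column names are case-insensitive; decimals always use ".".
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import ABCConfig, PriorSpec
from .noise import CountingNoiseSpec, CountRecord, SamplingScheme

__all__ = [
    "CountSeries",
    "SeriesGroup",
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_config",
    "group_series",
]


@dataclass(frozen=True)
class CountSeries:
    """A named, time-ordered set of count records."""

    name: str
    records: tuple[CountRecord, ...]
    group: str | None = None

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValueError("a count series needs at least one record")
        if any(r.name != self.name for r in records):
            raise ValueError("all records in a series must share the series name")
        times = [r.time for r in records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"series {self.name!r}: times must be strictly increasing")
        object.__setattr__(self, "records", records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.records], dtype=np.int64)

    @property
    def schemes(self) -> list[SamplingScheme]:
        return [r.scheme for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SeriesGroup:
    """Series fitted jointly: one shared rate curve, one N0 per series."""

    label: str
    members: tuple[CountSeries, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one series")
        object.__setattr__(self, "members", tuple(self.members))


@dataclass(frozen=True)
class RunConfig:
    """Everything a fit needs besides the data."""

    carrying_capacity: float
    prior: PriorSpec
    abc: ABCConfig
    noise: CountingNoiseSpec
    grouping: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.carrying_capacity > 0:
            raise ValueError("carrying capacity must be > 0")


def read_counts(path) -> list[CountSeries]:
    """Parse and validate a count CSV into per-name series.

    Sampling-fraction columns are any ``sample<i>`` columns, applied in
    index order; a file without them gets a single fraction of 1.0.
    Rows may appear in any order; each series is sorted by time.
    Validation is strict: non-numeric fields, negative or non-integer
    counts, and duplicate times within a series raise with the offending
    CSV row number.
    """
    frame = pd.read_csv(path, skipinitialspace=True)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    for col in ("name", "time", "count"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r}")
    sample_cols = sorted((c for c in frame.columns if c.startswith("sample") and c[6:].isdigit()),
                         key=lambda c: int(c[6:]))
    if len(frame) == 0:
        raise ValueError("no records in count file")

    def row_err(idx, msg):
        # +2: header line plus 1-based indexing
        return ValueError(f"row {idx + 2}: {msg}")

    records: dict[str, list[CountRecord]] = {}
    for idx, row in frame.iterrows():
        name = str(row["name"]).strip()
        try:
            time = float(row["time"])
            count = float(row["count"])
        except (TypeError, ValueError):
            raise row_err(idx, "non-numeric time or count") from None
        if not np.isfinite(time) or not np.isfinite(count):
            raise row_err(idx, "non-finite time or count")
        if count < 0 or count != int(count):
            raise row_err(idx, f"count must be a non-negative integer, got {row['count']!r}")
        if sample_cols:
            try:
                fractions = tuple(float(row[c]) for c in sample_cols)
            except (TypeError, ValueError):
                raise row_err(idx, "non-numeric sampling fraction") from None
        else:
            fractions = (1.0,)
        try:
            scheme = SamplingScheme(fractions)
        except ValueError as exc:
            raise row_err(idx, str(exc)) from None
        records.setdefault(name, []).append(
            CountRecord(name, time, int(count), scheme))

    out = []
    for name, recs in records.items():
        recs.sort(key=lambda r: r.time)
        times = [r.time for r in recs]
        if len(set(times)) != len(times):
            raise ValueError(f"series {name!r}: duplicate observation times {times}")
        out.append(CountSeries(name, tuple(recs)))
    return out


def write_counts(series_list, path) -> None:
    """Write series back to the count-CSV schema (round-trips read_counts)."""
    series_list = [series_list] if isinstance(series_list, CountSeries) else list(series_list)
    n_fr = max(len(r.scheme.fractions) for s in series_list for r in s.records)
    rows = []
    for s in series_list:
        for r in s.records:
            fr = r.scheme.fractions + (1.0,) * (n_fr - len(r.scheme.fractions))
            rows.append({"name": r.name, "time": r.time, "count": r.count,
                         **{f"sample{i + 1}": f for i, f in enumerate(fr)}})
    pd.DataFrame(rows).to_csv(path, index=False)


_KNOWN_KEYS = {
    "carrying_capacity", "rate_min", "rate_max", "control_points", "simulator",
    "p_wrong", "counting_noise", "n_particles", "n_generations",
    "epsilon_quantile", "distance", "n_parallel", "seed", "groups",
}


def read_config(path) -> RunConfig:
    """Parse the TOML run configuration.

    Only ``carrying_capacity`` is required.  Defaults: rate prior
    (0.01, 3.0) divisions/cell/day; control-point counts {1, 2, 3};
    deterministic simulator; counting noise normal_binomial with
    p_wrong = 0.05; 4 parallel workers.  Unknown keys warn, a missing
    carrying capacity errors.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    for key in raw:
        if key not in _KNOWN_KEYS:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
    if "carrying_capacity" not in raw:
        raise ValueError("config must set the carrying capacity (key 'carrying_capacity')")
    prior = PriorSpec(
        rate_min=float(raw.get("rate_min", 0.01)),
        rate_max=float(raw.get("rate_max", 3.0)),
        control_point_counts=tuple(int(m) for m in raw.get("control_points", (1, 2, 3))),
    )
    abc = ABCConfig(
        n_particles=int(raw.get("n_particles", 200)),
        n_generations=int(raw.get("n_generations", 6)),
        epsilon_quantile=float(raw.get("epsilon_quantile", 0.5)),
        distance_kind=str(raw.get("distance", "sqrt_euclid")),
        simulator=str(raw.get("simulator", "deterministic")),
        n_parallel=int(raw.get("n_parallel", 4)),
        seed=int(raw.get("seed", 0)),
    )
    noise = CountingNoiseSpec(
        kind=str(raw.get("counting_noise", "normal_binomial")),
        p_wrong=float(raw.get("p_wrong", 0.05)),
    )
    grouping = {str(g): [str(n) for n in names]
                for g, names in raw.get("groups", {}).items()}
    return RunConfig(float(raw["carrying_capacity"]), prior, abc, noise, grouping)


def group_series(series_list, grouping: dict[str, list[str]] | None = None) -> list[SeriesGroup]:
    """Partition series into joint-fit groups.

    ``grouping`` maps a group label to series names; series not named in
    any group become singleton groups labelled by their own name.  A
    series in two groups, or a grouping naming an unknown series, is an
    error.
    """
    grouping = grouping or {}
    by_name = {s.name: s for s in series_list}
    seen: dict[str, str] = {}
    groups = []
    for label, names in grouping.items():
        for n in names:
            if n not in by_name:
                raise ValueError(f"grouping {label!r} references unknown series {n!r}")
            if n in seen:
                raise ValueError(f"series {n!r} appears in groups {seen[n]!r} and {label!r}")
            seen[n] = label
        groups.append(SeriesGroup(label, tuple(by_name[n] for n in names)))
    for s in series_list:
        if s.name not in seen:
            groups.append(SeriesGroup(s.name, (s,)))
    return groups
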