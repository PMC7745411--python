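"""Observation model for cell counting.

A measured count is a heavily subsampled view of the culture: a small
volume is drawn (often diluted with trypan blue for viability staining)
and only part of it is actually counted in the haemocytometer chamber or
by an automated counter.  For well-dispersed cells each sampling stage
yields a Poisson-distributed number of cells, so repeated subsampling is
a nested chain of Poisson draws.  On top of that sits counting noise —
mistakes by the operator or instrument — modelled as a normal
approximation of a binomial miscount (each cell wrong with probability
``p_wrong``).

The dye dilution itself does not change the number of cells in the
sample; users fold it into the sampling fractions (see
:func:`haemocytometer_fractions`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingScheme",
    "CountingNoiseSpec",
    "CountRecord",
    "haemocytometer_fractions",
    "simulate_observation",
    "simulate_counts",
    "expected_count",
    "point_estimate_population",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Ordered chain of sampling fractions, each in (0, 1].

    E.g. ``(0.01, 0.02)``: 10 uL drawn from 1 mL of culture, then 0.2 uL
    (undiluted equivalent) of that sample counted.
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if len(fr) == 0:
            raise ValueError("sampling scheme needs at least one fraction")
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError(f"sampling fractions must be in (0, 1], got {fr}")
        object.__setattr__(self, "fractions", fr)

    @property
    def overall_fraction(self) -> float:
        """Product of all stage fractions (expected counted share)."""
        return float(np.prod(self.fractions))


@dataclass(frozen=True)
class CountingNoiseSpec:
    """Post-sampling counting-noise filter.

    kind="normal_binomial": each counted cell is wrong with probability
    ``p_wrong``; the miscount is approximated by a zero-mean normal with
    variance c * p_wrong * (1 - p_wrong), rounded and floored at 0.
    kind="none": the raw sampled count is reported.

    Noise is a pluggable post-sampling transform so other instruments'
    error models can slot in; only these two kinds ship.
    """

    kind: str = "normal_binomial"
    p_wrong: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("none", "normal_binomial"):
            raise ValueError(f"unknown counting-noise kind {self.kind!r}")
        if not (0.0 <= self.p_wrong < 1.0):
            raise ValueError("p_wrong must be in [0, 1)")


@dataclass(frozen=True)
class CountRecord:
    """One timestamped observed count with its sampling scheme."""

    name: str
    time: float
    count: int
    scheme: SamplingScheme

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValueError("time must be finite")
        if self.count < 0:
            raise ValueError("count must be >= 0")


def haemocytometer_fractions(culture_volume: float, sample_volume: float,
                             counted_volume: float, dilution_factor: float = 1.0,
                             ) -> tuple[float, float]:
    """Sampling fractions for a classic two-stage haemocytometer count.

    Stage 1: ``sample_volume`` drawn from ``culture_volume`` of culture
    (fraction sample_volume / culture_volume).  Stage 2: the sample is
    diluted by ``dilution_factor`` (e.g. 2 for a 1:1 mix with trypan
    blue) and ``counted_volume`` of the *diluted* mix is counted, i.e. a
    fraction counted_volume / (sample_volume * dilution_factor) of the
    sampled cells.  Dilution does not change cell numbers, so it only
    rescales the second fraction.

    All volumes in the same unit (e.g. uL).

    >>> haemocytometer_fractions(1000, 10, 0.4, dilution_factor=2)
    (0.01, 0.02)
    """
    if min(culture_volume, sample_volume, counted_volume) <= 0 or dilution_factor < 1:
        raise ValueError("volumes must be positive and dilution_factor >= 1")
    f1 = sample_volume / culture_volume
    f2 = counted_volume / (sample_volume * dilution_factor)
    for f in (f1, f2):
        if not 0 < f <= 1:
            raise ValueError("derived fraction outside (0, 1]; check volumes")
    return f1, f2


def simulate_counts(n_true, scheme: SamplingScheme, noise: CountingNoiseSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Vectorized forward observation model for an array of true sizes.

    Nested Poisson chain: c0 = N_true; c_i ~ Poisson(c_{i-1} * f_i).
    Then the counting-noise filter (zero-mean normal with binomial
    variance, rounded, floored at 0).
    """
    c = np.asarray(n_true, dtype=float)
    if np.any(c < 0):
        raise ValueError("true population sizes must be >= 0")
    c = np.atleast_1d(c)
    for f in scheme.fractions:
        c = rng.poisson(c * f).astype(float)
    if noise.kind == "normal_binomial" and noise.p_wrong > 0:
        sd = np.sqrt(c * noise.p_wrong * (1.0 - noise.p_wrong))
        c = np.maximum(0.0, np.rint(c + rng.normal(0.0, 1.0, size=c.shape) * sd))
    return c.astype(np.int64)


def simulate_observation(n_true: float, scheme: SamplingScheme,
                         noise: CountingNoiseSpec, rng: np.random.Generator) -> int:
    """Simulate a single observed count from a true population size."""
    return int(simulate_counts([n_true], scheme, noise, rng)[0])


def expected_count(n_true: float, scheme: SamplingScheme) -> float:
    """Mean of the observation model: N_true times the fraction product.

    Counting noise has zero mean and does not enter.
    """
    if n_true < 0:
        raise ValueError("true population size must be >= 0")
    return float(n_true) * scheme.overall_fraction


def point_estimate_population(record: CountRecord) -> float:
    """Invert the mean observation model: count / product(fractions)."""
    p = record.scheme.overall_fraction
    if p <= 0:
        raise ValueError("sampling-fraction product must be > 0")
    return record.count / p
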