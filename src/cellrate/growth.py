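"""Time-varying logistic growth.

The population model is logistic growth with a time-dependent per-capita
rate r(t), represented as a piecewise-linear curve over evenly spaced
control points:

    dN/dt = r(t) N - r(t) N^2 / K

With the cumulative rate R(t) = int_0^t r(xi) dxi, this Bernoulli equation
has the exact solution

    N(t) = K / (1 + (K/N0 - 1) * exp(-(R(t) - R(t_ref))))

anchored at N(t_ref) = N0.  Because r is piecewise linear, R is piecewise
quadratic and available in closed form, so the deterministic solver is
exact (no numerical integration).  Units throughout: time in days, rates
in divisions/cell/day, populations in cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateCurve",
    "CultureModel",
    "Trajectory",
    "solve_deterministic",
    "solve_deterministic_ode",
    "inhibited_growth_rate",
]


@dataclass(frozen=True)
class RateCurve:
    """Piecewise-linear growth rate r(t) over evenly spaced control points.

    Parameters
    ----------
    control_values
        Per-capita rates [divisions/cell/day] at the control points.  A
        single value means a constant rate.  Negative values are allowed
        (the deterministic solver accepts them; the stochastic simulator
        does not).
    t_start, t_end
        Time bounds [days] over which the control points are evenly
        spaced (first point at ``t_start``, last at ``t_end``).  Outside
        this window the rate is clamped to the nearest endpoint value.
    """

    control_values: tuple[float, ...]
    t_start: float = 0.0
    t_end: float = 1.0

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in np.atleast_1d(np.asarray(self.control_values, dtype=float)))
        if len(values) < 1:
            raise ValueError("RateCurve needs at least one control value")
        if not np.all(np.isfinite(values)):
            raise ValueError("control values must be finite")
        object.__setattr__(self, "control_values", values)
        if len(values) >= 2 and not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end for curves with >= 2 control points")

    @property
    def n_control_points(self) -> int:
        return len(self.control_values)

    @property
    def knots(self) -> np.ndarray:
        """Control-point times [days]."""
        if self.n_control_points == 1:
            return np.asarray([self.t_start])
        return np.linspace(self.t_start, self.t_end, self.n_control_points)

    def rate_at(self, t):
        """Evaluate r(t); clamps to the endpoint values outside the window."""
        t = np.asarray(t, dtype=float)
        v = np.asarray(self.control_values)
        if self.n_control_points == 1:
            out = np.full_like(t, v[0], dtype=float)
        else:
            out = np.interp(t, self.knots, v)
        return out if out.ndim else float(out)

    def cumulative_rate(self, t):
        """Signed integral R(t) = int_0^t r(xi) dxi, exact.

        The antiderivative of a piecewise-linear rate is piecewise
        quadratic; outside the control window the (clamped) rate is
        constant, so the antiderivative is linear there.  Additive:
        R(t2) - R(t1) is the integral over [t1, t2].
        """
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = self._antiderivative(t) - self._antiderivative(np.zeros(1))[0]
        return float(out[0]) if scalar else out

    def _antiderivative(self, t: np.ndarray) -> np.ndarray:
        """Antiderivative of r with an arbitrary additive constant."""
        k = self.knots
        v = np.asarray(self.control_values)
        if self.n_control_points == 1:
            return v[0] * t
        # Cumulative exact integral at the knots (trapezoid is exact here).
        knot_cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[:-1] + v[1:]) * np.diff(k))])
        seg = np.clip(np.searchsorted(k, t, side="right") - 1, 0, len(k) - 2)
        a, b = k[seg], k[seg + 1]
        slope = (v[seg + 1] - v[seg]) / (b - a)
        tau = t - a
        inside = knot_cum[seg] + v[seg] * tau + 0.5 * slope * tau**2
        below = v[0] * (t - k[0])
        above = knot_cum[-1] + v[-1] * (t - k[-1])
        return np.where(t < k[0], below, np.where(t > k[-1], above, inside))

    def shifted(self, dt: float) -> "RateCurve":
        """The same curve translated in time by ``dt`` days."""
        return RateCurve(self.control_values, self.t_start + dt, self.t_end + dt)

    def clamped_nonnegative(self) -> "RateCurve":
        """Copy with negative control values clamped to 0 (stochastic use)."""
        return RateCurve(tuple(max(0.0, v) for v in self.control_values), self.t_start, self.t_end)


@dataclass(frozen=True)
class CultureModel:
    """Fixed culture parameters: carrying capacity K and initial size N0.

    ``initial_population > carrying_capacity`` is allowed (overgrown
    cultures shrink back toward K under a positive rate).
    """

    carrying_capacity: float
    initial_population: float

    def __post_init__(self) -> None:
        if not self.carrying_capacity > 0:
            raise ValueError("carrying capacity must be > 0")
        if self.initial_population < 0:
            raise ValueError("initial population must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Population size over time: strictly increasing times, sizes >= 0."""

    times: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        sizes = np.asarray(self.sizes)
        if times.shape != sizes.shape or times.ndim != 1:
            raise ValueError("times and sizes must be equal-length 1-d arrays")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(np.asarray(sizes, dtype=float) < 0):
            raise ValueError("population sizes must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sizes", sizes)

    def __len__(self) -> int:
        return len(self.times)


def solve_deterministic(model: CultureModel, curve: RateCurve, times, t_ref: float = 0.0) -> Trajectory:
    """Exact solution of the time-varying logistic equation.

    Evaluates N(t) = K / (1 + (K/N0 - 1) exp(-(R(t) - R(t_ref)))) at the
    requested times, with N(t_ref) = N0.  Exact for any piecewise-linear
    rate, including negative rates.  N0 = 0 stays 0 and N0 = K stays K for
    every curve.  The pathological case N0 > K with a negative rate blows
    up in finite time; past the blow-up the solution is reported as inf.

    Parameters
    ----------
    times
        Strictly increasing observation times [days].
    t_ref
        Time at which the population equals ``model.initial_population``
        (default 0, the reference origin of the series).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    n0 = model.initial_population
    k = model.carrying_capacity
    if n0 == 0:
        return Trajectory(times, np.zeros_like(times))
    coef = k / n0 - 1.0
    if coef == 0.0:
        return Trajectory(times, np.full_like(times, k))
    big_r = curve.cumulative_rate(times) - curve.cumulative_rate(t_ref)
    with np.errstate(over="ignore"):
        x = coef * np.exp(-big_r)
    denom = 1.0 + x
    sizes = np.where(denom > 0, k / np.where(denom > 0, denom, 1.0), np.inf)
    return Trajectory(times, sizes)


def solve_deterministic_ode(model: CultureModel, curve: RateCurve, times, t_ref: float = 0.0,
                            rtol: float = 1e-9, atol: float = 1e-6) -> Trajectory:
    """Cross-check solver: adaptive ODE integration of dN/dt = r(t)N(1 - N/K).

    Exists to verify the closed-form path; the closed form is the primary
    solver.  Integrates forward (and backward if needed) from ``t_ref``.
    """
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    k = model.carrying_capacity

    def rhs(t, y):
        return curve.rate_at(t) * y * (1.0 - y / k)

    sizes = np.empty_like(times)
    for direction in (-1, 1):
        mask = (times < t_ref) if direction < 0 else (times >= t_ref)
        if not np.any(mask):
            continue
        tt = times[mask]
        t_span = (t_ref, tt[0]) if direction < 0 else (t_ref, tt[-1])
        t_eval = tt[::-1] if direction < 0 else tt
        if t_span[0] == t_span[1]:
            sizes[mask] = model.initial_population
            continue
        sol = solve_ivp(rhs, t_span, [model.initial_population], t_eval=t_eval,
                        rtol=rtol, atol=atol, method="LSODA")
        sizes[mask] = sol.y[0][::-1] if direction < 0 else sol.y[0]
    return Trajectory(times, np.maximum(sizes, 0.0))


def inhibited_growth_rate(uninhibited_rate: float, concentration: float, ic50: float,
                          hill: float = 1.0) -> float:
    """Expected growth rate under an inhibitor at a given concentration.

    Standard Hill dose-response: r = r0 / (1 + (c / IC50)^h).  At
    c = IC50 this is half the uninhibited rate by definition of IC50.
    Used to sanity-check observed rates against known inhibitor potency
    (e.g. Bcr-Abl1 inhibition of CML lines).
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return uninhibited_rate / (1.0 + (concentration / ic50) ** hill)
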