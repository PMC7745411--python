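"""Posterior summaries and report output.

The headline summary is the highest posterior density interval (HPDI):
the smallest continuous interval containing a given fraction of the
posterior samples (default mass 0.89).  Fit tables are plain CSV; the
figure combines the population panel (observed point estimates, median
curve, HPDI band) with connected raincloud plots of the rate posterior
(kernel density + box-plot + raw draws).  All numbers behind the figure
panels are computed by plain functions so they can be checked without
rendering anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_HPDI_MASS = 0.89

__all__ = [
    "DEFAULT_HPDI_MASS",
    "HPDInterval",
    "hpdi",
    "weighted_quantile",
    "write_fit_table",
    "report_panel_data",
    "plot_report",
]


@dataclass(frozen=True)
class HPDInterval:
    low: float
    high: float
    mass: float = DEFAULT_HPDI_MASS

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if not (0.0 < self.mass <= 1.0):
            raise ValueError("mass must be in (0, 1]")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    def overlaps(self, other: "HPDInterval") -> bool:
        return self.low <= other.high and other.low <= self.high


def hpdi(samples, weights=None, mass: float = DEFAULT_HPDI_MASS) -> HPDInterval:
    """Smallest contiguous interval holding at least ``mass`` of the weight.

    Sorts the samples and slides a window until the cumulative contained
    weight reaches ``mass``; among minimal-width windows the one with the
    lowest left endpoint wins.  With equal weights this is the minimal
    window over sorted samples covering ceil(mass * n) of them.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("hpdi needs at least one sample")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative and match samples")
        w = w / w.sum()
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    # contained weight of window [i, j] is cw[j+1] - cw[i]
    tol = 1e-12
    best_lo, best_hi, best_width = x[0], x[-1], np.inf
    j = 0
    for i in range(x.size):
        if j < i:
            j = i
        while j < x.size and cw[j + 1] - cw[i] < mass - tol:
            j += 1
        if j == x.size:
            break
        width = x[j] - x[i]
        if width < best_width - tol:
            best_lo, best_hi, best_width = x[i], x[j], width
    return HPDInterval(float(best_lo), float(best_hi), mass)


def weighted_quantile(samples, q, weights=None) -> np.ndarray:
    """Quantiles of a weighted sample (inverse of the weighted ECDF)."""
    x = np.asarray(samples, dtype=float).ravel()
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if weights is None:
        w = np.full(x.size, 1.0 / x.size)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        w = w / w.sum()
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    idx = np.searchsorted(cw, q, side="left")
    return x[np.clip(idx, 0, x.size - 1)]


def write_fit_table(post, path) -> pd.DataFrame:
    """Write the inferred-rate summary table as CSV; returns the frame.

    One row per (group, model, parameter): posterior mean, median, HPDI
    bounds and model probability.  Parameters are the rate control
    points (with their time on the curve) and the per-series initial
    populations (time set to the series start).
    """
    rows = []
    for m in sorted(post.models):
        mp = post.models[m]
        if mp.params.shape[0] == 0:
            continue
        prob = post.model_probabilities[m]
        for col, pname in enumerate(mp.param_names):
            vals = mp.params[:, col]
            band = hpdi(vals, mp.weights, DEFAULT_HPDI_MASS)
            rows.append({
                "group": post.group,
                "n_control_points": m,
                "model_probability": prob,
                "parameter": pname,
                "time": mp.param_times[col],
                "mean": float(np.average(vals, weights=mp.weights)),
                "median": float(weighted_quantile(vals, 0.5, mp.weights)[0]),
                "hpdi_low": band.low,
                "hpdi_high": band.high,
                "hpdi_mass": DEFAULT_HPDI_MASS,
            })
    frame = pd.DataFrame(rows, columns=[
        "group", "n_control_points", "model_probability", "parameter", "time",
        "mean", "median", "hpdi_low", "hpdi_high", "hpdi_mass"])
    frame.to_csv(path, index=False)
    return frame


def report_panel_data(series_list, post, mass: float = DEFAULT_HPDI_MASS,
                      n_grid: int = 60, n_kde: int = 128) -> dict:
    """All numeric series behind the report figure.

    Returns a dict with the population panel (observed point estimates
    per series, posterior-median curve and HPDI band), the rate panel
    (median and HPDI band of r(t) over a time grid), and per-control-
    point raincloud data (weighted KDE grid, box-plot quartiles, raw
    draws) for the highest-probability model.
    """
    from scipy.stats import gaussian_kde

    from .inference import posterior_population_band, posterior_rate_band
    from .noise import point_estimate_population

    grid = np.linspace(post.t_start, post.t_end, n_grid)
    rate_band = posterior_rate_band(post, grid, mass)
    rate_median = rate_band["median"]

    population = {}
    for s in series_list:
        pop_band = posterior_population_band(post, grid, mass, series=s.name)
        population[s.name] = {
            "obs_times": np.array([r.time for r in s.records]),
            "obs_estimates": np.array([point_estimate_population(r) for r in s.records]),
            "band_low": pop_band["low"],
            "band_high": pop_band["high"],
            "median": pop_band["median"],
        }

    best = max(post.model_probabilities, key=lambda m: post.model_probabilities[m])
    mp = post.models[best]
    rainclouds = []
    rate_cols = [i for i, n in enumerate(mp.param_names) if n.startswith("r")]
    for col in rate_cols:
        draws = mp.params[:, col]
        q1, q2, q3 = weighted_quantile(draws, [0.25, 0.5, 0.75], mp.weights)
        lo, hi = draws.min(), draws.max()
        pad = 0.05 * max(hi - lo, 1e-9)
        xs = np.linspace(lo - pad, hi + pad, n_kde)
        if np.ptp(draws) > 0:
            dens = gaussian_kde(draws, weights=mp.weights)(xs)
        else:
            dens = np.zeros_like(xs)
        rainclouds.append({
            "parameter": mp.param_names[col],
            "time": mp.param_times[col],
            "draws": draws,
            "weights": mp.weights,
            "kde_x": xs,
            "kde_density": dens,
            "quartiles": (float(q1), float(q2), float(q3)),
        })

    return {
        "times": grid,
        "population": population,
        "rate": {"median": rate_median, "band_low": rate_band["low"],
                 "band_high": rate_band["high"]},
        "best_model": best,
        "rainclouds": rainclouds,
        "mass": mass,
    }


def plot_report(series_list, post, path, mass: float = DEFAULT_HPDI_MASS,
                truth_curve=None) -> None:
    """Render the two-panel report figure (format chosen by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panel = report_panel_data(series_list, post, mass)
    grid = panel["times"]
    fig, (ax_pop, ax_rate) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)

    for name, p in panel["population"].items():
        ax_pop.fill_between(grid, p["band_low"], p["band_high"], color="0.8",
                            label=f"{int(round(mass * 100))}% HPDI" if name == next(iter(panel["population"])) else None)
        ax_pop.plot(grid, p["median"], color="0.2", lw=1.5)
        ax_pop.plot(p["obs_times"], p["obs_estimates"], "ko", ms=5, label=None)
    ax_pop.set_ylabel("population size [cells]")
    ax_pop.set_title(f"group {post.group!r} "
                     f"(best model: {panel['best_model']} control points)")

    ax_rate.fill_between(grid, panel["rate"]["band_low"], panel["rate"]["band_high"],
                         color="0.85")
    ax_rate.plot(grid, panel["rate"]["median"], color="k", lw=1.5, label="posterior median")
    ax_rate.plot(grid, panel["rate"]["band_low"], "k--", lw=0.8)
    ax_rate.plot(grid, panel["rate"]["band_high"], "k--", lw=0.8)
    if truth_curve is not None:
        ax_rate.plot(grid, truth_curve.rate_at(grid), "r-", lw=1.2, label="truth")

    span = max(post.t_end - post.t_start, 1.0)
    for rc in panel["rainclouds"]:
        x0 = rc["time"]
        draws, w = rc["draws"], rc["weights"]
        if rc["kde_density"].max() > 0:
            half_width = 0.08 * span
            offs = rc["kde_density"] / rc["kde_density"].max() * half_width
            ax_rate.fill_betweenx(rc["kde_x"], x0, x0 + offs, color="0.5", alpha=0.5)
        q1, q2, q3 = rc["quartiles"]
        ax_rate.plot([x0, x0], [q1, q3], color="k", lw=3, solid_capstyle="butt")
        ax_rate.plot(x0, q2, "w.", ms=4, zorder=5)
        jitter = (np.arange(len(draws)) % 7 - 3) / 3 * 0.02 * span
        ax_rate.plot(x0 - 0.04 * span + jitter, draws, ".", color="0.3", ms=2, alpha=0.3)

    ax_rate.set_xlabel("time [days]")
    ax_rate.set_ylabel("growth rate [divisions/cell/day]")
    ax_rate.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
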