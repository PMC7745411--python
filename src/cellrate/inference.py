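"""Likelihood-free inversion of the growth model by ABC-SMC.

The forward model (growth curve -> nested-Poisson sampling -> counting
noise) has no tractable likelihood, so the rate curve is inferred by
approximate Bayesian computation with sequential Monte Carlo: a particle
population is filtered through generations with a shrinking acceptance
threshold (the epsilon schedule is a quantile of the previous
generation's accepted distances), particles are perturbed with an
adaptive component-wise Gaussian kernel and reweighted with the standard
SMC importance weight.  When several control-point counts are requested
they compete as models under a uniform model prior, and the posterior
reports per-model probability mass alongside per-model parameter
samples.

Priors are uniform: the rate control points over a user-defined range
(default 0.01 to 3.0 divisions/cell/day), and each series' latent
initial population over 0.2x to 5x the point estimate from its first
count.  The default distance is Euclidean between square-root
transformed counts, which approximately stabilises the Poisson sampling
variance; plain Euclidean is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .branching import BranchingConfig, sample_trajectory, simulate_branching
from .growth import CultureModel, RateCurve, solve_deterministic
from .noise import CountingNoiseSpec, point_estimate_population, simulate_counts
from .report import DEFAULT_HPDI_MASS, hpdi, weighted_quantile

__all__ = [
    "PriorSpec",
    "ABCConfig",
    "ModelPosterior",
    "Posterior",
    "distance",
    "run_abc_smc",
    "posterior_rate_band",
    "posterior_population_band",
]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform priors for the rate control points and the latent N0."""

    rate_min: float = 0.01
    rate_max: float = 3.0
    control_point_counts: tuple[int, ...] = (1, 2, 3)
    n0_lo_factor: float = 0.2
    n0_hi_factor: float = 5.0

    def __post_init__(self) -> None:
        if not self.rate_min < self.rate_max:
            raise ValueError("rate_min must be < rate_max")
        counts = tuple(sorted(set(int(m) for m in self.control_point_counts)))
        if not counts or any(m < 1 for m in counts):
            raise ValueError("control_point_counts must be a non-empty set of ints >= 1")
        object.__setattr__(self, "control_point_counts", counts)
        if not 0 < self.n0_lo_factor <= self.n0_hi_factor:
            raise ValueError("need 0 < n0_lo_factor <= n0_hi_factor")


@dataclass(frozen=True)
class ABCConfig:
    """SMC tuning knobs.

    ``n_generations`` counts all generations including the initial
    prior-sampling one; ``epsilon_quantile`` sets the next threshold as
    that quantile of the current accepted distances.  ``n_parallel`` is
    accepted as a worker-count hint; execution is sequential and results
    do not depend on it.
    """

    n_particles: int = 200
    n_generations: int = 6
    epsilon_quantile: float = 0.5
    distance_kind: str = "sqrt_euclid"
    simulator: str = "deterministic"
    n_parallel: int = 4
    seed: int = 0
    max_sims_per_generation: int = 0  # 0 -> 200 * n_particles

    def __post_init__(self) -> None:
        if self.n_particles < 10:
            raise ValueError("n_particles must be >= 10")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 < self.epsilon_quantile < 1.0:
            raise ValueError("epsilon_quantile must be in (0, 1)")
        if self.distance_kind not in ("sqrt_euclid", "euclid"):
            raise ValueError(f"unknown distance {self.distance_kind!r}")
        if self.simulator not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown simulator {self.simulator!r}")
        if self.n_parallel < 1:
            raise ValueError("n_parallel must be >= 1")

    @property
    def sims_cap(self) -> int:
        return self.max_sims_per_generation or 200 * self.n_particles


@dataclass(frozen=True)
class ModelPosterior:
    """Weighted posterior samples for one control-point count."""

    n_control_points: int
    params: np.ndarray          # (n_samples, n_series + n_control_points)
    weights: np.ndarray         # normalized within the model
    param_names: tuple[str, ...]
    param_times: tuple[float, ...]


@dataclass(frozen=True)
class Posterior:
    """Joint ABC-SMC output for one fit group."""

    group: str
    models: dict[int, ModelPosterior]
    model_probabilities: dict[int, float]
    epsilons: tuple[float, ...]
    t_start: float
    t_end: float
    carrying_capacity: float
    series_names: tuple[str, ...]
    series_t0: dict[str, float]

    @property
    def n_series(self) -> int:
        return len(self.series_names)

    def rate_curve_for(self, n_control_points: int, params: np.ndarray) -> RateCurve:
        """Rate curve of one posterior draw (strips the N0 components)."""
        values = tuple(params[self.n_series:])
        return RateCurve(values, self.t_start, self.t_end)

    def pooled_rate_samples(self, times):
        """(weights, r(t) draw matrix) pooled over models by model mass."""
        times = np.asarray(times, dtype=float)
        wts, rows = [], []
        for m in sorted(self.models):
            mp = self.models[m]
            prob = self.model_probabilities[m]
            if prob <= 0 or mp.params.shape[0] == 0:
                continue
            for p, w in zip(mp.params, mp.weights):
                rows.append(np.atleast_1d(self.rate_curve_for(m, p).rate_at(times)))
                wts.append(prob * w)
        return np.asarray(wts), np.vstack(rows)


def _count_arrays(series):
    if hasattr(series, "records"):  # single CountSeries
        series = [series]
    return list(series)


def _distance_arrays(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "sqrt_euclid":
        a, b = np.sqrt(a), np.sqrt(b)
    return float(np.linalg.norm(a - b))


def distance(observed, simulated, kind: str = "sqrt_euclid") -> float:
    """Distance between two count series on identical time grids.

    Default ``sqrt_euclid``: Euclidean distance between element-wise
    square-rooted counts.  Symmetric; zero iff the counts are identical.
    """
    if not np.array_equal(observed.times, simulated.times):
        raise ValueError("count series are on different time grids")
    if [s.fractions for s in observed.schemes] != [s.fractions for s in simulated.schemes]:
        raise ValueError("count series have different sampling schemes")
    return _distance_arrays(observed.counts, simulated.counts, kind)


class _Problem:
    """Precomputed fit context shared by every particle evaluation."""

    def __init__(self, series, carrying_capacity, prior, cfg, noise):
        self.series = series
        self.k = float(carrying_capacity)
        self.prior = prior
        self.cfg = cfg
        self.noise = noise
        self.t_start = min(s.records[0].time for s in series)
        self.t_end = max(s.records[-1].time for s in series)
        if not self.t_end > self.t_start:
            raise ValueError("observations must span a positive time window")
        self.obs = np.concatenate([s.counts for s in series]).astype(float)
        self.times = [s.times for s in series]
        self.schemes = [s.schemes for s in series]
        self.uniform_scheme = [
            sch[0].fractions if all(x.fractions == sch[0].fractions for x in sch) else None
            for sch in self.schemes]
        self.rate_lo = prior.rate_min if cfg.simulator == "deterministic" \
            else max(0.0, prior.rate_min)
        self.rate_hi = prior.rate_max
        self.n0_bounds = []
        for s in series:
            est = max(point_estimate_population(s.records[0]), 1.0)
            self.n0_bounds.append((prior.n0_lo_factor * est, prior.n0_hi_factor * est))

    def dim(self, m: int) -> int:
        return len(self.series) + m

    def sample_prior(self, m: int, rng) -> np.ndarray:
        n0 = np.array([rng.uniform(lo, hi) for lo, hi in self.n0_bounds])
        rates = rng.uniform(self.rate_lo, self.rate_hi, size=m)
        return np.concatenate([n0, rates])

    def in_support(self, m: int, theta: np.ndarray) -> bool:
        k = len(self.series)
        for v, (lo, hi) in zip(theta[:k], self.n0_bounds):
            if not lo <= v <= hi:
                return False
        return bool(np.all((self.rate_lo <= theta[k:]) & (theta[k:] <= self.rate_hi)))

    def prior_density(self, m: int) -> float:
        dens = 1.0
        for lo, hi in self.n0_bounds:
            if hi > lo:
                dens /= hi - lo
        if self.rate_hi > self.rate_lo:
            dens /= (self.rate_hi - self.rate_lo) ** m
        return dens

    def curve(self, m: int, theta: np.ndarray) -> RateCurve:
        return RateCurve(tuple(theta[len(self.series):]), self.t_start, self.t_end)

    def simulate(self, m: int, theta: np.ndarray, rng) -> np.ndarray:
        """Forward-simulate the concatenated counts for one particle."""
        curve = self.curve(m, theta)
        out = []
        for i, s in enumerate(self.series):
            n0 = theta[i]
            times = self.times[i]
            if self.cfg.simulator == "deterministic":
                model = CultureModel(self.k, n0)
                sizes = solve_deterministic(model, curve, times, t_ref=times[0]).sizes
                sizes = np.clip(sizes, 0.0, 1e15)  # guard rare blow-up (N0>K, r<0)
            else:
                model = CultureModel(max(self.k, 1.0), float(round(float(n0))))
                span = times[-1] - times[0]
                bcfg = BranchingConfig(
                    model, curve.clamped_nonnegative().shifted(-times[0]),
                    t_end=span if span > 0 else 1.0,
                    seed=int(rng.integers(2**32)))
                traj = simulate_branching(bcfg)
                sizes = sample_trajectory(traj, times - times[0]).astype(float)
            fr = self.uniform_scheme[i]
            if fr is not None:
                from .noise import SamplingScheme
                counts = simulate_counts(sizes, SamplingScheme(fr), self.noise, rng)
            else:
                counts = np.array([
                    simulate_counts([n], sch, self.noise, rng)[0]
                    for n, sch in zip(sizes, self.schemes[i])])
            out.append(counts)
        return np.concatenate(out).astype(float)


def run_abc_smc(data, carrying_capacity: float, prior: PriorSpec | None = None,
                cfg: ABCConfig | None = None, noise: CountingNoiseSpec | None = None,
                group_label: str | None = None, progress=None) -> Posterior:
    """Fit the growth-rate curve to one series (or a joint group) by ABC-SMC.

    Parameters
    ----------
    data
        A CountSeries, or a list of CountSeries fitted jointly (shared
        rate curve, one latent N0 per series).
    carrying_capacity
        K in cells; fixed, not inferred.
    progress
        Optional callable ``progress(generation, epsilon, n_sims)``
        invoked after each generation (used by the CLI for logging).

    Returns a :class:`Posterior`; a fixed seed in ``cfg`` makes the
    result fully reproducible.

    Raises ``RuntimeError`` if a generation exhausts its simulation
    budget without filling the particle population (epsilon schedule too
    aggressive for the model/prior).
    """
    prior = prior or PriorSpec()
    cfg = cfg or ABCConfig()
    noise = noise if noise is not None else CountingNoiseSpec()
    series = _count_arrays(data)
    if sum(len(s) for s in series) < 2:
        raise ValueError("need at least two count records to fit a rate")
    prob = _Problem(series, carrying_capacity, prior, cfg, noise)
    models = list(prior.control_point_counts)
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_particles
    ms = [models[i] for i in rng.integers(len(models), size=n)]
    thetas = [prob.sample_prior(m, rng) for m in ms]
    dists = np.array([_distance_arrays(prob.obs, prob.simulate(m, th, rng), cfg.distance_kind)
                      for m, th in zip(ms, thetas)])
    weights = np.full(n, 1.0 / n)
    epsilons = [math.inf]
    if progress:
        progress(0, math.inf, n)

    for gen in range(1, cfg.n_generations):
        eps = float(weighted_quantile(dists, cfg.epsilon_quantile, weights)[0])
        epsilons.append(eps)
        # per-model bookkeeping from the previous generation
        idx_by_m = {m: [i for i, mi in enumerate(ms) if mi == m] for m in models}
        mass_by_m = {m: float(sum(weights[i] for i in idx)) for m, idx in idx_by_m.items()}
        live = [m for m in models if mass_by_m[m] > 0 and idx_by_m[m]]
        live_p = np.array([mass_by_m[m] for m in live])
        live_p = live_p / live_p.sum()
        kernels = {}
        for m in live:
            idx = idx_by_m[m]
            th = np.vstack([thetas[i] for i in idx])
            w = np.array([weights[i] for i in idx])
            w = w / w.sum()
            var = np.average((th - np.average(th, axis=0, weights=w)) ** 2, axis=0, weights=w)
            sigma = np.sqrt(2.0 * var)
            kernels[m] = (th, w, sigma)

        new_ms, new_thetas, new_dists, new_weights = [], [], [], []
        sims = 0
        while len(new_ms) < n:
            if sims >= cfg.sims_cap:
                raise RuntimeError(
                    f"generation {gen}: no particle population at epsilon={eps:.4g} "
                    f"within {cfg.sims_cap} simulations; epsilon schedule too aggressive")
            m = live[int(rng.choice(len(live), p=live_p))]
            th_prev, w_prev, sigma = kernels[m]
            j = int(rng.choice(len(w_prev), p=w_prev))
            step = np.where(sigma > 0, sigma * rng.standard_normal(len(sigma)), 0.0)
            theta = th_prev[j] + step
            sims += 1
            if not prob.in_support(m, theta):
                continue
            sim = prob.simulate(m, theta, rng)
            d = _distance_arrays(prob.obs, sim, cfg.distance_kind)
            if d <= eps:
                # SMC importance weight: prior / (model mass * kernel density)
                moving = sigma > 0
                if np.any(moving):
                    z = (theta[moving] - th_prev[:, moving]) / sigma[moving]
                    log_k = -0.5 * np.sum(z**2, axis=1) - np.sum(np.log(sigma[moving]))
                    dens = np.exp(log_k - log_k.max())
                    fixed_ok = np.all(th_prev[:, ~moving] == theta[~moving], axis=1)
                    denom = float(np.sum(w_prev * dens * fixed_ok)) * math.exp(log_k.max())
                else:
                    denom = float(np.sum(w_prev * np.all(th_prev == theta, axis=1)))
                mass = mass_by_m[m]
                new_ms.append(m)
                new_thetas.append(theta)
                new_dists.append(d)
                new_weights.append(prob.prior_density(m) / max(mass * denom, 1e-300))
        ms, thetas, dists = new_ms, new_thetas, np.asarray(new_dists)
        weights = np.asarray(new_weights)
        weights = weights / weights.sum()
        if progress:
            progress(gen, eps, sims)

    model_probs = {m: float(sum(w for mi, w in zip(ms, weights) if mi == m)) for m in models}
    model_posts = {}
    for m in models:
        idx = [i for i, mi in enumerate(ms) if mi == m]
        if idx:
            params = np.vstack([thetas[i] for i in idx])
            w = np.array([weights[i] for i in idx])
            w = w / w.sum()
        else:
            params = np.empty((0, prob.dim(m)))
            w = np.empty(0)
        names = tuple(f"n0[{s.name}]" for s in series) + tuple(f"r{i}" for i in range(m))
        knots = RateCurve((0.0,) * m, prob.t_start, prob.t_end).knots
        times = tuple(s.records[0].time for s in series) + tuple(float(t) for t in knots)
        model_posts[m] = ModelPosterior(m, params, w, names, times)

    label = group_label or (series[0].group or series[0].name)
    return Posterior(
        group=label, models=model_posts, model_probabilities=model_probs,
        epsilons=tuple(epsilons), t_start=prob.t_start, t_end=prob.t_end,
        carrying_capacity=prob.k, series_names=tuple(s.name for s in series),
        series_t0={s.name: float(s.records[0].time) for s in series})


def posterior_rate_band(post: Posterior, times, mass: float = DEFAULT_HPDI_MASS) -> dict:
    """Per-time HPD band of r(t) from the pooled weighted posterior."""
    times = np.asarray(times, dtype=float)
    wts, mat = post.pooled_rate_samples(times)
    if mat.shape[0] == 0:
        raise ValueError("empty posterior")
    low = np.empty(len(times))
    high = np.empty(len(times))
    med = np.empty(len(times))
    for i in range(len(times)):
        band = hpdi(mat[:, i], wts, mass)
        low[i], high[i] = band.low, band.high
        med[i] = weighted_quantile(mat[:, i], 0.5, wts)[0]
    return {"times": times, "low": low, "high": high, "median": med}


def posterior_population_band(post: Posterior, times, mass: float = DEFAULT_HPDI_MASS,
                              series: str | None = None) -> dict:
    """Per-time HPD band of the population curve N(t) for one series."""
    times = np.asarray(times, dtype=float)
    if series is None:
        if len(post.series_names) != 1:
            raise ValueError("specify which series to band in a grouped fit")
        series = post.series_names[0]
    s_idx = post.series_names.index(series)
    t_ref = post.series_t0[series]
    k = post.carrying_capacity
    wts, rows = [], []
    for m in sorted(post.models):
        mp = post.models[m]
        p_model = post.model_probabilities[m]
        if p_model <= 0 or mp.params.shape[0] == 0:
            continue
        for p, w in zip(mp.params, mp.weights):
            curve = post.rate_curve_for(m, p)
            model = CultureModel(k, p[s_idx])
            rows.append(solve_deterministic(model, curve, times, t_ref=t_ref).sizes)
            wts.append(p_model * w)
    wts = np.asarray(wts)
    mat = np.vstack(rows)
    low = np.empty(len(times))
    high = np.empty(len(times))
    med = np.empty(len(times))
    for i in range(len(times)):
        band = hpdi(mat[:, i], wts, mass)
        low[i], high[i] = band.low, band.high
        med[i] = weighted_quantile(mat[:, i], 0.5, wts)[0]
    return {"times": times, "low": low, "high": high, "median": med}
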