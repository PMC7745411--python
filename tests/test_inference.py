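import dataclasses

import numpy as np
import pytest

from cellrate import (
    ABCConfig,
    CountRecord,
    CountSeries,
    CountingNoiseSpec,
    PriorSpec,
    SamplingScheme,
    distance,
    hpdi,
    posterior_population_band,
    posterior_rate_band,
    run_abc_smc,
)
from cellrate.inference import ModelPosterior, Posterior
from cellrate.scenarios import builtin_scenarios, generate_scenario


def series_from_counts(counts, times=None, fractions=(1.0,), name="s"):
    times = times if times is not None else list(range(len(counts)))
    scheme = SamplingScheme(fractions)
    return CountSeries(name, tuple(
        CountRecord(name, float(t), int(c), scheme) for t, c in zip(times, counts)))


class TestDistance:
    def test_identical_series_zero(self):
        a = series_from_counts([4, 9, 16])
        assert distance(a, a) == 0.0

    def test_hand_computed_sqrt_euclid(self):
        a = series_from_counts([4, 9])
        b = series_from_counts([1, 4])
        assert distance(a, b) == pytest.approx(np.sqrt(2.0))

    def test_symmetry(self):
        a = series_from_counts([3, 7, 1])
        b = series_from_counts([5, 2, 9])
        assert distance(a, b) == distance(b, a)

    def test_plain_euclid(self):
        a = series_from_counts([4, 9])
        b = series_from_counts([1, 4])
        assert distance(a, b, kind="euclid") == pytest.approx(np.sqrt(9 + 25))

    def test_mismatched_grid_rejected(self):
        a = series_from_counts([4, 9], times=[0, 1])
        b = series_from_counts([4, 9], times=[0, 2])
        with pytest.raises(ValueError, match="time grids"):
            distance(a, b)


def small_cfg(seed=0, **kw):
    kw.setdefault("n_particles", 50)
    kw.setdefault("n_generations", 4)
    return ABCConfig(seed=seed, **kw)


@pytest.fixture(scope="module")
def constant_data():
    return generate_scenario(builtin_scenarios()["constant"].with_seed(8))[0]


class TestRunAbcSmc:
    def test_epsilon_schedule_non_increasing(self, constant_data):
        post = run_abc_smc(constant_data, 3e6, PriorSpec(control_point_counts=(1,)),
                           small_cfg(seed=1))
        eps = post.epsilons[1:]
        assert all(b <= a for a, b in zip(eps, eps[1:]))

    def test_identical_seed_identical_posterior(self, constant_data):
        prior = PriorSpec(control_point_counts=(1, 2))
        a = run_abc_smc(constant_data, 3e6, prior, small_cfg(seed=4))
        b = run_abc_smc(constant_data, 3e6, prior, small_cfg(seed=4))
        assert a.model_probabilities == b.model_probabilities
        for m in a.models:
            np.testing.assert_array_equal(a.models[m].params, b.models[m].params)
            np.testing.assert_array_equal(a.models[m].weights, b.models[m].weights)

    def test_weights_normalised(self, constant_data):
        post = run_abc_smc(constant_data, 3e6, PriorSpec(control_point_counts=(1, 2)),
                           small_cfg(seed=2))
        assert sum(post.model_probabilities.values()) == pytest.approx(1.0)
        for mp in post.models.values():
            if len(mp.weights):
                assert mp.weights.sum() == pytest.approx(1.0)
                assert np.all(mp.weights >= 0)

    def test_collapsed_prior_returns_the_point(self):
        """With observation noise off and the prior squeezed onto the
        truth, the posterior is (numerically) that point."""
        truth = 0.9
        scen = dataclasses.replace(
            builtin_scenarios()["constant"],
            curve=dataclasses.replace(builtin_scenarios()["constant"].curve,
                                      control_values=(truth,)),
            noise=CountingNoiseSpec(kind="none"), seed=1)
        data, _ = generate_scenario(scen)
        eps_w = 1e-9
        prior = PriorSpec(rate_min=truth - eps_w, rate_max=truth + eps_w,
                          control_point_counts=(1,),
                          n0_lo_factor=1.0, n0_hi_factor=1.0)
        post = run_abc_smc(data, 3e6, prior, small_cfg(seed=3, n_particles=20,
                                                       n_generations=2))
        mp = post.models[1]
        np.testing.assert_allclose(mp.params[:, 1], truth, atol=1e-6)
        assert mp.weights.sum() == pytest.approx(1.0)

    def test_too_few_records_rejected(self):
        single = series_from_counts([5], times=[0.0])
        with pytest.raises(ValueError, match="two count records"):
            run_abc_smc(single, 1e5)

    def test_impossible_epsilon_raises(self, constant_data):
        """A simulation budget too small to fill a generation signals an
        over-aggressive schedule instead of looping forever."""
        cfg = small_cfg(seed=5, n_particles=50, n_generations=8,
                        max_sims_per_generation=120)
        with pytest.raises(RuntimeError, match="simulations"):
            run_abc_smc(constant_data, 3e6, PriorSpec(control_point_counts=(1,)), cfg)

    def test_posterior_contraction_with_more_observations(self):
        """Doubling the observation density shrinks the constant-rate
        HPDI on average.  Observed over a window where the culture is
        still growing: points taken after saturation carry no rate
        information and cannot contract anything."""
        from cellrate import RateCurve

        widths = {}
        for label, times in [("sparse", (0.0, 1.0, 2.0, 3.0, 4.0)),
                             ("dense", tuple(np.linspace(0, 4, 9)))]:
            ws = []
            for seed in range(4):
                scen = dataclasses.replace(builtin_scenarios()["constant"],
                                           curve=RateCurve((1.0,), 0.0, 4.0),
                                           times=times, seed=30 + seed)
                data, _ = generate_scenario(scen)
                post = run_abc_smc(data, 3e6, PriorSpec(control_point_counts=(1,)),
                                   ABCConfig(n_particles=100, n_generations=9, seed=seed))
                mp = post.models[1]
                ws.append(hpdi(mp.params[:, 1], mp.weights).width)
            widths[label] = np.mean(ws)
        assert widths["dense"] < widths["sparse"]

    def test_grouped_fit_shares_curve_with_per_series_n0(self):
        """Two replicate series fitted jointly yield one rate posterior
        and two initial-population parameters."""
        s1, _ = generate_scenario(builtin_scenarios()["constant"].with_seed(21))
        scen2 = dataclasses.replace(builtin_scenarios()["constant"], seed=22)
        s2raw, _ = generate_scenario(scen2)
        s2 = CountSeries("rep2", tuple(
            dataclasses.replace(r, name="rep2") for r in s2raw.records))
        post = run_abc_smc([s1, s2], 3e6, PriorSpec(control_point_counts=(1,)),
                           small_cfg(seed=6))
        mp = post.models[1]
        assert mp.param_names == ("n0[constant]", "n0[rep2]", "r0")
        assert mp.params.shape[1] == 3


def point_posterior(rate_values, t_span=(0.0, 8.0), n0=1e5, k=3e6):
    """Posterior with a single sample, for band plumbing tests."""
    m = len(rate_values)
    params = np.array([[n0] + list(rate_values)])
    mp = ModelPosterior(m, params, np.array([1.0]),
                        ("n0[s]",) + tuple(f"r{i}" for i in range(m)),
                        (t_span[0],) * (1 + m))
    return Posterior("s", {m: mp}, {m: 1.0}, (np.inf,), t_span[0], t_span[1],
                     k, ("s",), {"s": t_span[0]})


class TestBands:
    def test_single_sample_band_is_the_curve(self):
        post = point_posterior([0.3, 1.1])
        band = posterior_rate_band(post, [0.0, 4.0, 8.0])
        np.testing.assert_allclose(band["low"], [0.3, 0.7, 1.1])
        np.testing.assert_allclose(band["high"], band["low"])

    def test_full_mass_spans_sample_range(self, small_posterior):
        _, post = small_posterior
        t = [0.0, 8.0]
        full = posterior_rate_band(post, t, mass=1.0)
        default = posterior_rate_band(post, t)
        assert np.all(full["low"] <= default["low"] + 1e-12)
        assert np.all(full["high"] >= default["high"] - 1e-12)

    def test_population_band_starts_near_n0(self):
        post = point_posterior([1.0], n0=5e4)
        band = posterior_population_band(post, [0.0, 4.0])
        assert band["low"][0] == pytest.approx(5e4)
        assert band["high"][1] > band["high"][0]

    def test_endpoint_band_wider_on_saturating_data(self):
        """Once the culture sits at carrying capacity the rate no longer
        moves the counts, so the late-time rate posterior is wider."""
        data, _ = generate_scenario(builtin_scenarios()["constant"].with_seed(17))
        post = run_abc_smc(data, 3e6, PriorSpec(control_point_counts=(2,)),
                           ABCConfig(n_particles=100, n_generations=6, seed=7))
        band = posterior_rate_band(post, [0.0, 8.0])
        start_width = band["high"][0] - band["low"][0]
        end_width = band["high"][1] - band["low"][1]
        assert end_width > start_width
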