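import numpy as np
import pytest

from cellrate import (
    ABCConfig,
    CountRecord,
    CountSeries,
    PriorSpec,
    SamplingScheme,
    run_abc_smc,
)
from cellrate.scenarios import builtin_scenarios, generate_scenario

# The minimal worked example: 1 mL culture, K = 3e6, two-stage sampling
# 10 uL of 1 mL then 0.2 uL (undiluted equivalent) of the sample.
TABLE1_ROWS = [(0.0, 19), (2.0, 105), (4.0, 403), (6.0, 529), (8.0, 591)]
TABLE1_SCHEME = SamplingScheme((0.01, 0.02))


@pytest.fixture
def minimal_series() -> CountSeries:
    records = tuple(CountRecord("minimal", t, c, TABLE1_SCHEME) for t, c in TABLE1_ROWS)
    return CountSeries("minimal", records)


@pytest.fixture
def minimal_csv(tmp_path):
    path = tmp_path / "minimal.csv"
    lines = ["name,time,count,sample1,sample2"]
    lines += [f"minimal,{t},{c},0.01,0.02" for t, c in TABLE1_ROWS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def minimal_toml(tmp_path):
    path = tmp_path / "minimal.toml"
    path.write_text("carrying_capacity = 3e6\nseed = 1\n")
    return path


@pytest.fixture(scope="session")
def small_posterior():
    """A quick two-model fit of a constant-rate synthetic series, shared
    across reporting/inference tests that only need a valid posterior."""
    series, _ = generate_scenario(builtin_scenarios()["constant"].with_seed(3))
    prior = PriorSpec(control_point_counts=(1, 2))
    cfg = ABCConfig(n_particles=60, n_generations=4, seed=5)
    post = run_abc_smc(series, 3e6, prior, cfg)
    return series, post


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
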