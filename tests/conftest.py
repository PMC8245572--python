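"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import somtag as st


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark (planted treatment effect on walking
    and eating), at the package's default study conditions."""
    return st.make_benchmark(seed=1)


@pytest.fixture(scope="session")
def null_benchmark():
    """Benchmark with an identity treatment effect."""
    cfg = st.BenchmarkConfig(effect=st.TreatmentEffect.null())
    return st.make_benchmark(cfg, seed=1)


@pytest.fixture(scope="session")
def model7(benchmark):
    """7×7 model trained on a 2000-epoch draw from the bib_off pool."""
    rng = np.random.default_rng(0)
    idx = rng.choice(len(benchmark.train_off), 2000, replace=True)
    return st.train_supersom(
        benchmark.train_off.iloc[idx], st.make_grid(7, 7), seed=0
    )


@pytest.fixture(scope="session")
def small_table():
    """Feature table from a short (300 s) simulated trace."""
    ds = st.simulate_trace(
        st.default_behaviour_library(), 300.0, seed=7, min_class_s=10.0
    )
    return st.build_feature_table(ds.trace, ds.intervals)


@pytest.fixture()
def flat_trace():
    """60 s of a resting device: constant (0, 0, 1) g at 50 Hz."""
    n = 3000
    return st.RawTrace(
        times=np.arange(n) / 50.0,
        x=np.zeros(n),
        y=np.zeros(n),
        z=np.ones(n),
        rate_hz=50.0,
    )
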