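import numpy as np
import pytest

from neurotox import (
    PlateLayout,
    SpikeTrainSpec,
    biphasic_template,
    generate_spike_trains,
)


@pytest.fixture(scope="session")
def short_layout():
    """Small plate for fast unit tests: 1 well worth of 4 electrodes, 60 s."""
    return PlateLayout(n_wells=24, electrodes_per_well=4, duration=60.0)


@pytest.fixture(scope="session")
def template():
    return biphasic_template(sampling_rate=12500.0, peak_amplitude=50.0)


@pytest.fixture(scope="session")
def bursty_trains(short_layout):
    spec = SpikeTrainSpec(background_rate=0.5, burst_rate=6.0, seed=7)
    trains, truth = generate_spike_trains(short_layout, spec, wells=["A1"])
    return trains, truth


def random_trains(seed: int, duration: float = 60.0, n: int = 200):
    """Mixed Poisson / bursty spike-time arrays for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kind = rng.integers(3)
        if kind == 0:  # sparse Poisson
            t = np.sort(rng.uniform(0, duration, rng.poisson(20)))
        elif kind == 1:  # dense Poisson (ISIs often below 0.1 s)
            t = np.sort(rng.uniform(0, duration, rng.poisson(900)))
        else:  # bursty: clustered around onsets
            onsets = rng.uniform(0, duration, rng.poisson(8))
            parts = [
                o + np.cumsum(rng.uniform(0.01, 0.12, rng.integers(2, 12)))
                for o in onsets
            ]
            base = np.sort(rng.uniform(0, duration, rng.poisson(30)))
            t = np.sort(np.concatenate([base, *parts])) if parts else base
            t = t[t <= duration]
        out.append(t)
    return out
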