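"""Burst detection, firing-rate and synchrony metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurotox import (
    Burst,
    BurstSettings,
    SpikeTrainSet,
    SynchronySettings,
    active_electrodes,
    compute_well_metrics,
    detect_bursts_isi,
    mean_firing_rate,
    normalized_multiinformation,
    sttc_pair,
    synchrony_index,
    well_burst_stats,
)
from conftest import random_trains


def brute_force_bursts(t: np.ndarray, min_spikes: int = 5, max_isi: float = 0.1):
    """Oracle: enumerate all maximal runs with every ISI <= max_isi."""
    bursts = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] - t[j] <= max_isi:
            j += 1
        if j - i + 1 >= min_spikes:
            bursts.append((float(t[i]), float(t[j]), j - i + 1))
        i = j + 1
    return bursts


class TestBurstDetection:
    def test_single_burst_of_six(self):
        t = np.array([0, 0.05, 0.10, 0.15, 0.20, 0.25])
        (b,) = detect_bursts_isi(t)
        assert (b.start, b.end, b.n_spikes) == (0.0, 0.25, 6)

    def test_four_spikes_is_no_burst(self):
        assert detect_bursts_isi(np.array([0, 0.05, 0.10, 0.15])) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            detect_bursts_isi(np.array([0.2, 0.1, 0.3, 0.4, 0.5]))

    def test_oracle_equivalence_on_random_trains(self):
        for i, t in enumerate(random_trains(seed=123, n=300)):
            got = [
                (b.start, b.end, b.n_spikes) for b in detect_bursts_isi(t)
            ]
            assert got == brute_force_bursts(t), f"train {i}"

    @given(st.lists(st.floats(0, 60), min_size=0, max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_burst_maximality_and_containment(self, times):
        t = np.sort(np.asarray(times, dtype=float))
        bursts = detect_bursts_isi(t)
        total_in_bursts = 0
        for b in bursts:
            inside = t[(t >= b.start) & (t <= b.end)]
            assert inside.size == b.n_spikes
            assert np.all(np.diff(inside) <= 0.1)
            total_in_bursts += b.n_spikes
            # not extendable on either side
            left = t[t < b.start]
            right = t[t > b.end]
            if left.size:
                assert b.start - left[-1] > 0.1
            if right.size:
                assert right[0] - b.end > 0.1
        assert total_in_bursts <= t.size


class TestRates:
    def test_mfr_definition(self):
        t = np.linspace(0, 299, 300)
        assert mean_firing_rate(t, (0.0, 300.0)) == 1.0
        assert mean_firing_rate(np.empty(0), (0.0, 300.0)) == 0.0

    def test_mfr_equals_oracle_count_over_duration(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 300, 1234))
        sub = (50.0, 200.0)
        oracle = np.sum((t >= sub[0]) & (t <= sub[1])) / 150.0
        assert mean_firing_rate(t, sub) == oracle

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            mean_firing_rate(np.array([1.0]), (2.0, 2.0))

    def test_well_burst_stats_sums_over_electrodes(self):
        burst = lambda t0, n: t0 + np.arange(n) * 0.05
        trains = {
            ("A1", 0): np.concatenate([burst(1, 6), burst(10, 7)]),
            ("A1", 1): np.array([0.5, 5.0, 9.0]),
            ("A1", 2): burst(3, 5),
            ("A1", 3): burst(4, 12),
        }
        n, freq = well_burst_stats(trains, duration=60.0)
        assert n == 4
        # bursting electrodes have 2, 1, 1 bursts -> mean/duration
        assert freq == pytest.approx(np.mean([2, 1, 1]) / 60.0)

    def test_empty_well_zeros(self):
        assert well_burst_stats({("A1", 0): np.empty(0)}, duration=60.0) == (0, 0.0)

    def test_active_electrode_threshold(self):
        trains = {
            ("A1", 0): np.sort(np.linspace(1, 59, 60)),  # 1 Hz
            ("A1", 1): np.array([1.0, 2.0]),             # 2/min < 5/min
            ("A1", 2): np.empty(0),
        }
        assert active_electrodes(trains, duration=60.0) == 1


class TestSynchrony:
    def test_identical_trains_give_unity(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 300, 300))
        assert sttc_pair(t, t, 0.05, 300.0) == pytest.approx(1.0)
        assert synchrony_index({("A1", 0): t, ("A1", 1): t}, duration=300.0) > 0.9

    def test_independent_trains_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trains = {
                ("A1", i): np.sort(rng.uniform(0, 300, rng.poisson(300)))
                for i in range(16)
            }
            vals.append(synchrony_index(trains, duration=300.0))
        assert np.mean(vals) < 0.1

    def test_fewer_than_two_active_gives_zero(self):
        assert synchrony_index({("A1", 0): np.array([1.0, 2.0])}, duration=10.0) == 0.0

    def test_common_time_shift_invariance(self):
        rng = np.random.default_rng(3)
        base = {
            ("A1", i): np.sort(rng.uniform(10, 280, 250)) for i in range(6)
        }
        shifted = {k: v + 5.0 for k, v in base.items()}
        a = synchrony_index(base, duration=300.0)
        b = synchrony_index(shifted, duration=300.0)
        assert abs(a - b) < 0.05


class TestNMI:
    def test_identical_channels_give_one(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 300, 200))
        trains = {("A1", i): t for i in range(4)}
        assert normalized_multiinformation(trains, duration=300.0) == pytest.approx(1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(1)
        trains = {
            ("A1", i): np.sort(rng.uniform(0, 300, 300)) for i in range(16)
        }
        assert normalized_multiinformation(trains, duration=300.0) <= 0.05

    def test_single_electrode_is_zero(self):
        assert (
            normalized_multiinformation(
                {("A1", 0): np.array([1.0, 2.0])}, duration=10.0
            )
            == 0.0
        )

    def test_silent_well_is_zero(self):
        trains = {("A1", i): np.empty(0) for i in range(4)}
        assert normalized_multiinformation(trains, duration=10.0) == 0.0


class TestWellMetrics:
    def test_empty_well_all_zero(self):
        sts = SpikeTrainSet(
            trains={("A1", i): np.empty(0) for i in range(16)}, duration=300.0
        )
        m = compute_well_metrics(sts)
        assert m.number_of_spikes == 0
        assert m.mean_firing_rate == 0.0
        assert m.number_of_bursts == 0
        assert m.n_active_electrodes == 0
        assert m.synchrony_index == 0.0
        assert m.nmi == 0.0

    def test_metrics_invariant_under_relabeling(self, bursty_trains):
        trains, _ = bursty_trains
        relabeled = SpikeTrainSet(
            trains={
                (w, 100 - e): t for (w, e), t in trains.trains.items()
            },
            duration=trains.duration,
        )
        a = compute_well_metrics(trains)
        b = compute_well_metrics(relabeled)
        assert a.number_of_spikes == b.number_of_spikes
        assert a.number_of_bursts == b.number_of_bursts
        assert a.mean_firing_rate == pytest.approx(b.mean_firing_rate)
        assert a.synchrony_index == pytest.approx(b.synchrony_index)

    def test_burst_spikes_bounded_by_total(self, bursty_trains):
        trains, _ = bursty_trains
        for key, t in trains.trains.items():
            n_burst_spikes = sum(b.n_spikes for b in detect_bursts_isi(t))
            assert n_burst_spikes <= t.size

    def test_detected_bursts_match_truth_on_clean_well(self, short_layout):
        from neurotox import SpikeTrainSpec, generate_spike_trains

        spec = SpikeTrainSpec(background_rate=0.0, burst_rate=4.0, seed=21)
        trains, truth = generate_spike_trains(short_layout, spec, wells=["A1"])
        n, _ = well_burst_stats(trains)
        assert n == len(truth)
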