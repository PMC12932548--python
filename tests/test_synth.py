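"""Generator properties: determinism, conservation, ground-truth consistency."""

import dataclasses

import numpy as np
import pytest

from neurotox import (
    DoseEffectSpec,
    MorphologySpec,
    PlateLayout,
    SpikeTrainSet,
    SpikeTrainSpec,
    apply_dose_effect,
    biphasic_template,
    generate_neuron_image,
    generate_spike_trains,
    render_voltage_trace,
)
from neurotox.synth import SomaGroundTruth, band_limited_noise


class TestSpikeTrains:
    def test_silent_spec_gives_empty_output(self, short_layout):
        spec = SpikeTrainSpec(background_rate=0.0, burst_rate=0.0, seed=0)
        trains, truth = generate_spike_trains(short_layout, spec, wells=["A1"])
        assert truth == []
        assert all(t.size == 0 for t in trains.trains.values())

    def test_poisson_background_total_count(self):
        # 1 Hz x 300 s x 100 electrodes: Poisson mean 30000
        layout = PlateLayout(electrodes_per_well=100, duration=300.0)
        spec = SpikeTrainSpec(background_rate=1.0, burst_rate=0.0, seed=11)
        trains, _ = generate_spike_trains(layout, spec, wells=["A1"])
        total = trains.n_spikes()
        assert abs(total - 30_000) <= 3 * np.sqrt(30_000)

    def test_ground_truth_bursts_satisfy_isi_rule(self, bursty_trains):
        trains, truth = bursty_trains
        assert truth, "expected bursts at 6/min"
        for b in truth:
            t = trains.trains[(b.well, b.electrode)]
            inside = t[(t >= b.start - 1e-12) & (t <= b.end + 1e-12)]
            assert b.n_spikes >= 5
            assert inside.size >= b.n_spikes  # background may add spikes
            # added spikes only split ISIs, so the rule still holds inside
            assert np.all(np.diff(inside) <= 0.1 + 1e-12)

    def test_sorted_and_bounded(self, bursty_trains, short_layout):
        trains, _ = bursty_trains
        for t in trains.trains.values():
            assert np.all(np.diff(t) >= 0)
            if t.size:
                assert t[0] >= 0 and t[-1] <= short_layout.duration

    def test_same_seed_bit_identical(self, short_layout):
        spec = SpikeTrainSpec(seed=5)
        a, ta = generate_spike_trains(short_layout, spec, wells=["A1"])
        b, tb = generate_spike_trains(short_layout, spec, wells=["A1"])
        assert ta == tb
        for k in a.trains:
            np.testing.assert_array_equal(a.trains[k], b.trains[k])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout(duration=0.0)


class TestVoltageRendering:
    def test_noise_only_trace_has_requested_sd(self, template):
        empty = SpikeTrainSet(trains={("A1", 0): np.empty(0)}, duration=10.0)
        rec = render_voltage_trace(empty, template, noise_sd=5.0, seed=3)
        assert rec.data.shape == (1, 125_000)
        assert abs(rec.data.std() - 5.0) < 0.5

    def test_noiseless_single_spike_places_template_peak(self, template):
        trains = SpikeTrainSet(trains={("A1", 0): np.array([1.0])}, duration=2.0)
        rec = render_voltage_trace(trains, template, noise_sd=0.0, seed=0)
        x = rec.data[0]
        assert np.abs(x).argmax() == 12_500
        lo = 12_500 - template.peak_index
        np.testing.assert_allclose(
            x[lo : lo + template.samples.size], template.samples
        )
        outside = np.concatenate([x[: lo], x[lo + template.samples.size :]])
        assert np.all(outside == 0)

    def test_linear_superposition_conserves_insertions(self, template):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0.1, 9.9, 50))
        trains = SpikeTrainSet(trains={("A1", 0): t}, duration=10.0)
        rec = render_voltage_trace(trains, template, noise_sd=0.0, seed=0)
        # overlapping spikes sum linearly, so the trace integral is n x the
        # template integral
        np.testing.assert_allclose(
            rec.data.sum(), 50 * template.samples.sum(), rtol=1e-9
        )

    def test_spike_beyond_duration_rejected(self, template):
        trains = SpikeTrainSet(trains={("A1", 0): np.array([1.0])}, duration=2.0)
        trains.trains[("A1", 0)] = np.array([2.5])  # bypass container check
        with pytest.raises(ValueError, match="outside recording"):
            render_voltage_trace(trains, template, noise_sd=0.0, seed=0)

    def test_band_limited_noise_is_zero_mean_with_target_sd(self):
        x = band_limited_noise(np.random.default_rng(0), 125_000, 12500.0, 5.0)
        assert abs(x.mean()) < 0.2
        assert np.isclose(x.std(), 5.0)


def _brute_force_phenotypes(soma: SomaGroundTruth) -> dict:
    """Independent traversal of the stored segment tree."""
    children: dict[int, list] = {}
    for s in soma.segments:
        children.setdefault(s.parent, []).append(s)

    def tip_depth(seg) -> float:
        kids = children.get(seg.index, [])
        if not kids:
            return seg.length
        return seg.length + max(tip_depth(k) for k in kids)

    roots = children.get(-1, [])
    return {
        "n_roots": len(roots),
        "n_segments": len(soma.segments),
        "n_extremities": sum(
            1 for s in soma.segments if s.index not in children
        ),
        "n_nodes": sum(1 for s in soma.segments if s.index in children),
        "total": sum(s.length for s in soma.segments),
        "max": max((tip_depth(r) for r in roots), default=0.0),
    }


class TestNeuronImages:
    def test_soma_without_neurites_has_zero_phenotypes(self):
        spec = MorphologySpec(n_somas=1, neurites_mean=0.0, seed=1)
        image, gt = generate_neuron_image(spec)
        assert len(gt.somas) == 1
        s = gt.somas[0]
        assert (s.n_roots, s.n_nodes, s.n_extremities, s.n_segments) == (0, 0, 0, 0)
        assert image.nuclei.max() > 0 and image.marker.max() > 0

    def test_ground_truth_matches_brute_force_traversal(self):
        for seed in range(10):
            _, gt = generate_neuron_image(MorphologySpec(seed=seed))
            for s in gt.somas:
                bf = _brute_force_phenotypes(s)
                assert s.n_roots == bf["n_roots"]
                assert s.n_segments == bf["n_segments"]
                assert s.n_extremities == bf["n_extremities"]
                assert s.n_nodes == bf["n_nodes"]
                assert np.isclose(s.total_length, bf["total"])
                assert np.isclose(s.max_length, bf["max"])

    def test_trees_are_acyclic_with_binary_nodes(self):
        # every internal segment has exactly two children: segments =
        # roots + 2 x nodes and extremities = roots + nodes
        for seed in range(10):
            _, gt = generate_neuron_image(MorphologySpec(seed=seed))
            for s in gt.somas:
                assert s.n_segments == s.n_roots + 2 * s.n_nodes
                assert s.n_extremities == s.n_roots + s.n_nodes

    def test_image_determinism(self):
        a_img, a_gt = generate_neuron_image(MorphologySpec(seed=3))
        b_img, b_gt = generate_neuron_image(MorphologySpec(seed=3))
        np.testing.assert_array_equal(a_img.marker, b_img.marker)
        assert a_gt.to_dict() == b_gt.to_dict()

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError):
            MorphologySpec(image_size=(32, 32), soma_radius=12)


class TestDoseEffects:
    def test_identity_factor_leaves_spec_unchanged(self):
        base = SpikeTrainSpec(background_rate=2.0, burst_rate=6.0)
        eff = DoseEffectSpec(factors={(10.0, 24.0): 1.0})
        mod = apply_dose_effect(base, eff, 10.0, 24.0)
        assert mod.background_rate == base.background_rate
        assert mod.burst_rate == base.burst_rate

    def test_half_factor_halves_rates(self):
        base = SpikeTrainSpec(background_rate=2.0, burst_rate=6.0)
        eff = DoseEffectSpec(factors={(10.0, 24.0): 0.5})
        mod = apply_dose_effect(base, eff, 10.0, 24.0)
        assert mod.background_rate == 1.0
        assert mod.burst_rate == 3.0
        assert mod.provenance["dose_effect"]["factor"] == 0.5

    def test_morphology_lengths_scale(self):
        base = MorphologySpec(segment_length_mean=40.0)
        eff = DoseEffectSpec(factors={(5.0, 72.0): 0.75})
        mod = apply_dose_effect(base, eff, 5.0, 72.0)
        assert mod.segment_length_mean == 30.0

    def test_unknown_condition_rejected(self):
        eff = DoseEffectSpec(factors={(10.0, 24.0): 0.5})
        with pytest.raises(KeyError):
            apply_dose_effect(SpikeTrainSpec(), eff, 99.0, 24.0)

    def test_baseline_factor_must_be_one(self):
        with pytest.raises(ValueError):
            DoseEffectSpec(factors={(0.0, 24.0): 0.5})
        with pytest.raises(ValueError):
            DoseEffectSpec(factors={(10.0, 24.0): -1.0})
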