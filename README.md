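# neurotox

Dual-endpoint in-vitro neurotoxicity quantification for stem-cell-derived
neuronal cultures: microelectrode-array (MEA) network electrophysiology and
high-content neurite-outgrowth morphometry, tied together by a
dose–response statistical layer and a synthetic-data generator that
provides exact ground truth for every stage.

## Who this is for

Screening labs that record multi-well MEA plates (24 wells × 16
extracellular electrodes, 12.5 kHz sampling) and image β-III-tubulin /
DAPI-stained neurons, and want an open, testable re-implementation of the
standard vendor analysis chain: spike detection → burst/synchrony metrics →
baseline-normalized dose–time effect calls, plus the six neurite phenotypes
and the ANOVA/Dunnett comparisons applied to them. Because raw recordings
for this assay class are rarely deposited, the package ships a generator
that produces voltage traces, neuron images, and dose-effect scenarios with
known truth, so the whole chain is verifiable end to end.

## The methods at the core

**Spike detection.** Traces are band-passed 200–3000 Hz (4th-order
Butterworth, zero phase) and thresholded adaptively at *k*·σ̂ with *k* = 6,
where σ̂ = median(|x|)/0.6745 is re-estimated in 1-second bins per
electrode. Events are extrema of |x| within a ±dead-time window (1.5 ms),
so raising *k* can only remove detections.

**Burst detection (ISI threshold).** An electrode burst is a maximal run of
≥ 5 spikes with every inter-spike interval ≤ 0.1 s. Well-level Number of
Bursts is the sum over electrodes.

**Network metrics.** Mean Firing Rate = spikes / duration (Hz); active
electrodes fire ≥ 5 spikes/min; the Synchrony Index is the spike-time
tiling coefficient (STTC) averaged over electrode pairs and clipped to
[0, 1]; the Normalized Multiinformation is
(Σᵢ H(Xᵢ) − H(X₁,…,Xₖ)) / (Σᵢ H(Xᵢ) − maxᵢ H(Xᵢ)) on 50-ms binarized
trains, 1 for identical channels and ≈ 0 for independent ones.

**Morphometry.** Nuclei are Otsu-thresholded and watershed-split; somas are
the opening-surviving marker blobs; the neurite mask is skeletonized to 1 px
and converted to a soma-rooted graph with geodesic edge lengths (1 axial,
√2 diagonal). The six phenotypes are: maximum neurite length, total neurite
length, and the numbers of extremities, roots, segments and nodes.

**Statistics.** Time-course metrics are normalized to their pre-dose (0 h)
baseline; per (dose, timepoint) the relative value is classified excitatory
(> 1.2), inhibitory (< 0.8) or none, with per-dose trajectory labels such
as "inhibition→excitation". Replicated dose groups run Shapiro–Wilk,
Bartlett, one-way ANOVA, and Dunnett's many-to-one comparisons against the
dose-0 control (α = 0.05). qPCR tables are reduced by the ΔΔCt method and
reported as −ΔΔCt (positive = enhanced expression vs the calibrator).

## Worked example

Simulate one well at the standard recording settings, render voltage with a
50 µV biphasic template over 5 µV band-limited noise (SNR 10), detect
spikes, and compute the well metric panel:

```python
from neurotox import (
    PlateLayout, SpikeTrainSpec, biphasic_template, generate_spike_trains,
    render_voltage_trace, detect_spikes, compute_well_metrics,
)

layout = PlateLayout()                      # 24 wells x 16 electrodes, 12.5 kHz, 300 s
spec = SpikeTrainSpec(background_rate=1.0, burst_rate=6.0,
                      synchrony_coupling=0.5, seed=42)
trains, truth = generate_spike_trains(layout, spec, wells=["A1"])
rec = render_voltage_trace(trains, biphasic_template(peak_amplitude=50.0),
                           noise_sd=5.0, seed=43)
detected = detect_spikes(rec)
m = compute_well_metrics(detected, well="A1")
```

This prints:

```
ground-truth spikes: 8616  bursts: 474
detected spikes:     8598
mean firing rate:    1.791 Hz per active electrode
number of bursts:    474
burst frequency avg: 0.0988 Hz
active electrodes:   16
synchrony index:     0.089
NMI:                 0.074
```

At SNR 10 the detector recovers 99.8 % of the generated spikes; every
generated burst is found by the ISI rule; and a half-coupled well sits at a
low but non-zero synchrony level (fully shared burst onsets drive the index
toward 1, independent wells toward 0).

The same stages are available as a CLI (`neurotox simulate mea|images`,
`neurotox detect-spikes`, `neurotox mea-metrics`, `neurotox neurite`,
`neurotox ddct`, `neurotox run`), with `neurotox run --config cfg.yaml`
executing the full simulate → detect → metrics → normalize → classify
pipeline and writing CSV/JSON outputs stamped with the configuration hash.

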