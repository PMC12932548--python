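# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic data do and do not emulate, and the known
limitations.

## MEA signal chain

**Acquisition model.** A plate is 24 wells × 16 extracellular electrodes
sampled at 12.5 kHz for 300 s (all configurable through `PlateLayout`).
Traces are in microvolts.

**Filtering.** The 200–3000 Hz acquisition band is realized as a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero phase and
effectively 8th order in magnitude. Zero phase matters because spike
timestamps are compared to ground truth at sub-millisecond tolerance. The
first and last 3 × order samples are excluded from detection as filter
transients.

**Adaptive threshold.** The detection threshold is 6 × the background-noise
SD, re-estimated per electrode in non-overlapping 1-second bins. The
estimator is the robust σ̂ = median(|x − median(x)|)/0.6745, which is
consistent for Gaussian noise and nearly unaffected by spikes occupying a
small fraction of a window (a plain SD would be inflated and cost recall on
active electrodes). Whether the original vendor software uses an RMS or a
robust estimator is not public; the robust choice is this package's
decision and is configurable via `DetectionSettings`.

**Event extraction.** A spike is a local extremum of |x| (polarity
configurable) that is the maximum of its ± dead-time neighbourhood
(1.5 ms) and exceeds the local threshold. Because the candidate set — the
window maxima — does not depend on the threshold, detections are
monotone in the multiplier: raising it can only remove events. This also
enforces the dead time exactly and merges multiphasic waveform lobes into
one event. Detections are invariant to positive rescaling of a trace
(threshold is relative) and electrodes are processed independently.
Electrodes whose noise SD stays below 0.01 µV are flagged dead and excluded
from metric denominators.

**Operating point.** At SNR 10 (50 µV peak template in 5 µV noise) the
measured recall is ≈ 0.998 at precision ≈ 1.0; on pure band-limited noise
the false-positive rate is ≈ 2·10⁻⁵ Hz per electrode (|N| > 6σ tail). The
residual misses are spikes within a dead time of a larger spike.

## Network metrics

* **MFR**: spikes/duration, exactly. The well-level convention divides the
  well's total spikes by (duration × active electrodes); a `well_total`
  mode (total/duration) is provided because figure conventions differ
  between vendors and papers. Both are recorded in provenance.
* **Bursts**: maximal runs of ≥ 5 spikes with all ISIs ≤ 0.1 s, found by a
  left-to-right scan over the ISI sequence, which provably enumerates the
  maximal runs (a run boundary is an ISI > 0.1 s, so greedy = maximal and
  bursts cannot overlap). `burst_frequency_avg` is the mean over bursting
  electrodes of bursts/duration.
* **Active electrodes**: MFR ≥ 5 spikes/min, a common MEA activity
  criterion; the threshold is a parameter.
* **Synchrony index**: the spike-time tiling coefficient (STTC) with
  coincidence half-width Δt = 50 ms, averaged over electrode pairs and
  clipped to [0, 1]. STTC was chosen over a cross-correlogram area ratio
  because it has the required behaviour at the extremes without tuning:
  identical trains give exactly 1, independent stationary trains
  concentrate near 0, and the index rises monotonically with the fraction
  of shared burst onsets. It is a documented stand-in with the same range
  and monotonicity as the vendor's synchrony metric, not a bit-exact clone
  (the vendor formula is not public).
* **NMI**: trains are binned at 50 ms and binarized; the multiinformation
  Σᵢ H(Xᵢ) − H(joint) is estimated with plug-in entropies over observed
  binary patterns and normalized by Σᵢ H(Xᵢ) − maxᵢ H(Xᵢ), which makes
  identical channels give exactly 1. Electrodes are capped at 12 (key
  order, deterministic) to keep the joint-pattern estimate tractable; at
  6000 bins the estimator's bias for independent channels is ≲ 0.02. A
  single electrode or silent well returns 0 by convention.

## Synthetic spike trains and voltage

Background activity is homogeneous Poisson per electrode (default 1 Hz).
Bursts arrive at 6/min with spike counts floored at 5 (so every generated
burst satisfies the burst rule) and intra-burst ISIs jittered around 20 ms,
clipped below 0.1 s. Synchrony uses a mother process: a well-level onset
train is copied to each electrode with probability = coupling (with 2 ms
jitter) plus independent onsets at the complementary rate, keeping the
per-electrode burst rate constant; the coupling is therefore a clean
monotone knob. Bursts are dropped if they would overlap the recording end
or start within 0.25 s of the previous burst on that electrode; the stored
truth lists exactly the committed bursts.

Voltage rendering places a canonical biphasic 1.2 ms template (dominant
negative trough, 45 % rebound) with its extremum at each spike sample;
overlapping spikes sum linearly, the simplest physical assumption. Noise is
white Gaussian band-limited to 200–3000 Hz and rescaled to the requested
SD, so the detector's noise estimator operates in the same regime as on
real filtered data. Real recordings additionally contain electrode drift,
waveform diversity across units, stimulation artifacts and non-stationary
noise — none of which are modelled, so passing tests demonstrate the
correctness of the chain's logic, not robustness to every real-world
artifact.

## Synthetic neuron images and morphometry

Images are two channels (nuclei: filled discs; marker: soma discs plus
neurite strokes) on a 512 × 512 lattice, 5 somas of radius 12 px by
default. Trees grow as straight ~45 px segments that bifurcate with
probability 0.35 up to depth 2, with child angles 0.55–0.85 rad off the
parent. Growth is collision-free by construction: a wide keep-out zone
around every soma (radius + 12 px) is impenetrable, committed strokes carry
a 3-px clearance, and candidate segments are truncated with a back-off so a
tip never lands adjacent to foreign structure; inside the branch
neighbourhood, where the clearance is suspended, candidates are still
checked from their first pixel against a 1-px-dilated occupancy map from
which only a 2-px sleeve around the parent is exempt. A bifurcation is
committed only if both children fit, so the stored tree always matches the
drawing; both sibling strokes are drawn before either subtree grows, so a
descendant always sees its uncle as an obstacle. The stored truth records
per-segment pixel-chain lengths (1 axial, √2 diagonal) and the tree
topology.

The analysis side thresholds the marker channel (Otsu), removes specks,
excludes detected soma interiors, skeletonizes, and builds a graph: the
8-connected pixel graph with the standard diagonal reduction (a diagonal
link is dropped when an axial common neighbour exists), vertex pixels
(endpoints, junctions, and pixels within 5 px of a soma) clustered into
typed vertices, and branch-free chains traced into edges. Junction pixels
merge when a skeleton path of ≤ 5 steps connects them — thinning can split
one true branch point into two nearby junction pixels, while genuine
vertices of different neurites are never short-path connected. Edges
leaving a root cluster are extended by the start pixel's distance to the
soma so lengths are measured from the soma boundary, compensating skeleton
retraction. Spur branches < 5 px are pruned, leftover degree-2 junctions
dissolved, and any remaining loop broken at the edge farthest from the
soma. "Segment" means a maximal branch-point-free path; aggregate
treated-vs-control comparisons are invariant to this convention.

On 400 generated images the four count phenotypes match the stored truth
exactly and both length phenotypes agree within ≈ 2 % on average (worst
image ≈ 5 %).

Real immunofluorescence differs in ways the generator does not attempt:
intensity inhomogeneity, touching cells and fasciculating neurites, debris,
out-of-focus light. Exact count recovery on synthetic images validates the
graph logic; on real images the segmentation parameters
(`MorphometryParams`) carry the burden.

## Statistics

Baseline normalization divides each (compound, dose, metric) series by its
0 h value; 0/0 is defined as 0 (complete, sustained suppression), x/0 with
x > 0 is flagged undefined and excluded with a warning. Classification uses
a ± 0.2 margin around 1.0 by default (configurable); trajectory labels join
the post-baseline calls in time order, collapsing repeats.

The group-testing chain is Shapiro–Wilk per group (n ≥ 3), Bartlett across
groups, one-way ANOVA, and Dunnett's two-sided many-to-one comparisons via
multivariate-t integration (scipy), with a fixed integration seed so
repeated runs are byte-identical. Normality or homogeneity failures are
reported as flags; ANOVA/Dunnett still run (the analysis does not silently
switch tests). All-constant data short-circuit to a `degenerate` status
with no significance claims. The measured family-wise type-I rate under
the null (4 groups × n = 4, 10 000 replicates) is ≈ 0.048.

A real MEA dose design often ends with a single well per dose group; with
n = 1 no formal test is possible and the pipeline reports descriptive
relatives only — the morphometric endpoint, with 4 replicate wells (9
images each) per group, is where the ANOVA/Dunnett layer applies.

ΔΔCt: ΔCt = Ct_target − Ct_reference per condition (replicates averaged),
ΔΔCt = ΔCt_sample − ΔCt_calibrator, reported as −ΔΔCt so positive values
mean enhanced expression; 2^(−ΔΔCt) is the fold change. The reference gene
defaults to β-actin (ACTB) and the calibrator to the first condition.

## Pipeline and formats

`neurotox run` simulates one compound across doses × {0, 24, 72} h (one
well per dose, mirroring the constrained MEA design), detects, computes
metrics, normalizes, classifies, and optionally adds the imaging arm with
replicate images per dose and relative-to-control phenotypes plus dose
tests. Outputs (spike CSVs, metric/relative CSVs, effect JSON, provenance
JSON) carry a 12-hex configuration hash; identical configurations reproduce
byte-identical files. Spike times are stored as decimal seconds with 6
fractional digits (1 µs, finer than the 80 µs sample grid); traces as HDF5
with one dataset per electrode under `/<well>/e<index>`; images as
2-channel TIFF with a JSON truth sidecar.

Default problem sizes (300-s wells for detector characterization, 50 images
for morphometric recovery, 10 000 null replicates for calibration, 3
replicate wells per timepoint for effect recovery) were chosen so each
check is statistically meaningful while a full verification run completes
in minutes on one CPU.

## Known limitations

* The synchrony index and NMI are faithful in range and monotonicity but
  are not numerically interchangeable with vendor metrics.
* Burst detection is per-electrode only; network bursts (cross-electrode
  coincident bursting) are out of scope.
* The generator draws planar, non-crossing trees; real neurite crossings
  produce graph ambiguities that this package resolves only by its cycle
  and spur heuristics.
* No spike sorting: all threshold crossings on an electrode form one train.
* Lengths are reported in pixels unless a pixel size is supplied; relative
  (treated/control) comparisons cancel the unit.
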