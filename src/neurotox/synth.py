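"""Synthetic MEA recordings and neuron images with exact ground truth.

Every downstream stage of the pipeline (spike detection, burst/synchrony
metrics, morphometry, dose-response statistics) is tested against data from
this module, because no public raw recordings exist for the assay design it
emulates. The generators therefore return both the observable (voltage
traces, two-channel images) and the generating truth (spike times, burst
intervals, neurite tree topology and lengths), and are bit-reproducible for
a fixed seed.

Spike trains are Poisson background plus bursty episodes. Cross-electrode
synchrony uses a "mother process": a well-level burst-onset train is copied
to each electrode with probability ``synchrony_coupling``, topped up with
independent onsets so the per-electrode burst rate stays constant. The
coupling is thus a monotone synchrony knob with fully shared onsets at 1 and
independent wells at 0.

Neuron images contain filled nuclei discs plus soma discs with branching
neurite trees drawn as thin strokes on the integer lattice; trees are grown
collision-free so that skeleton-based morphometry can in principle recover
the stored topology exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from skimage.draw import disk as _disk_px
from skimage.draw import line as _line_px
from skimage.morphology import dilation as _dilation
from skimage.morphology import disk

from .core import ElectrodeKey, PlateLayout, SpikeTrainSet, VoltageRecording

__all__ = [
    "SpikeTrainSpec",
    "WaveformTemplate",
    "MorphologySpec",
    "DoseEffectSpec",
    "GroundTruthBurst",
    "NeuronImage",
    "SegmentRecord",
    "SomaGroundTruth",
    "MorphologyGroundTruth",
    "biphasic_template",
    "generate_spike_trains",
    "render_voltage_trace",
    "generate_neuron_image",
    "apply_dose_effect",
]


# --------------------------------------------------------------------------
# Spike-train generation
# --------------------------------------------------------------------------

@dataclass
class SpikeTrainSpec:
    """Parameters of the Poisson-plus-burst spike train generator.

    Rates are per electrode. ``intra_burst_isi`` is the nominal gap between
    spikes inside a burst (jittered multiplicatively, clipped below 0.1 s so
    generated bursts always satisfy the ISI burst criterion).
    """

    background_rate: float = 1.0          # Hz
    burst_rate: float = 6.0               # bursts / minute
    spikes_per_burst_mean: float = 8.0
    spikes_per_burst_dispersion: float = 2.0   # SD of the count distribution
    intra_burst_isi: float = 0.02         # s
    synchrony_coupling: float = 0.5       # in [0, 1]
    min_burst_gap: float = 0.25           # s, enforced per electrode
    onset_jitter: float = 0.002           # s, SD of shared-onset jitter
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("background_rate", "burst_rate", "spikes_per_burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.synchrony_coupling <= 1.0:
            raise ValueError("synchrony_coupling must be in [0, 1]")
        if self.intra_burst_isi <= 0:
            raise ValueError("intra_burst_isi must be > 0")


@dataclass(frozen=True)
class GroundTruthBurst:
    """One generated burst: electrode, extent and spike count."""

    well: str
    electrode: int
    start: float
    end: float
    n_spikes: int


def _draw_burst_size(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Spike count per burst: (negative-)binomial-like draw, floor 5.

    The floor guarantees every generated burst satisfies the >=5-spike
    burst criterion used downstream.
    """
    var = sd * sd
    if var <= mean or mean <= 0:
        n = rng.poisson(mean)
    else:  # over-dispersed: gamma-Poisson mixture
        shape = mean * mean / (var - mean)
        n = rng.poisson(rng.gamma(shape, (var - mean) / mean))
    return max(5, int(n))


def _burst_times(
    rng: np.random.Generator, onset: float, spec: SpikeTrainSpec
) -> np.ndarray:
    n = _draw_burst_size(rng, spec.spikes_per_burst_mean, spec.spikes_per_burst_dispersion)
    isis = spec.intra_burst_isi * rng.uniform(0.5, 1.5, size=n - 1)
    np.clip(isis, None, 0.099, out=isis)   # keep bursts detectable
    return onset + np.concatenate([[0.0], np.cumsum(isis)])


def generate_spike_trains(
    layout: PlateLayout,
    spec: SpikeTrainSpec,
    wells: list[str] | None = None,
) -> tuple[SpikeTrainSet, list[GroundTruthBurst]]:
    """Generate per-electrode spike trains plus ground-truth burst intervals.

    Returns a :class:`SpikeTrainSet` (sorted times in ``[0, duration]``) and
    the list of every generated burst. Bursts that would extend past the
    recording end, or start within ``min_burst_gap`` of the previous burst
    on the same electrode, are dropped (and not listed in the truth). The
    same seed reproduces the output bit-for-bit.
    """
    if layout.duration <= 0:
        raise ValueError("layout duration must be positive")
    rng = np.random.default_rng(spec.seed)
    wells = list(wells) if wells is not None else layout.wells
    dur = layout.duration
    c = spec.synchrony_coupling
    mother_rate = spec.burst_rate / 60.0  # Hz

    trains: dict[ElectrodeKey, np.ndarray] = {}
    truth: list[GroundTruthBurst] = []
    for well in wells:
        n_mother = rng.poisson(mother_rate * dur)
        mother = np.sort(rng.uniform(0.0, dur, size=n_mother))
        for e in range(layout.electrodes_per_well):
            shared = mother[rng.random(n_mother) < c] if n_mother else np.empty(0)
            if spec.onset_jitter > 0 and shared.size:
                shared = shared + rng.normal(0.0, spec.onset_jitter, size=shared.size)
            n_indep = rng.poisson((1.0 - c) * mother_rate * dur)
            onsets = np.sort(np.concatenate([shared, rng.uniform(0.0, dur, n_indep)]))

            spikes: list[np.ndarray] = []
            last_end = -np.inf
            for onset in onsets:
                if onset < 0 or onset - last_end < spec.min_burst_gap:
                    continue
                t = _burst_times(rng, onset, spec)
                if t[-1] > dur:
                    continue
                spikes.append(t)
                truth.append(
                    GroundTruthBurst(well, e, float(t[0]), float(t[-1]), t.size)
                )
                last_end = t[-1]
            n_bg = rng.poisson(spec.background_rate * dur)
            if n_bg:
                spikes.append(rng.uniform(0.0, dur, size=n_bg))
            all_t = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
            trains[(well, e)] = all_t

    sts = SpikeTrainSet(
        trains=trains,
        duration=dur,
        provenance={"generator": "poisson+burst", "spec": dataclasses.asdict(spec)},
    )
    return sts, truth


# --------------------------------------------------------------------------
# Voltage rendering
# --------------------------------------------------------------------------

@dataclass
class WaveformTemplate:
    """Sampled extracellular spike waveform (microvolts).

    Must be short (<= 3 ms) with a single dominant extremum so that one
    template insertion corresponds to one detectable event.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.duration > 3e-3 + 1e-12:
            raise ValueError("template duration must be <= 3 ms")
        a = np.abs(self.samples)
        order = np.argsort(a)
        if a[order[-1]] <= 0:
            raise ValueError("template must be non-zero")
        # dominant extremum: runner-up outside the peak's immediate lobe
        peak = order[-1]
        away = a[np.abs(np.arange(a.size) - peak) > max(2, a.size // 10)]
        if away.size and away.max() >= a[peak]:
            raise ValueError("template must have a single dominant extremum")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def peak_amplitude(self) -> float:
        return float(np.abs(self.samples).max())

    @property
    def peak_index(self) -> int:
        return int(np.abs(self.samples).argmax())


def biphasic_template(
    sampling_rate: float = 12500.0,
    peak_amplitude: float = 100.0,
    duration: float = 1.2e-3,
) -> WaveformTemplate:
    """Canonical biphasic waveform: sharp negative trough, smaller rebound."""
    n = max(4, int(round(duration * sampling_rate)))
    t = np.arange(n) / (n - 1)
    w = -np.exp(-((t - 0.35) ** 2) / (2 * 0.09**2)) + 0.45 * np.exp(
        -((t - 0.72) ** 2) / (2 * 0.14**2)
    )
    w *= peak_amplitude / np.abs(w).max()
    return WaveformTemplate(samples=w, sampling_rate=sampling_rate)


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    sampling_rate: float,
    sd: float,
    band: tuple[float, float] = (200.0, 3000.0),
) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to the acquisition band.

    White noise is band-pass filtered (4th-order Butterworth, zero phase)
    and rescaled to the requested standard deviation, so detector noise
    estimates behave as on real filtered data.
    """
    if sd == 0:
        return np.zeros(n_samples)
    sos = _signal.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    x = _signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x * (sd / x.std())


def render_voltage_trace(
    trains: SpikeTrainSet,
    template: WaveformTemplate,
    noise_sd: float,
    seed: int = 0,
    layout: PlateLayout | None = None,
) -> VoltageRecording:
    """Render spike trains into voltage traces: template + band-limited noise.

    The template's dominant extremum is placed at each spike's sample index;
    overlapping spikes sum linearly. ``noise_sd`` is the per-sample standard
    deviation of the additive band-limited Gaussian noise in microvolts.
    """
    if template.peak_amplitude <= 0:
        raise ValueError("template peak amplitude must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fs = template.sampling_rate
    n = int(round(fs * trains.duration))
    rng = np.random.default_rng(seed)
    electrodes = list(trains.trains)
    data = np.zeros((len(electrodes), n))
    tmpl = template.samples
    pk = template.peak_index
    for i, key in enumerate(electrodes):
        if noise_sd > 0:
            data[i] = band_limited_noise(rng, n, fs, noise_sd)
        for t in trains.trains[key]:
            if t < 0 or t > trains.duration:
                raise ValueError(f"spike time {t} outside recording for {key}")
            idx = int(round(t * fs))
            lo, hi = idx - pk, idx - pk + tmpl.size
            s0, s1 = max(lo, 0), min(hi, n)
            data[i, s0:s1] += tmpl[s0 - lo : s1 - lo]
    return VoltageRecording(
        data=data,
        electrodes=electrodes,
        sampling_rate=fs,
        duration=trains.duration,
        layout=layout,
    )


# --------------------------------------------------------------------------
# Neuron image generation
# --------------------------------------------------------------------------

@dataclass
class MorphologySpec:
    """Parameters of the synthetic neuron-image generator."""

    n_somas: int = 5
    soma_radius: int = 12
    neurites_mean: float = 3.0
    neurites_max: int = 5
    branch_probability: float = 0.35
    max_branch_depth: int = 2
    segment_length_mean: float = 45.0
    segment_length_sd: float = 10.0
    image_size: tuple[int, int] = (512, 512)
    marker_positive_fraction: float = 1.0
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_somas < 0:
            raise ValueError("n_somas must be >= 0")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        h, w = self.image_size
        if min(h, w) < 6 * self.soma_radius:
            raise ValueError("image too small to contain somas at stated radius")


@dataclass(frozen=True)
class SegmentRecord:
    """One branch-free neurite path in the generative tree.

    ``parent`` is the index of the parent segment within the same soma's
    tree, or -1 for a root segment (attached to the soma). ``length`` is the
    geodesic pixel-chain length (1 per axial step, sqrt(2) per diagonal).
    """

    index: int
    parent: int
    length: float
    depth: int
    is_leaf: bool


@dataclass
class SomaGroundTruth:
    center: tuple[int, int]
    radius: int
    marker_positive: bool
    segments: list[SegmentRecord]

    @property
    def n_roots(self) -> int:
        return sum(1 for s in self.segments if s.parent == -1)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_extremities(self) -> int:
        return sum(1 for s in self.segments if s.is_leaf)

    @property
    def n_nodes(self) -> int:
        # every internal segment end is a bifurcation with exactly 2 children
        return sum(1 for s in self.segments if not s.is_leaf)

    @property
    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    @property
    def max_length(self) -> float:
        """Longest root-to-extremity geodesic in the tree."""
        if not self.segments:
            return 0.0
        cum = {}
        for s in self.segments:  # parents precede children by construction
            cum[s.index] = s.length + (cum[s.parent] if s.parent >= 0 else 0.0)
        leaves = [cum[s.index] for s in self.segments if s.is_leaf]
        return float(max(leaves)) if leaves else 0.0


@dataclass
class MorphologyGroundTruth:
    somas: list[SomaGroundTruth]
    image_size: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "image_size": list(self.image_size),
            "somas": [
                {
                    "center": list(s.center),
                    "radius": s.radius,
                    "marker_positive": s.marker_positive,
                    "segments": [dataclasses.asdict(seg) for seg in s.segments],
                }
                for s in self.somas
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MorphologyGroundTruth":
        return cls(
            somas=[
                SomaGroundTruth(
                    center=tuple(s["center"]),
                    radius=s["radius"],
                    marker_positive=s["marker_positive"],
                    segments=[SegmentRecord(**seg) for seg in s["segments"]],
                )
                for s in d["somas"]
            ],
            image_size=tuple(d["image_size"]),
        )


@dataclass
class NeuronImage:
    """Two-channel fluorescence image: nuclei + neurite marker."""

    nuclei: np.ndarray
    marker: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.nuclei.shape != self.marker.shape:
            raise ValueError("channels must share shape")


_NUCLEUS_VALUE = 200.0
_SOMA_VALUE = 180.0
_STROKE_VALUE = 120.0


def _chain_length(rr: np.ndarray, cc: np.ndarray) -> float:
    """Geodesic length of a pixel chain: 1 per axial, sqrt(2) per diagonal."""
    if rr.size < 2:
        return 0.0
    dr = np.abs(np.diff(rr))
    dc = np.abs(np.diff(cc))
    return float(np.sum(np.where((dr == 1) & (dc == 1), np.sqrt(2.0), 1.0)))


def _probe_segment(
    start: tuple[float, float],
    angle: float,
    length: float,
    blocked: np.ndarray,
    shape: tuple[int, int],
    free_run: int = 10,
    occupied: np.ndarray | None = None,
    strict_run: int = 4,
    occupied_near: np.ndarray | None = None,
    near_run: int = 7,
    hard: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham pixel chain from start along angle, truncated at collisions.

    The first ``free_run`` pixels ignore the clearance (``blocked``) mask:
    they sit next to the parent structure. Actual drawn structure
    (``occupied``) still truncates the chain after ``strict_run`` pixels, so
    a branch can start close to its parent but can never cross another
    stroke. The ``hard`` mask (keep-out zones around somas) is honoured from
    the very first pixel, so no free run can carry a stroke into a soma's
    root zone. Returns (rows, cols), possibly empty.
    """
    r0, c0 = start
    r1 = r0 + length * np.sin(angle)
    c1 = c0 + length * np.cos(angle)
    h, w = shape
    rr, cc = _line_px(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    inb = (rr >= 2) & (rr < h - 2) & (cc >= 2) & (cc < w - 2)
    stop = np.argmin(inb) if not inb.all() else rr.size
    rr, cc = rr[:stop], cc[:stop]
    if rr.size > free_run:
        hit = blocked[rr[free_run:], cc[free_run:]]
        if hit.any():
            # back off from the clearance zone so children spawned at a
            # truncated tip cannot cross the foreign stroke in their first,
            # collision-exempt pixels
            stop = free_run + max(0, int(np.argmax(hit)) - 4)
            rr, cc = rr[:stop], cc[:stop]
    if occupied is not None and rr.size > strict_run:
        hit = occupied[rr[strict_run:], cc[strict_run:]]
        if hit.any():
            # back off so the truncated tip never touches the structure it
            # collided with (stroke thickening would otherwise fuse them)
            stop = max(0, strict_run + int(np.argmax(hit)) - 5)
            rr, cc = rr[:stop], cc[:stop]
    if occupied_near is not None and rr.size > near_run:
        # inside the free run the wide clearance mask is suspended, but a
        # stroke must still not pass immediately beside existing structure
        hit = occupied_near[rr[near_run:], cc[near_run:]]
        if hit.any():
            stop = max(0, near_run + int(np.argmax(hit)) - 5)
            rr, cc = rr[:stop], cc[:stop]
    if hard is not None and rr.size:
        hit = hard[rr, cc]
        if hit.any():
            stop = int(np.argmax(hit))
            rr, cc = rr[:stop], cc[:stop]
    return rr, cc


def generate_neuron_image(
    spec: MorphologySpec,
    max_soma_attempts: int = 2000,
) -> tuple[NeuronImage, MorphologyGroundTruth]:
    """Generate a two-channel neuron image plus its morphology ground truth.

    Nuclei channel: filled discs at soma centres. Marker channel: soma discs
    plus branching neurite trees drawn as ~3-px strokes. Trees are grown with
    collision avoidance (no crossings between neurites or somas), bifurcate
    with ``branch_probability`` at segment ends up to ``max_branch_depth``,
    and the stored truth lists every committed segment with its pixel-chain
    length. Somas that cannot be placed without overlap raise ``ValueError``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    nuclei = np.zeros((h, w), dtype=np.float32)
    marker = np.zeros((h, w), dtype=np.float32)
    r_soma = spec.soma_radius

    # --- place somas, rejection-sampled for separation
    centers: list[tuple[int, int]] = []
    min_sep = 4.5 * r_soma
    margin = int(2.0 * r_soma) + 4
    attempts = 0
    while len(centers) < spec.n_somas:
        attempts += 1
        if attempts > max_soma_attempts:
            raise ValueError("could not place somas without overlap")
        cand = (
            int(rng.integers(margin, h - margin)),
            int(rng.integers(margin, w - margin)),
        )
        if all(np.hypot(cand[0] - r, cand[1] - c) >= min_sep for r, c in centers):
            centers.append(cand)

    n_pos = int(round(spec.marker_positive_fraction * spec.n_somas))
    positive = np.zeros(spec.n_somas, dtype=bool)
    positive[:n_pos] = True  # soma order is already random

    # blocked mask: structure other neurites must not approach; the wide
    # zone around each soma keeps foreign strokes out of its root zone and
    # is also stored as a labelled keep-out map honoured without free-run
    blocked = np.zeros((h, w), dtype=bool)
    zones = np.zeros((h, w), dtype=np.int32)
    for i, (r, c) in enumerate(centers, start=1):
        rr, cc = _disk_px((r, c), r_soma + 12, shape=(h, w))
        blocked[rr, cc] = True
        zones[rr, cc] = i

    somas: list[SomaGroundTruth] = []
    grow_disk = disk(3)  # clearance added around committed strokes
    for i, (r, c) in enumerate(centers):
        rr, cc = _disk_px((r, c), max(2, int(0.6 * r_soma)), shape=(h, w))
        nuclei[rr, cc] = _NUCLEUS_VALUE
        segs: list[SegmentRecord] = []
        if positive[i]:
            rr, cc = _disk_px((r, c), r_soma, shape=(h, w))
            marker[rr, cc] = _SOMA_VALUE
            segs = _grow_tree(
                rng, spec, (r, c), marker, blocked, grow_disk,
                zones=zones, own_zone=i + 1,
            )
        somas.append(
            SomaGroundTruth(
                center=(r, c), radius=r_soma, marker_positive=bool(positive[i]),
                segments=segs,
            )
        )
    return (
        NeuronImage(nuclei=nuclei, marker=marker),
        MorphologyGroundTruth(somas=somas, image_size=(h, w)),
    )


def _commit_stroke(
    marker: np.ndarray, blocked: np.ndarray, rr: np.ndarray, cc: np.ndarray,
    grow_disk: np.ndarray,
) -> None:
    stroke = np.zeros(marker.shape, dtype=bool)
    stroke[rr, cc] = True
    thick = _dilation(stroke, footprint=np.ones((2, 2), dtype=bool))
    marker[thick] = np.maximum(marker[thick], _STROKE_VALUE)
    blocked |= _dilation(stroke, footprint=grow_disk)


def _grow_tree(
    rng: np.random.Generator,
    spec: MorphologySpec,
    center: tuple[int, int],
    marker: np.ndarray,
    blocked: np.ndarray,
    grow_disk: np.ndarray,
    zones: np.ndarray,
    own_zone: int,
) -> list[SegmentRecord]:
    """Grow one soma's neurite trees; draws strokes, returns segment records."""
    h, w = marker.shape
    r0, c0 = center
    k = int(np.clip(rng.poisson(spec.neurites_mean), 0, spec.neurites_max))
    # attachment angles with minimum separation so roots stay resolvable
    angles: list[float] = []
    for _ in range(40):
        if len(angles) >= k:
            break
        a = rng.uniform(0, 2 * np.pi)
        if all(
            min(abs(a - b), 2 * np.pi - abs(a - b)) > 0.8 for b in angles
        ):
            angles.append(a)

    segs: list[SegmentRecord] = []
    min_len_px = 14
    hard_other = (zones > 0) & (zones != own_zone)
    hard_all = zones > 0

    def draw_len() -> float:
        return float(
            np.clip(rng.normal(spec.segment_length_mean, spec.segment_length_sd),
                    18.0, None)
        )

    def place(rr: np.ndarray, cc: np.ndarray, depth: int, parent: int) -> int:
        idx = len(segs)
        segs.append(SegmentRecord(idx, parent, _chain_length(rr, cc), depth, True))
        _commit_stroke(marker, blocked, rr, cc, grow_disk)
        return idx

    def _near_mask(allow_rr: np.ndarray, allow_cc: np.ndarray) -> np.ndarray:
        """Adjacency keep-out: everything drawn, dilated by 1 px, except a
        2-px sleeve around the parent structure a new branch grows from.

        Committed strokes keep >= 3 px clearance from foreign structure, so
        nothing foreign can hide inside the sleeve — a probe checked against
        this mask from its first pixel can touch its parent but nothing else.
        """
        occ_near = _dilation(marker > 0, footprint=np.ones((3, 3), dtype=bool))
        allow = np.zeros((h, w), dtype=bool)
        allow[allow_rr, allow_cc] = True
        occ_near &= ~_dilation(allow, footprint=disk(2))
        return occ_near

    def maybe_branch(idx: int, tail: tuple[np.ndarray, np.ndarray],
                     angle: float, depth: int) -> None:
        """Possibly bifurcate at a committed segment's end.

        Children are probed against the current masks *together*: either
        both are committed (the end becomes a node) or neither (it stays an
        extremity), so the stored tree always matches the drawing. Both
        child strokes are drawn before either subtree grows further, so a
        later descendant always sees its uncle's stroke as an obstacle.
        """
        if depth >= spec.max_branch_depth or rng.random() >= spec.branch_probability:
            return
        end = (float(tail[0][-1]), float(tail[1][-1]))
        spread = rng.uniform(0.55, 0.85)
        drift = rng.uniform(-0.1, 0.1)
        a1, a2 = angle + drift + spread, angle + drift - spread
        occ = marker > 0
        occ_near = _near_mask(tail[0][-8:], tail[1][-8:])
        p1 = _probe_segment(end, a1, draw_len(), blocked, (h, w), occupied=occ,
                            occupied_near=occ_near, near_run=1, hard=hard_all)
        p2 = _probe_segment(end, a2, draw_len(), blocked, (h, w), occupied=occ,
                            occupied_near=occ_near, near_run=1, hard=hard_all)
        if p1[0].size >= min_len_px and p2[0].size >= min_len_px:
            segs[idx] = dataclasses.replace(segs[idx], is_leaf=False)
            i1 = place(*p1, depth + 1, idx)
            i2 = place(*p2, depth + 1, idx)
            maybe_branch(i1, p1, a1, depth + 1)
            maybe_branch(i2, p2, a2, depth + 1)

    def ang_sep(a: float, b: float) -> float:
        d = abs(a - b) % (2 * np.pi)
        return min(d, 2 * np.pi - d)

    used: list[float] = []
    for a in angles:
        for _ in range(8):  # retry a few angles if blocked
            if all(ang_sep(a, u) > 0.8 for u in used):
                start = (r0 + (spec.soma_radius + 1) * np.sin(a),
                         c0 + (spec.soma_radius + 1) * np.cos(a))
                soma_rr, soma_cc = _disk_px((r0, c0), spec.soma_radius, shape=(h, w))
                rr, cc = _probe_segment(
                    start, a, draw_len(), blocked, (h, w), occupied=marker > 0,
                    occupied_near=_near_mask(soma_rr, soma_cc), near_run=1,
                    hard=hard_other,
                )
                if rr.size >= min_len_px:
                    idx = place(rr, cc, 0, -1)
                    maybe_branch(idx, (rr, cc), a, 0)
                    used.append(a)
                    break
            a = rng.uniform(0, 2 * np.pi)
    return segs


# --------------------------------------------------------------------------
# Dose-effect scenarios
# --------------------------------------------------------------------------

@dataclass
class DoseEffectSpec:
    """Multiplicative concentration- and time-dependent effect on activity
    or morphology parameters.

    ``factors`` maps ``(dose, timepoint_h)`` to a multiplier applied to the
    generator's rate (spike trains) or length (morphology) parameters.
    Factors > 1 are excitatory, < 1 inhibitory; dose 0 and timepoint 0 h
    must be unaffected (factor 1).
    """

    factors: dict[tuple[float, float], float]

    def __post_init__(self) -> None:
        for key, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {key} must be > 0")
            dose, tp = key
            if (dose == 0 or tp == 0) and abs(f - 1.0) > 1e-12:
                raise ValueError(
                    f"factor at dose 0 / timepoint 0 h must be 1.0, got {f} for {key}"
                )

    def factor(self, dose: float, timepoint: float) -> float:
        try:
            return self.factors[(dose, timepoint)]
        except KeyError:
            raise KeyError(
                f"no effect factor defined for dose={dose}, timepoint={timepoint}"
            ) from None


def apply_dose_effect(
    base: SpikeTrainSpec | MorphologySpec,
    effect: DoseEffectSpec,
    dose: float,
    timepoint: float,
):
    """Scale a generator spec by the effect factor for (dose, timepoint).

    Spike-train specs have their rates scaled; morphology specs their
    segment lengths. The applied factor is recorded in the returned spec's
    provenance.
    """
    f = effect.factor(dose, timepoint)
    prov = dict(base.provenance)
    prov["dose_effect"] = {"dose": dose, "timepoint": timepoint, "factor": f}
    if isinstance(base, SpikeTrainSpec):
        return dataclasses.replace(
            base,
            background_rate=base.background_rate * f,
            burst_rate=base.burst_rate * f,
            provenance=prov,
        )
    if isinstance(base, MorphologySpec):
        return dataclasses.replace(
            base,
            segment_length_mean=base.segment_length_mean * f,
            segment_length_sd=base.segment_length_sd * f,
            provenance=prov,
        )
    raise TypeError(f"unsupported spec type: {type(base).__name__}")
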