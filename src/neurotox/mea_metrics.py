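"""Per-electrode and per-well network activity metrics from spike trains.

Metrics follow the conventions of multi-well MEA neurotoxicity screening:

* Mean firing rate (MFR): spikes / analysis duration, in Hz.
* Electrode bursts by the ISI-threshold rule: a burst is a maximal run of
  at least 5 spikes on one electrode with every inter-spike interval no
  larger than 0.1 s. The well-level Number of Bursts is the total across
  electrodes.
* Active electrodes: electrodes firing at >= 5 spikes/min (a common MEA
  activity criterion).
* Synchrony index in [0, 1]: the spike-time tiling coefficient (STTC)
  averaged over electrode pairs and clipped at 0. Identical trains give 1,
  independent stationary trains give ~0, and the index rises monotonically
  with shared burst timing.
* Normalized multiinformation (NMI): total correlation of the binarized
  binned trains, (sum_i H(X_i) - H(X_joint)) / (sum_i H(X_i) - max_i H(X_i)),
  with plug-in entropies; 1 for identical channels, ~0 for independent ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ElectrodeKey, SpikeTrainSet

__all__ = [
    "BurstSettings",
    "Burst",
    "SynchronySettings",
    "WellMetrics",
    "mean_firing_rate",
    "detect_bursts_isi",
    "well_burst_stats",
    "active_electrodes",
    "sttc_pair",
    "synchrony_index",
    "normalized_multiinformation",
    "compute_well_metrics",
]

logger = logging.getLogger(__name__)

#: Default activity criterion: 5 spikes per minute.
DEFAULT_ACTIVE_RATE = 5.0 / 60.0


@dataclass(frozen=True)
class BurstSettings:
    """ISI-threshold burst rule: >= ``min_spikes`` spikes, all ISIs <= ``max_isi``."""

    min_spikes: int = 5
    max_isi: float = 0.1

    def __post_init__(self) -> None:
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.max_isi <= 0:
            raise ValueError("max_isi must be > 0")


@dataclass(frozen=True)
class Burst:
    """One electrode burst: interval extent and spike count."""

    electrode: ElectrodeKey | None
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class SynchronySettings:
    """Synchrony parameters.

    ``cross_correlation_window`` is the coincidence half-width (seconds) of
    the tiling coefficient; ``bin`` is the discretisation used by binned
    measures (NMI binarization).
    """

    cross_correlation_window: float = 0.05
    bin: float = 0.01

    def __post_init__(self) -> None:
        if not self.cross_correlation_window > self.bin > 0:
            raise ValueError("need window > bin > 0")


@dataclass
class WellMetrics:
    """The per-well network metric panel."""

    well: str
    number_of_spikes: int
    mean_firing_rate: float
    number_of_bursts: int
    burst_frequency_avg: float
    n_active_electrodes: int
    synchrony_index: float
    nmi: float | None = None
    duration: float = 0.0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "well": self.well,
            "number_of_spikes": self.number_of_spikes,
            "mean_firing_rate": self.mean_firing_rate,
            "number_of_bursts": self.number_of_bursts,
            "burst_frequency_avg": self.burst_frequency_avg,
            "n_active_electrodes": self.n_active_electrodes,
            "synchrony_index": self.synchrony_index,
            "nmi": self.nmi,
            "duration": self.duration,
        }


def mean_firing_rate(
    spikes: np.ndarray, interval: tuple[float, float]
) -> float:
    """Spike count inside ``interval`` divided by its duration (Hz)."""
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval duration must be > 0")
    spikes = np.asarray(spikes, dtype=float)
    n = int(np.count_nonzero((spikes >= t0) & (spikes <= t1)))
    return n / (t1 - t0)


def detect_bursts_isi(
    spikes: np.ndarray,
    settings: BurstSettings | None = None,
    electrode: ElectrodeKey | None = None,
) -> list[Burst]:
    """Detect electrode bursts with the ISI-threshold rule.

    A burst is a *maximal* run of consecutive spikes whose ISIs are all
    <= ``max_isi`` and which contains >= ``min_spikes`` spikes. Runs are
    found by a left-to-right scan, which provably yields exactly the
    maximal runs; bursts never overlap.
    """
    settings = settings or BurstSettings()
    t = np.asarray(spikes, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike timestamps must be sorted ascending")
    if t.size < settings.min_spikes:
        return []
    ok = np.diff(t) <= settings.max_isi
    # run boundaries over the ISI sequence
    edges = np.diff(ok.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if ok[0]:
        starts = np.concatenate([[0], starts])
    if ok[-1]:
        ends = np.concatenate([ends, [ok.size]])
    bursts = []
    for s, e in zip(starts, ends):
        n = e - s + 1  # spikes in the run spanning ISIs [s, e)
        if n >= settings.min_spikes:
            bursts.append(Burst(electrode, float(t[s]), float(t[e]), int(n)))
    return bursts


def well_burst_stats(
    trains: SpikeTrainSet | dict[ElectrodeKey, np.ndarray],
    settings: BurstSettings | None = None,
    duration: float | None = None,
) -> tuple[int, float]:
    """Well-level burst summary.

    Returns ``(number_of_bursts, burst_frequency_avg)``: the total count of
    single-electrode bursts across the well, and the mean over *bursting*
    electrodes of bursts/duration (Hz); ``(0, 0.0)`` for a burst-free well.
    """
    if isinstance(trains, SpikeTrainSet):
        mapping, duration = trains.trains, trains.duration
    else:
        mapping = trains
        if duration is None:
            raise ValueError("duration required when passing a plain mapping")
    counts = [
        len(detect_bursts_isi(t, settings, electrode=k)) for k, t in mapping.items()
    ]
    total = int(sum(counts))
    bursting = [c for c in counts if c > 0]
    freq = float(np.mean(bursting) / duration) if bursting else 0.0
    return total, freq


def active_electrodes(
    trains: SpikeTrainSet | dict[ElectrodeKey, np.ndarray],
    min_rate: float = DEFAULT_ACTIVE_RATE,
    duration: float | None = None,
) -> int:
    """Count electrodes with MFR >= ``min_rate`` (default 5 spikes/min)."""
    if isinstance(trains, SpikeTrainSet):
        mapping, duration = trains.trains, trains.duration
    else:
        mapping = trains
        if duration is None:
            raise ValueError("duration required when passing a plain mapping")
    return int(sum(1 for t in mapping.values() if t.size / duration >= min_rate))


# --------------------------------------------------------------------------
# Synchrony
# --------------------------------------------------------------------------

def _tiled_fraction(t: np.ndarray, dt: float, duration: float) -> float:
    """Fraction of the recording lying within +-dt of any spike of t."""
    if t.size == 0:
        return 0.0
    # union of sorted tiles [t-dt, t+dt]: overlaps merge via min(gap, 2dt);
    # only the first/last tile can be clipped by the recording boundary
    total = float(np.sum(np.minimum(np.diff(t), 2 * dt))) + 2 * dt
    total -= max(0.0, dt - t[0]) + max(0.0, t[-1] + dt - duration)
    return min(1.0, total / duration)


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in ``a`` with a spike of ``b`` within +-dt."""
    idx = np.searchsorted(b, a)
    left = np.abs(a - b[np.clip(idx - 1, 0, b.size - 1)])
    right = np.abs(b[np.clip(idx, 0, b.size - 1)] - a)
    return float(np.mean(np.minimum(left, right) <= dt))


def sttc_pair(
    a: np.ndarray, b: np.ndarray, dt: float, duration: float
) -> float:
    """Spike-time tiling coefficient of two spike trains.

    ``0.5 * ((Pa - Tb)/(1 - Pa*Tb) + (Pb - Ta)/(1 - Pb*Ta))`` where ``Tx``
    is the tiled fraction of the recording and ``Px`` the proportion of
    coincident spikes. Degenerate terms (denominator ~0, i.e. a train tiling
    the whole recording) are dropped.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        return 0.0
    ta = _tiled_fraction(a, dt, duration)
    tb = _tiled_fraction(b, dt, duration)
    pa = _prop_within(a, b, dt)
    pb = _prop_within(b, a, dt)
    terms = []
    for p, t in ((pa, tb), (pb, ta)):
        den = 1.0 - p * t
        if den > 1e-12:
            terms.append((p - t) / den)
        elif p >= 1.0 - 1e-12:
            terms.append(1.0)
    return float(np.mean(terms)) if terms else 0.0


def synchrony_index(
    trains: SpikeTrainSet | dict[ElectrodeKey, np.ndarray],
    settings: SynchronySettings | None = None,
    duration: float | None = None,
) -> float:
    """Pairwise synchrony in [0, 1]: mean STTC over electrode pairs, clipped.

    Needs at least two non-empty electrodes; otherwise 0 is returned with a
    warning. Invariant to a common time shift of all trains (up to boundary
    effects) and deterministic for fixed input.
    """
    settings = settings or SynchronySettings()
    if isinstance(trains, SpikeTrainSet):
        mapping, duration = trains.trains, trains.duration
    else:
        mapping = trains
        if duration is None:
            raise ValueError("duration required when passing a plain mapping")
    trs = [np.asarray(t, float) for t in mapping.values() if np.asarray(t).size > 0]
    if len(trs) < 2:
        logger.warning("synchrony_index: fewer than 2 active electrodes; returning 0")
        return 0.0
    dt = settings.cross_correlation_window
    vals = [
        sttc_pair(trs[i], trs[j], dt, duration)
        for i in range(len(trs))
        for j in range(i + 1, len(trs))
    ]
    return float(np.clip(np.mean(vals), 0.0, 1.0))


# --------------------------------------------------------------------------
# Normalized multiinformation
# --------------------------------------------------------------------------

def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def normalized_multiinformation(
    trains: SpikeTrainSet | dict[ElectrodeKey, np.ndarray],
    bin: float = 0.05,
    max_electrodes: int = 12,
    duration: float | None = None,
) -> float:
    """NMI of the binarized binned trains, in [0, 1].

    Trains are binned at ``bin`` seconds and binarized (any spike -> 1).
    The multiinformation sum_i H(X_i) - H(joint) is estimated with plug-in
    entropies over observed binary patterns and normalised by
    sum_i H(X_i) - max_i H(X_i), so identical channels give exactly 1 and
    independent channels give ~0. Electrodes beyond ``max_electrodes`` are
    dropped (deterministically, in key order) to keep the joint-pattern
    estimate tractable; a single electrode or silent well returns 0.
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    if isinstance(trains, SpikeTrainSet):
        mapping, duration = trains.trains, trains.duration
    else:
        mapping = trains
        if duration is None:
            raise ValueError("duration required when passing a plain mapping")
    keys = list(mapping)[:max_electrodes]
    if len(keys) < 2:
        return 0.0
    n_bins = max(1, int(np.floor(duration / bin)))
    mat = np.zeros((len(keys), n_bins), dtype=np.uint64)
    for i, k in enumerate(keys):
        t = np.asarray(mapping[k], float)
        idx = np.clip((t / bin).astype(int), 0, n_bins - 1)
        mat[i, idx] = 1
    h_marg = np.array(
        [_entropy_bits(np.bincount(row.astype(int), minlength=2)) for row in mat]
    )
    if np.count_nonzero(h_marg) == 0:
        return 0.0
    # pack each time bin's binary pattern into one integer
    weights = (np.uint64(1) << np.arange(len(keys), dtype=np.uint64))[:, None]
    codes = (mat * weights).sum(axis=0)
    _, counts = np.unique(codes, return_counts=True)
    h_joint = _entropy_bits(counts)
    denom = h_marg.sum() - h_marg.max()
    if denom <= 0:
        return 0.0
    return float(np.clip((h_marg.sum() - h_joint) / denom, 0.0, 1.0))


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

def compute_well_metrics(
    trains: SpikeTrainSet,
    well: str | None = None,
    burst_settings: BurstSettings | None = None,
    synchrony_settings: SynchronySettings | None = None,
    nmi_bin: float = 0.05,
    nmi_max_electrodes: int = 12,
    active_rate: float = DEFAULT_ACTIVE_RATE,
    mfr_mode: str = "per_active_electrode",
    compute_nmi: bool = True,
) -> WellMetrics:
    """Assemble the full per-well metric panel.

    ``mfr_mode`` selects the well-level MFR convention: the default
    ``per_active_electrode`` divides total spikes by duration x active
    electrodes (0 if no electrode is active); ``well_total`` divides by
    duration only. All component settings are recorded in the provenance.
    """
    if mfr_mode not in ("per_active_electrode", "well_total"):
        raise ValueError(f"unknown mfr_mode {mfr_mode!r}")
    sts = trains.subset(well) if well is not None else trains
    well_name = well if well is not None else (sts.wells[0] if sts.wells else "")
    duration = sts.duration
    bset = burst_settings or BurstSettings()
    sset = synchrony_settings or SynchronySettings()

    n_spikes = sts.n_spikes()
    n_active = active_electrodes(sts, min_rate=active_rate)
    if mfr_mode == "per_active_electrode":
        mfr = n_spikes / (duration * n_active) if n_active else 0.0
    else:
        mfr = n_spikes / duration
    n_bursts, burst_freq = well_burst_stats(sts, bset)
    sync = synchrony_index(sts, sset)
    nmi = (
        normalized_multiinformation(sts, bin=nmi_bin, max_electrodes=nmi_max_electrodes)
        if compute_nmi
        else None
    )
    return WellMetrics(
        well=well_name,
        number_of_spikes=n_spikes,
        mean_firing_rate=float(mfr),
        number_of_bursts=n_bursts,
        burst_frequency_avg=burst_freq,
        n_active_electrodes=n_active,
        synchrony_index=sync,
        nmi=nmi,
        duration=duration,
        provenance={
            "burst": {"min_spikes": bset.min_spikes, "max_isi": bset.max_isi},
            "synchrony": {
                "window": sset.cross_correlation_window, "bin": sset.bin,
            },
            "nmi": {"bin": nmi_bin, "max_electrodes": nmi_max_electrodes},
            "active_rate": active_rate,
            "mfr_mode": mfr_mode,
        },
    )
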