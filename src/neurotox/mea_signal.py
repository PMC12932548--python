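"""Raw voltage traces -> per-electrode spike timestamp trains.

The acquisition/detection chain mirrors standard multi-well MEA practice:
a 200-3000 Hz band-pass (4th-order Butterworth, applied forward-backward
for zero phase), followed by an adaptive amplitude threshold set at 6 times
the standard deviation of the background noise of each electrode, with the
noise level re-estimated in 1-second bins. The noise SD is estimated
robustly as ``median(|x|) / 0.6745`` so that the spikes themselves do not
inflate the estimate.

A spike is the extremum of ``|x|`` within a +-dead-time neighbourhood that
exceeds the local threshold; because the candidate set (local window maxima)
does not depend on the threshold, raising the threshold multiplier can only
remove detections, never add them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import ElectrodeKey, SpikeTrainSet, VoltageRecording

__all__ = [
    "FilterSettings",
    "DetectionSettings",
    "bandpass_filter",
    "estimate_noise_sd",
    "detect_spikes",
]

_ROBUST_SCALE = 0.6744897501960817  # Phi^-1(0.75): MAD -> SD for Gaussian noise


@dataclass(frozen=True)
class FilterSettings:
    """Band-pass filter band (Hz) and Butterworth order."""

    low_cut: float = 200.0
    high_cut: float = 3000.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high_cut >= sampling_rate / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz >= Nyquist {sampling_rate / 2} Hz"
            )

    def sos(self, sampling_rate: float) -> np.ndarray:
        self.validate_for(sampling_rate)
        return signal.butter(
            self.order, (self.low_cut, self.high_cut), btype="bandpass",
            fs=sampling_rate, output="sos",
        )


@dataclass(frozen=True)
class DetectionSettings:
    """Adaptive-threshold spike detection parameters.

    ``threshold_multiplier`` scales the per-window noise SD; ``noise_window``
    is the binning interval for the adaptive noise estimate; events closer
    than ``dead_time`` are merged to the larger extremum. Electrodes whose
    overall noise SD falls below ``dead_floor`` (microvolts) are flagged dead
    and excluded from metric denominators.
    """

    threshold_multiplier: float = 6.0
    noise_window: float = 1.0
    dead_time: float = 1.5e-3
    polarity: str = "both"  # both | negative | positive
    dead_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.dead_time <= 0:
            raise ValueError("dead_time must be > 0")
        if self.noise_window <= 0:
            raise ValueError("noise_window must be > 0")
        if self.polarity not in ("both", "negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def bandpass_filter(rec: VoltageRecording, settings: FilterSettings | None = None) -> VoltageRecording:
    """Zero-phase band-pass filter every electrode trace.

    Same length out as in; the DC component lies outside the pass band and
    is removed.
    """
    settings = settings or FilterSettings()
    sos = settings.sos(rec.sampling_rate)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return VoltageRecording(
        data=out,
        electrodes=list(rec.electrodes),
        sampling_rate=rec.sampling_rate,
        duration=rec.duration,
        layout=rec.layout,
    )


def estimate_noise_sd(
    trace: np.ndarray,
    sampling_rate: float,
    settings: DetectionSettings | None = None,
) -> np.ndarray:
    """Robust noise SD per non-overlapping window of ``noise_window`` seconds.

    Uses ``median(|x|)/0.6745``, which is consistent for the SD of Gaussian
    noise and nearly unaffected by sparse large spikes. A ragged final
    window shorter than half the nominal length is folded into the previous
    one. Returns one value per window; all zeros for a constant trace.
    """
    settings = settings or DetectionSettings()
    trace = np.asarray(trace, dtype=float)
    win = int(round(settings.noise_window * sampling_rate))
    if win < 100:
        raise ValueError("noise window must contain at least 100 samples")
    n = trace.size
    n_win = max(1, n // win)
    sds = np.empty(n_win)
    for i in range(n_win):
        lo = i * win
        hi = n if i == n_win - 1 else (i + 1) * win
        x = trace[lo:hi]
        sds[i] = np.median(np.abs(x - np.median(x))) / _ROBUST_SCALE
    return sds


def _window_maxima(absx: np.ndarray, radius: int) -> np.ndarray:
    """Indices where |x| is the maximum of its +-radius neighbourhood.

    Plateaus of equal maxima within one radius keep only the first index,
    so any two returned indices are more than ``radius`` apart.
    """
    mx = ndimage.maximum_filter1d(absx, size=2 * radius + 1, mode="nearest")
    cand = np.flatnonzero((absx == mx) & (absx > 0))
    if cand.size == 0 or np.all(np.diff(cand) > radius):
        return cand  # distinct-valued maxima are always > radius apart
    keep = [cand[0]]
    for i in cand[1:]:
        if i - keep[-1] > radius:
            keep.append(i)
    return np.asarray(keep)


def detect_spikes(
    rec: VoltageRecording,
    filter_settings: FilterSettings | None = None,
    detection_settings: DetectionSettings | None = None,
    prefiltered: bool = False,
) -> SpikeTrainSet:
    """Detect spikes on every electrode with an adaptive 6-sigma threshold.

    Each electrode is band-pass filtered (unless ``prefiltered``), its noise
    SD estimated per 1-second bin, and events are taken at local extrema of
    the (polarity-restricted) amplitude exceeding ``multiplier x local SD``.
    Thresholds are per-electrode and per-window, so electrodes are fully
    independent and detections are invariant to rescaling a trace by a
    positive constant. Filter edge transients (3 x order samples at each
    end) are excluded. Dead electrodes (noise below ``dead_floor``) yield
    empty trains and are flagged.
    """
    fset = filter_settings or FilterSettings()
    dset = detection_settings or DetectionSettings()
    if not prefiltered:
        rec = bandpass_filter(rec, fset)
    fs = rec.sampling_rate
    if rec.duration < dset.noise_window:
        raise ValueError("recording shorter than the noise window")
    radius = max(1, int(round(dset.dead_time * fs)))
    edge = 3 * fset.order
    win = int(round(dset.noise_window * fs))

    trains: dict[ElectrodeKey, np.ndarray] = {}
    dead: set[ElectrodeKey] = set()
    for key, x in zip(rec.electrodes, rec.data):
        sds = estimate_noise_sd(x, fs, dset)
        if np.max(sds) < dset.dead_floor:
            trains[key] = np.empty(0)
            dead.add(key)
            continue
        if dset.polarity == "negative":
            amp = np.clip(-x, 0, None)
        elif dset.polarity == "positive":
            amp = np.clip(x, 0, None)
        else:
            amp = np.abs(x)
        idx = _window_maxima(amp, radius)
        if idx.size:
            thr = dset.threshold_multiplier * sds[
                np.minimum(idx // win, sds.size - 1)
            ]
            ok = (amp[idx] >= thr) & (idx >= edge) & (idx < x.size - edge)
            idx = idx[ok]
        trains[key] = idx / fs
    return SpikeTrainSet(
        trains=trains,
        duration=rec.duration,
        dead=dead,
        provenance={
            "filter": {"low_cut": fset.low_cut, "high_cut": fset.high_cut,
                       "order": fset.order, "prefiltered": prefiltered},
            "detection": {
                "threshold_multiplier": dset.threshold_multiplier,
                "noise_window": dset.noise_window,
                "dead_time": dset.dead_time,
                "polarity": dset.polarity,
                "dead_floor": dset.dead_floor,
            },
        },
    )
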