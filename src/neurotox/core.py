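"""Shared containers for plate-based MEA data.

A recording session is organised as a multi-well plate (24 wells by default,
named A1..D6 row-major) with a fixed number of extracellular electrodes per
well. Electrodes are addressed by ``(well, index)`` pairs throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard plate formats -> (n_rows, n_cols)
_PLATE_GRIDS = {6: (2, 3), 12: (3, 4), 24: (4, 6), 48: (6, 8), 96: (8, 12)}

ElectrodeKey = tuple[str, int]


def well_names(n_wells: int) -> list[str]:
    """Row-major well labels (A1..D6 for a 24-well plate).

    Unknown formats fall back to a single row A1..A{n}.
    """
    rows, cols = _PLATE_GRIDS.get(n_wells, (1, n_wells))
    letters = "ABCDEFGHIJKLMNOP"
    return [f"{letters[r]}{c + 1}" for r in range(rows) for c in range(cols)]


@dataclass(frozen=True)
class PlateLayout:
    """Geometry and acquisition parameters of one MEA plate.

    Defaults follow the standard 24-well configuration: 16 recording
    electrodes per well sampled at 12.5 kHz for a 5-minute recording.
    """

    n_wells: int = 24
    electrodes_per_well: int = 16
    sampling_rate: float = 12500.0
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError(f"n_wells must be >= 1, got {self.n_wells}")
        if self.electrodes_per_well < 1:
            raise ValueError(
                f"electrodes_per_well must be >= 1, got {self.electrodes_per_well}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def wells(self) -> list[str]:
        return well_names(self.n_wells)

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    def electrodes(self) -> list[ElectrodeKey]:
        return [(w, e) for w in self.wells for e in range(self.electrodes_per_well)]


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps (seconds) over one recording interval.

    ``trains`` maps ``(well, electrode)`` to a sorted float array of spike
    times in ``[0, duration]``. Electrodes flagged in ``dead`` carried no
    usable signal (zero-variance trace) and are excluded from metric
    denominators downstream.
    """

    trains: dict[ElectrodeKey, np.ndarray]
    duration: float
    dead: set[ElectrodeKey] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        clean: dict[ElectrodeKey, np.ndarray] = {}
        for key, t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"spike times for {key} are not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration + 1e-9):
                raise ValueError(f"spike times for {key} outside [0, duration]")
            clean[key] = t
        self.trains = clean

    @property
    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for w, _ in self.trains:
            seen.setdefault(w)
        return list(seen)

    def electrodes_of(self, well: str) -> list[ElectrodeKey]:
        return [k for k in self.trains if k[0] == well]

    def subset(self, well: str) -> "SpikeTrainSet":
        keys = self.electrodes_of(well)
        return SpikeTrainSet(
            trains={k: self.trains[k] for k in keys},
            duration=self.duration,
            dead={k for k in self.dead if k[0] == well},
            provenance=dict(self.provenance),
        )

    def n_spikes(self, well: str | None = None) -> int:
        keys = self.electrodes_of(well) if well is not None else list(self.trains)
        return int(sum(self.trains[k].size for k in keys))


@dataclass
class VoltageRecording:
    """Raw or filtered per-electrode voltage traces in microvolts.

    ``data`` has shape ``(n_electrodes, n_samples)``; row *i* belongs to
    ``electrodes[i]``. All electrodes share the sampling rate and length,
    with ``n_samples == round(sampling_rate * duration)``.
    """

    data: np.ndarray
    electrodes: list[ElectrodeKey]
    sampling_rate: float
    duration: float
    layout: PlateLayout | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (electrodes x samples)")
        if len(self.electrodes) != self.data.shape[0]:
            raise ValueError("electrodes list does not match data rows")
        expected = int(round(self.sampling_rate * self.duration))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"trace length {self.data.shape[1]} != round(rate*duration)={expected}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def trace(self, key: ElectrodeKey) -> np.ndarray:
        return self.data[self.electrodes.index(key)]
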