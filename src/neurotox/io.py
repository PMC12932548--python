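"""File formats, run configuration, and provenance.

Formats are deliberately plain: spike trains as CSV (well, electrode,
time_s at microsecond precision), voltage traces as an HDF5 container (one
dataset per electrode under /<well>/e<index>, acquisition parameters as
root attributes), images as 2-channel TIFF with a JSON ground-truth /
provenance sidecar, metric tables as CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ElectrodeKey, PlateLayout, SpikeTrainSet, VoltageRecording
from .synth import MorphologyGroundTruth, NeuronImage

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_traces_h5",
    "read_traces_h5",
    "write_neuron_image",
    "read_neuron_image",
    "read_platemap",
    "RunConfig",
]

_TIME_FMT = "%.6f"  # 1 us resolution; exceeds the 12.5 kHz sample grid (80 us)


# --------------------------------------------------------------------------
# Spike CSV
# --------------------------------------------------------------------------

def write_spike_csv(path: str | Path, trains: SpikeTrainSet) -> None:
    """Write spikes as CSV rows (well, electrode, time_s), 6 decimals."""
    rows = []
    for (well, e), t in trains.trains.items():
        for ts in t:
            rows.append((well, e, _TIME_FMT % ts))
    with open(path, "w") as fh:
        fh.write("well,electrode,time_s\n")
        for well, e, ts in rows:
            fh.write(f"{well},{e},{ts}\n")


def read_spike_csv(
    path: str | Path, duration: float
) -> SpikeTrainSet:
    """Read a spike CSV; rows may arrive unsorted, trains come back sorted.

    Malformed rows raise ``ValueError`` naming the line number.
    """
    trains: dict[ElectrodeKey, list[float]] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:3] != ["well", "electrode", "time_s"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                well, e, t = parts[0], int(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            trains.setdefault((well, e), []).append(t)
    return SpikeTrainSet(
        trains={k: np.sort(np.asarray(v)) for k, v in trains.items()},
        duration=duration,
    )


# --------------------------------------------------------------------------
# Trace container (HDF5)
# --------------------------------------------------------------------------

def write_traces_h5(path: str | Path, rec: VoltageRecording) -> None:
    """One dataset per electrode at /<well>/e<index>; acquisition attrs at root."""
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["duration"] = rec.duration
        if rec.layout is not None:
            f.attrs["n_wells"] = rec.layout.n_wells
            f.attrs["electrodes_per_well"] = rec.layout.electrodes_per_well
        for (well, e), row in zip(rec.electrodes, rec.data):
            f.create_dataset(f"{well}/e{e}", data=row.astype(np.float32))


def read_traces_h5(path: str | Path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        sampling_rate = float(f.attrs["sampling_rate"])
        duration = float(f.attrs["duration"])
        layout = None
        if "n_wells" in f.attrs:
            layout = PlateLayout(
                n_wells=int(f.attrs["n_wells"]),
                electrodes_per_well=int(f.attrs["electrodes_per_well"]),
                sampling_rate=sampling_rate,
                duration=duration,
            )
        electrodes: list[ElectrodeKey] = []
        traces = []
        for well in f:
            for name in f[well]:
                electrodes.append((well, int(name[1:])))
                traces.append(f[well][name][:])
    return VoltageRecording(
        data=np.asarray(traces, dtype=float),
        electrodes=electrodes,
        sampling_rate=sampling_rate,
        duration=duration,
        layout=layout,
    )


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------

def write_neuron_image(
    path: str | Path,
    image: NeuronImage,
    ground_truth: MorphologyGroundTruth | None = None,
) -> None:
    """2-channel TIFF (nuclei, marker) with an optional JSON truth sidecar."""
    stack = np.stack([image.nuclei, image.marker]).astype(np.float32)
    tifffile.imwrite(str(path), stack)
    if ground_truth is not None:
        Path(str(path) + ".json").write_text(
            json.dumps(ground_truth.to_dict(), indent=1)
        )


def read_neuron_image(
    path: str | Path,
) -> tuple[NeuronImage, MorphologyGroundTruth | None]:
    stack = tifffile.imread(str(path))
    img = NeuronImage(nuclei=stack[0], marker=stack[1])
    sidecar = Path(str(path) + ".json")
    gt = None
    if sidecar.exists():
        gt = MorphologyGroundTruth.from_dict(json.loads(sidecar.read_text()))
    return img, gt


# --------------------------------------------------------------------------
# Plate map
# --------------------------------------------------------------------------

def read_platemap(path: str | Path) -> pd.DataFrame:
    """Plate map CSV: well, compound, dose, timepoint[, role].

    Wells must be unique per timepoint; control wells must carry dose 0.
    """
    df = pd.read_csv(path)
    required = {"well", "compound", "dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"platemap missing columns: {sorted(missing)}")
    if (df["dose"] < 0).any():
        raise ValueError("platemap doses must be >= 0")
    if "role" in df.columns:
        bad = df[(df["role"] == "control") & (df["dose"] != 0)]
        if not bad.empty:
            raise ValueError("control wells must have dose 0")
    key_cols = ["well", "timepoint"] if "timepoint" in df.columns else ["well"]
    if df.duplicated(key_cols).any():
        raise ValueError("duplicate well ids in platemap")
    return df


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat key-value configuration of the end-to-end pipeline.

    Serializes to/from YAML; unknown keys are rejected on load so typos
    cannot silently fall back to defaults.
    """

    seed: int = 0
    out_dir: str = "neurotox_out"
    compound: str = "compound"
    doses: list = field(default_factory=lambda: [0.0, 10.0, 50.0])
    timepoints: list = field(default_factory=lambda: [0.0, 24.0, 72.0])
    # effect_factors["dose"]["timepoint"] -> multiplicative factor (YAML keys
    # are strings); unlisted combinations default to 1.0
    effect_factors: dict = field(default_factory=dict)
    # MEA simulation
    electrodes_per_well: int = 16
    sampling_rate: float = 12500.0
    duration: float = 60.0
    background_rate: float = 1.0
    burst_rate: float = 6.0
    spikes_per_burst_mean: float = 8.0
    intra_burst_isi: float = 0.02
    synchrony_coupling: float = 0.5
    noise_sd: float = 5.0
    peak_amplitude: float = 50.0
    write_traces: bool = False
    # detection
    low_cut: float = 200.0
    high_cut: float = 3000.0
    filter_order: int = 4
    threshold_multiplier: float = 6.0
    noise_window: float = 1.0
    dead_time: float = 1.5e-3
    # metrics
    min_spikes: int = 5
    max_isi: float = 0.1
    synchrony_window: float = 0.05
    synchrony_bin: float = 0.01
    nmi_bin: float = 0.05
    # morphometry simulation
    run_morphometry: bool = True
    images_per_dose: int = 2
    image_size: int = 384
    somas_per_image: int = 4
    # stats
    effect_margin: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def factor(self, dose: float, timepoint: float) -> float:
        if dose == 0 or timepoint == 0:
            return 1.0
        for dk, tps in self.effect_factors.items():
            if float(dk) == float(dose):
                for tk, f in tps.items():
                    if float(tk) == float(timepoint):
                        return float(f)
        return 1.0

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
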