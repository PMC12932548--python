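"""End-to-end pipeline: simulate -> detect -> metrics -> morphometry -> stats.

The pipeline emulates the screening design around a single test compound:
one MEA well per dose group recorded before dosing (0 h) and at 24 h and
72 h after, plus replicate images per dose group for the morphometric
endpoint. All outputs carry the configuration hash so results from
different configurations never collide, and a fixed seed reproduces every
file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import PlateLayout, well_names
from .io import RunConfig, write_spike_csv, write_traces_h5
from .mea_metrics import (
    BurstSettings,
    SynchronySettings,
    compute_well_metrics,
)
from .mea_signal import DetectionSettings, FilterSettings, detect_spikes
from .morphometry import MorphometryParams, aggregate_phenotypes, analyze_image
from .stats import classify_effects, normalize_to_baseline, test_dose_groups
from .synth import (
    MorphologySpec,
    SpikeTrainSpec,
    biphasic_template,
    generate_neuron_image,
    generate_spike_trains,
    render_voltage_trace,
)

logger = logging.getLogger(__name__)

_MEA_METRICS = ("number_of_spikes", "mean_firing_rate", "number_of_bursts",
                "synchrony_index")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write the results bundle to ``out_dir``.

    Returns a dict with the in-memory tables: per-well metrics, baseline
    relatives, effect calls and trajectories, morphometry phenotypes, and
    (when the design has replicates) the dose-group test results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash
    logger.info("pipeline run %s -> %s", tag, out)

    try:
        metric_rows = _run_mea_arm(config, out, tag)
    except Exception as exc:  # pragma: no cover - stage tagging only
        raise RuntimeError(f"[mea] stage failed: {exc}") from exc

    metrics_df = pd.DataFrame(metric_rows)
    timeline = metrics_df.melt(
        id_vars=["compound", "dose", "timepoint", "well"],
        value_vars=list(_MEA_METRICS),
        var_name="metric", value_name="value",
    )
    try:
        relatives = normalize_to_baseline(timeline)
        mfr = relatives[relatives["metric"] == "mean_firing_rate"]
        calls, trajectories = classify_effects(mfr, margin=config.effect_margin)
    except Exception as exc:
        raise RuntimeError(f"[stats] stage failed: {exc}") from exc

    morpho_df, morpho_stats = None, None
    if config.run_morphometry:
        try:
            morpho_df, morpho_stats = _run_morphometry_arm(config)
        except Exception as exc:
            raise RuntimeError(f"[morphometry] stage failed: {exc}") from exc

    _write_outputs(config, out, tag, metrics_df, relatives, calls,
                   trajectories, morpho_df, morpho_stats)
    return {
        "metrics": metrics_df,
        "relatives": relatives,
        "effect_calls": calls,
        "trajectories": trajectories,
        "morphometry": morpho_df,
        "morphometry_stats": morpho_stats,
        "config_hash": tag,
    }


def _run_mea_arm(config: RunConfig, out: Path, tag: str) -> list[dict]:
    fset = FilterSettings(config.low_cut, config.high_cut, config.filter_order)
    dset = DetectionSettings(
        threshold_multiplier=config.threshold_multiplier,
        noise_window=config.noise_window,
        dead_time=config.dead_time,
    )
    bset = BurstSettings(config.min_spikes, config.max_isi)
    sset = SynchronySettings(config.synchrony_window, config.synchrony_bin)
    wells = well_names(24)
    rows = []
    for di, dose in enumerate(config.doses):
        well = wells[di]
        for ti, tp in enumerate(config.timepoints):
            f = config.factor(dose, tp)
            seed = (config.seed * 1_000_003 + di * 101 + ti) % (2**31)
            spec = SpikeTrainSpec(
                background_rate=config.background_rate * f,
                burst_rate=config.burst_rate * f,
                spikes_per_burst_mean=config.spikes_per_burst_mean,
                intra_burst_isi=config.intra_burst_isi,
                synchrony_coupling=config.synchrony_coupling,
                seed=seed,
            )
            layout = PlateLayout(
                n_wells=24,
                electrodes_per_well=config.electrodes_per_well,
                sampling_rate=config.sampling_rate,
                duration=config.duration,
            )
            trains, _ = generate_spike_trains(layout, spec, wells=[well])
            template = biphasic_template(
                sampling_rate=config.sampling_rate,
                peak_amplitude=config.peak_amplitude,
            )
            rec = render_voltage_trace(
                trains, template, noise_sd=config.noise_sd, seed=seed + 7,
                layout=layout,
            )
            if config.write_traces:
                write_traces_h5(out / f"traces_{tag}_d{di}_t{ti}.h5", rec)
            detected = detect_spikes(rec, fset, dset)
            write_spike_csv(out / f"spikes_{tag}_d{di}_t{ti}.csv", detected)
            wm = compute_well_metrics(
                detected, well=well, burst_settings=bset,
                synchrony_settings=sset, nmi_bin=config.nmi_bin,
            )
            rows.append({
                "compound": config.compound, "dose": dose, "timepoint": tp,
                **wm.to_dict(),
            })
    return rows


def _run_morphometry_arm(config: RunConfig):
    params = MorphometryParams()
    rows = []
    for di, dose in enumerate(config.doses):
        # morphometric endpoint responds to the late-timepoint factor
        f = config.factor(dose, config.timepoints[-1])
        for img_i in range(config.images_per_dose):
            seed = (config.seed * 999_983 + di * 131 + img_i) % (2**31)
            spec = MorphologySpec(
                n_somas=config.somas_per_image,
                image_size=(config.image_size, config.image_size),
                segment_length_mean=45.0 * f,
                segment_length_sd=10.0 * f,
                seed=seed,
            )
            image, _ = generate_neuron_image(spec)
            table, qc = analyze_image(image, params)
            agg = aggregate_phenotypes(table)
            rows.append({
                "compound": config.compound, "dose": dose, "image": img_i,
                "n_cells": qc["n_cells"],
                "marker_positive_fraction": qc["marker_positive_fraction"],
                **agg.to_dict(),
            })
    df = pd.DataFrame(rows)
    # relative-to-control aggregates
    ctrl = df[df["dose"] == 0].drop(columns=["compound", "dose", "image"]).mean()
    pheno_cols = ["max_neurite_length", "total_neurite_length", "n_extremities",
                  "n_roots", "n_segments", "n_nodes"]
    for c in pheno_cols:
        df[f"relative_{c}"] = df[c] / ctrl[c] if ctrl[c] else np.nan

    stats_results = None
    if config.images_per_dose >= 2 and len(config.doses) >= 2:
        long = df.melt(
            id_vars=["compound", "dose", "image"], value_vars=pheno_cols,
            var_name="endpoint", value_name="value",
        )
        stats_results = test_dose_groups(long)
    return df, stats_results


def _write_outputs(config, out, tag, metrics_df, relatives, calls,
                   trajectories, morpho_df, morpho_stats) -> None:
    ff = "%.6f"
    metrics_df.to_csv(out / f"well_metrics_{tag}.csv", index=False, float_format=ff)
    relatives.to_csv(out / f"relatives_{tag}.csv", index=False, float_format=ff)
    calls_payload = {
        "effect_calls": [dataclasses.asdict(c) for c in calls],
        "trajectories": {f"{k[0]}@{k[1]}": v for k, v in trajectories.items()},
    }
    (out / f"effects_{tag}.json").write_text(json.dumps(calls_payload, indent=1))
    if morpho_df is not None:
        morpho_df.to_csv(out / f"phenotypes_{tag}.csv", index=False, float_format=ff)
    if morpho_stats is not None:
        (out / f"phenotype_stats_{tag}.json").write_text(
            json.dumps([r.to_dict() for r in morpho_stats], indent=1)
        )
    provenance = {
        "config_hash": tag,
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    (out / f"provenance_{tag}.json").write_text(json.dumps(provenance, indent=1))
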