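"""End-to-end pipeline: dataset (or generator) -> responses -> maps ->
paired metrics -> statistics report.

Every stage is also available as a standalone function so the pipeline is
just composition plus bookkeeping (a run manifest with a config hash makes
any result table reproducible from the dataset alone).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core import CellRecording
from .events import (EvokedResponse, QuantalEventSet, average_sweeps,
                     baseline_subtract, classify_response, detect_events,
                     event_rates, normalize_to_power, noise_sd_estimate,
                     peak_amplitude, remove_direct, window_events,
                     windowed_mean_amplitude)
from .exceptions import InvalidParameterError, SchemaError
from .maps import (GroupMap, InputMap, align_to_soma, average_group,
                   build_cell_map, interpolate_half, region_mean)
from .stats import PairedMeasure, TestResult, coefficient_of_variation, \
    paired_compare, percent_change
from .synthgen import SynthConfig, simulate_grid_experiment, simulate_sr_experiment

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "write_results",
           "analyze_grid_cell", "analyze_led_bulk", "analyze_sr",
           "pair_metrics", "MODE_ANALYSIS_DEFAULTS"]

log = logging.getLogger(__name__)

#: analysis-window defaults per mode: (measure, window in ms after stimulus)
MODE_ANALYSIS_DEFAULTS = {
    "sCRACM": ("peak", (5.0, 80.0)),
    "LSPS": ("peak", (5.0, 80.0)),
    "AP_map": ("mean", (2.0, 30.0)),
    "LED_bulk": ("peak", (5.0, 80.0)),
    "NMDA": ("peak", (5.0, 150.0)),   # slow NMDAR kinetics need a wider window
    "Sr2+": ("events", None),
}

#: default analysis region (aligned-frame um): proximal apical dendrite
DEFAULT_REGIONS = {"proximal_apical": (-75.0, 75.0, 0.0, 150.0)}


@dataclass
class PipelineConfig:
    """Configuration of one analysis run."""

    mode: str = "sCRACM"
    window: Optional[tuple] = None      # ms after stimulus; mode default if None
    measure: Optional[str] = None       # "peak" | "mean"; mode default if None
    min_n: int = 8                      # group-map minimum neurons per pixel
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    normality_alpha: float = 0.05
    normalize_power: bool = True
    amp_threshold: Optional[float] = None   # pA; None -> 3x baseline noise
    direct_rise_max: float = 1.0        # ms, 20-80 % rise defining "fast"
    peak_smooth_ms: float = 1.0         # ~1 kHz boxcar before peak-picking on
                                        # noisy averages; 0 disables
    k_sigma: float = 3.0                # event-detection threshold
    min_iei: float = 2.0                # ms, event refractory
    seed: int = 0
    synth: dict = field(default_factory=dict)   # SynthConfig overrides

    def __post_init__(self):
        if self.mode not in MODE_ANALYSIS_DEFAULTS:
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        measure, window = MODE_ANALYSIS_DEFAULTS[self.mode]
        if self.measure is None:
            self.measure = measure
        if self.window is None:
            self.window = window
        if self.window is not None:
            self.window = tuple(self.window)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window) if self.window else None
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


@dataclass
class ResultBundle:
    """Everything one pipeline run produces."""

    responses: pd.DataFrame                 # per cell x spot
    metrics: pd.DataFrame                   # per pair x metric (wide: wt/ko)
    stats: pd.DataFrame                     # test results per metric
    cell_maps: dict = field(default_factory=dict)    # cell_id -> InputMap
    group_maps: dict = field(default_factory=dict)   # genotype -> GroupMap
    events: Optional[pd.DataFrame] = None   # Sr2+ event table
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-cell analyses

def _auto_threshold(avg, explicit: Optional[float]) -> float:
    if explicit is not None:
        return explicit
    i_stim = max(int(round(avg.stim_onset / avg.dt)), 1)
    return max(3.0 * noise_sd_estimate(avg.samples[:i_stim]), 1.0)


def analyze_grid_cell(cell: CellRecording, config: PipelineConfig) -> tuple:
    """Average, classify and measure every grid spot of one cell.

    Returns ``(responses, input_map)``.  In LSPS / AP-map modes responses
    are classified and direct components subtracted (pure-direct spots are
    excluded from the map); in sCRACM (TTX/4-AP) every supra-threshold
    response is synaptic by construction.
    """
    if cell.grid is None:
        raise SchemaError(f"cell {cell.cell_id}: grid mode needs grid geometry")
    classify = cell.mode in ("LSPS", "AP_map")
    responses = []
    n_direct = 0
    for spot, sweeps in sorted(cell.sweeps_by_spot().items()):
        if spot is None:
            raise SchemaError(f"cell {cell.cell_id}: ungridded sweep in grid mode")
        avg = baseline_subtract(average_sweeps(sweeps))
        thr = _auto_threshold(avg, config.amp_threshold)
        if classify:
            resp = classify_response(avg, amp_threshold=thr,
                                     direct_rise_max=config.direct_rise_max,
                                     analysis_window=config.window,
                                     grid_index=spot)
            resp = remove_direct(resp)
            if resp.excluded:
                n_direct += 1
        else:
            amp = peak_amplitude(avg, config.window,
                                 smooth_ms=config.peak_smooth_ms)
            resp = EvokedResponse(trace=avg, amplitude=amp,
                                  classification="synaptic",
                                  analysis_window=config.window,
                                  grid_index=spot)
        if config.measure == "mean" and not resp.excluded:
            resp.amplitude = windowed_mean_amplitude(resp.trace, config.window)
        elif config.measure == "peak" and not resp.excluded and classify:
            resp.amplitude = peak_amplitude(resp.trace, config.window,
                                            smooth_ms=config.peak_smooth_ms)
        responses.append(resp)
    if n_direct:
        log.info("cell %s: %d direct pixel(s) excluded", cell.cell_id, n_direct)
    imap = build_cell_map(responses, cell.grid, cell.soma_pos,
                          metadata={"cell_id": cell.cell_id,
                                    "genotype": cell.genotype,
                                    "pair_id": cell.pair_id,
                                    "power": cell.led_power})
    return responses, imap


def analyze_led_bulk(cell: CellRecording, config: PipelineConfig) -> dict:
    """Bulk LED stimulation: peak of the averaged EPSC, power-normalised
    amplitude, and trial-to-trial CV from per-sweep peaks."""
    sweeps = cell.sweeps
    avg = baseline_subtract(average_sweeps(sweeps))
    amp = peak_amplitude(avg, config.window, smooth_ms=config.peak_smooth_ms)
    trial_amps = [peak_amplitude(baseline_subtract(s), config.window,
                                 smooth_ms=config.peak_smooth_ms)
                  for s in sweeps]
    cv = coefficient_of_variation(trial_amps) if len(trial_amps) >= 3 else np.nan
    out = {"cell_id": cell.cell_id, "genotype": cell.genotype,
           "pair_id": cell.pair_id, "amplitude_pA": amp, "cv": cv,
           "n_sweeps": len(sweeps)}
    if cell.led_power:
        out["amp_per_mW"] = normalize_to_power(amp, cell.led_power)
    return out


def analyze_sr(cell: CellRecording, config: PipelineConfig) -> tuple:
    """Detect, window and rate Sr2+ quantal events for one cell.

    Returns ``(rates_dict, labelled_event_set)``.
    """
    sets = []
    for s in cell.sweeps:
        ev = detect_events(s, k_sigma=config.k_sigma, min_iei=config.min_iei)
        ev.sweep_ids = np.full(len(ev), s.sweep_id, dtype=object)
        sets.append(window_events(ev))
    pooled = QuantalEventSet.concatenate(sets) if sets else None
    if pooled is None:
        raise SchemaError(f"cell {cell.cell_id}: no sweeps")
    pooled.sweep_ids = np.concatenate([s.sweep_ids for s in sets])
    rates = event_rates(pooled)
    rates.update({"cell_id": cell.cell_id, "genotype": cell.genotype,
                  "pair_id": cell.pair_id})
    return rates, pooled


# ---------------------------------------------------------------------------
# pairing and statistics

def pair_metrics(per_cell: pd.DataFrame, metric_cols: list) -> tuple:
    """Pivot a per-cell table into per-pair WT/KO measures.

    Returns ``(metrics_frame, {metric: [PairedMeasure, ...]})``; pairs with
    a missing member are dropped with a log entry.
    """
    measures: dict = {m: [] for m in metric_cols}
    rows = []
    dropped = 0
    for pair_id, sub in per_cell.groupby("pair_id"):
        wt = sub[sub.genotype == "WT"]
        ko = sub[sub.genotype == "KO"]
        if len(wt) != 1 or len(ko) != 1:
            dropped += 1
            log.info("pair %s dropped: needs exactly one WT and one KO cell",
                     pair_id)
            continue
        row = {"pair_id": pair_id}
        for m in metric_cols:
            wv = float(wt.iloc[0][m])
            kv = float(ko.iloc[0][m])
            row[f"wt_{m}"] = wv
            row[f"ko_{m}"] = kv
            measures[m].append(PairedMeasure(pair_id=pair_id, wt_value=wv,
                                             ko_value=kv, metric=m))
        rows.append(row)
    if dropped:
        log.info("dropped %d incomplete pair(s)", dropped)
    return pd.DataFrame(rows), measures


def _stats_table(measures: dict, alpha: float) -> pd.DataFrame:
    rows = []
    for metric, pairs in measures.items():
        complete = [p for p in pairs if p.complete]
        if len(complete) < 3:
            log.warning("metric %s: fewer than 3 complete pairs; skipped", metric)
            continue
        res: TestResult = paired_compare(complete, alpha=alpha, metric=metric)
        wt_mean = float(np.mean([p.wt_value for p in complete]))
        ko_mean = float(np.mean([p.ko_value for p in complete]))
        rows.append({
            "metric": metric,
            "test": res.test,
            "statistic": res.statistic,
            "df": res.df[0] if res.df else np.nan,
            "p": res.pvalue,
            "n_pairs": res.n,
            "wt_mean": wt_mean,
            "ko_mean": ko_mean,
            "percent_change": percent_change(wt_mean, ko_mean)
            if wt_mean > 0 else np.nan,
            "ko_lt_wt": ko_mean < wt_mean and res.pvalue < alpha,
            "both_normal": res.normality.get("both_normal", False),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver

def run_pipeline(config: PipelineConfig, cells: Optional[list] = None,
                 dataset_path=None, out_dir=None) -> ResultBundle:
    """Run the full analysis for one experiment mode.

    Input priority: explicit ``cells`` list, then ``dataset_path``, else a
    synthetic dataset is generated from ``config.seed`` and
    ``config.synth`` overrides.  Fully deterministic given the seed.
    """
    from .io import read_dataset  # local import to avoid a cycle

    if cells is None and dataset_path is not None:
        cells, _ = read_dataset(dataset_path)
    if cells is None:
        synth = SynthConfig.for_mode(config.mode, seed=config.seed,
                                     **config.synth)
        if config.mode == "Sr2+":
            cells, _ = simulate_sr_experiment(synth)
        else:
            cells, _ = simulate_grid_experiment(synth, mode=config.mode)
    modes = {c.mode for c in cells}
    if modes and modes != {config.mode}:
        raise SchemaError(
            f"config mode {config.mode!r} does not match dataset mode(s) "
            f"{sorted(modes)!r}")

    grid_modes = ("sCRACM", "LSPS", "AP_map")
    resp_rows = []
    cell_maps: dict = {}
    group_maps: dict = {}
    events_df = None

    if config.mode in grid_modes:
        per_cell_rows = []
        aligned: dict = {"WT": [], "KO": []}
        for cell in cells:
            responses, imap = analyze_grid_cell(cell, config)
            cell_maps[cell.cell_id] = imap
            for r in responses:
                resp_rows.append({
                    "cell_id": cell.cell_id, "genotype": cell.genotype,
                    "pair_id": cell.pair_id,
                    "grid_row": r.grid_index[0], "grid_col": r.grid_index[1],
                    "amplitude_pA": np.nan if r.excluded else r.amplitude,
                    "classification": r.classification,
                    "direct_corrected": bool(r.info.get("direct_corrected", False)),
                    "onset_ms": r.onset_latency})
            amap = align_to_soma(imap)
            power = cell.led_power if config.normalize_power else None
            row = {"cell_id": cell.cell_id, "genotype": cell.genotype,
                   "pair_id": cell.pair_id}
            for name, rect in config.regions.items():
                row[f"region_{name}"] = region_mean(amap, rect, power=power)
            per_cell_rows.append(row)
            gmap = amap
            if power:
                vals = np.where(np.isfinite(amap.values),
                                amap.values / power, np.nan)
                gmap = InputMap(values=vals, mask=amap.mask.copy(),
                                x_coords=amap.x_coords, y_coords=amap.y_coords,
                                frame=amap.frame, soma_pos=amap.soma_pos,
                                metadata=dict(amap.metadata))
            aligned[cell.genotype].append(interpolate_half(gmap))
        for gen, ms in aligned.items():
            if ms:
                group_maps[gen] = average_group(ms, min_n=config.min_n, label=gen)
        per_cell = pd.DataFrame(per_cell_rows)
        metric_cols = [c for c in per_cell.columns if c.startswith("region_")]
    elif config.mode == "LED_bulk":
        per_cell = pd.DataFrame([analyze_led_bulk(c, config) for c in cells])
        metric_cols = [c for c in ("amplitude_pA", "amp_per_mW", "cv")
                       if c in per_cell.columns]
        resp_rows = per_cell.to_dict("records")
    elif config.mode == "Sr2+":
        rate_rows = []
        ev_rows = []
        for cell in cells:
            rates, pooled = analyze_sr(cell, config)
            rate_rows.append(rates)
            for t, a, lab, sid in zip(pooled.times, pooled.amplitudes,
                                      pooled.labels, pooled.sweep_ids):
                ev_rows.append({"cell_id": cell.cell_id, "sweep_id": sid,
                                "t_ms": t, "amp_pA": a, "label": lab})
        per_cell = pd.DataFrame(rate_rows)
        events_df = pd.DataFrame(ev_rows)
        metric_cols = ["spont_hz", "evoked_hz", "spont_amp_pA", "evoked_amp_pA"]
        resp_rows = per_cell.to_dict("records")
    else:  # pragma: no cover
        raise InvalidParameterError(config.mode)

    metrics, measures = pair_metrics(per_cell, metric_cols)
    stats = _stats_table(measures, alpha=config.normality_alpha)
    responses = pd.DataFrame(resp_rows)
    n_direct = int((responses.get("classification") == "direct").sum()) \
        if "classification" in responses else 0
    manifest = {
        "optomap_version": _version,
        "mode": config.mode,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "n_cells": len(cells),
        "n_pairs": int(metrics.shape[0]) if len(metrics) else 0,
        "n_direct_excluded": n_direct,
    }
    bundle = ResultBundle(responses=responses, metrics=metrics, stats=stats,
                          cell_maps=cell_maps, group_maps=group_maps,
                          events=events_df, manifest=manifest)
    if out_dir is not None:
        write_results(bundle, out_dir)
    return bundle


def _write_map(m, path: Path, name: str):
    vals = pd.DataFrame(m.values)
    vals.to_csv(path / f"{name}.csv", index=False, header=False)
    header = {
        "frame": m.frame,
        "x_coords": list(np.asarray(m.x_coords, dtype=float)),
        "y_coords": list(np.asarray(m.y_coords, dtype=float)),
        "mask_encoding": "NaN = masked",
    }
    if isinstance(m, GroupMap):
        header["min_n"] = m.min_n
        header["label"] = m.label
        pd.DataFrame(m.n).to_csv(path / f"{name}.n.csv", index=False, header=False)
    (path / f"{name}.json").write_text(json.dumps(header, indent=1))


def write_results(bundle: ResultBundle, out_dir) -> Path:
    """Write all result tables, maps and the run manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.responses.to_csv(out / "responses.csv", index=False)
    bundle.metrics.to_csv(out / "pair_metrics.csv", index=False)
    bundle.stats.to_csv(out / "stats.csv", index=False)
    if bundle.events is not None:
        bundle.events.to_csv(out / "events.csv", index=False)
    if bundle.group_maps:
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        for gen, gm in bundle.group_maps.items():
            _write_map(gm, map_dir, f"group_{gen}")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1))
    log.info("results written to %s", out)
    return out
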