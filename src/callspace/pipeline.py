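"""End-to-end orchestration: simulate -> detect -> features -> space ->
metrics -> network -> models, under one config and one master seed.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so a rerun with an identical config is bit-identical
through the embedding stage.  Each run writes into its own directory with an
immutable manifest recording versions, seeds, parameters, and input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import DetectorParams, energy_detect, match_detections, optimize_detector
from .features import extract_features, feature_table, preprocess, scale_features
from .io import (
    frame_to_selections,
    read_selection_table,
    read_wav,
    selections_to_frame,
    write_selection_table,
)
from .metrics import compute_vocal_metrics
from .models import fit_battery
from .network import interaction_edges, network_metrics, proximity_edges
from .space import embed
from .synth import ExperimentConfig, simulate_experiment

log = logging.getLogger("callspace")

STAGES = ("simulate", "detect", "features", "space", "metrics", "network",
          "models")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters plus the master seed."""

    master_seed: int = 0
    simulate: bool = True
    experiment: ExperimentConfig = dataclasses.field(
        default_factory=ExperimentConfig
    )
    detector_grid: dict = dataclasses.field(
        default_factory=lambda: {
            "amplitude_threshold": [0.05, 0.1, 0.2],
            "min_duration": [0.03, 0.05],
            "max_duration": [0.5],
            "hold_time": [0.02],
        }
    )
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    grid_resolution: int = 200
    hdr_level: float = 0.95
    proximity_threshold_cm: float = 10.0
    network_period: str = "all"
    interaction_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        exp = raw.pop("experiment", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        exp_known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        exp_unknown = set(exp) - exp_known
        if exp_unknown:
            raise ValueError(
                f"unknown experiment config fields: {sorted(exp_unknown)}"
            )
        return cls(experiment=ExperimentConfig(**exp), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    recordings: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    snapshots: pd.DataFrame | None = None,
    use_truth_selections: bool = False,
) -> dict:
    """Run all stages; returns the manifest dict (also written to the run
    directory).  With ``config.simulate`` false, ``recordings`` (and
    optionally ``events``/``snapshots``) must be supplied, with columns
    flock/individual/age_class/block/session/wav_path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "stages": {},
        "inputs": {},
    }

    # -- simulate ----------------------------------------------------------
    if config.simulate:
        seed = stage_seed(config.master_seed, "simulate")
        log.info("simulate: seed=%d", seed)
        experiment = simulate_experiment(config.experiment, out / "synthetic",
                                         seed=seed)
        recordings = experiment.recordings
        events = experiment.events
        snapshots = experiment.snapshots
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "n_recordings": len(recordings),
            "status": "completed",
        }
    else:
        if recordings is None:
            raise ValueError("recordings table required when simulate is off")
        manifest["stages"]["simulate"] = {"status": "skipped"}
    manifest["inputs"]["recordings"] = {
        "n": len(recordings),
        "hash": hashlib.sha256(
            recordings.to_csv(index=False).encode()
        ).hexdigest()[:16],
    }

    # -- detect ------------------------------------------------------------
    log.info("detect: optimizing on first annotated session")
    first = recordings.iloc[0]
    wave0, rate0 = read_wav(first["wav_path"])
    if "truth_path" in recordings.columns and pd.notna(first.get("truth_path")):
        truth0 = frame_to_selections(read_selection_table(first["truth_path"]))
        best, diag, _ = optimize_detector(
            wave0, rate0, truth0, config.detector_grid
        )
        detect_diag = diag.as_dict()
    else:
        best, detect_diag = DetectorParams(), {}
    sel_dir = out / "selections"
    sel_dir.mkdir(exist_ok=True)
    sel_rows = []
    for _, rec in recordings.iterrows():
        if use_truth_selections and pd.notna(rec.get("truth_path")):
            sels = frame_to_selections(
                read_selection_table(rec["truth_path"]),
                recording=rec["wav_path"],
            )
        else:
            wave, rate = read_wav(rec["wav_path"])
            sels = energy_detect(wave, rate, best, recording=rec["wav_path"])
        for s in sels:
            sel_rows.append(
                {
                    "wav_path": rec["wav_path"],
                    "individual": rec["individual"],
                    "flock": rec["flock"],
                    "age_class": rec["age_class"],
                    "block": rec["block"],
                    "session": rec["session"],
                    "Begin Time (s)": s.begin,
                    "End Time (s)": s.end,
                }
            )
    selections = pd.DataFrame(sel_rows)
    selections_out = selections.rename(columns={"wav_path": "Begin File"})
    write_selection_table(selections_out, sel_dir / "all_detections.txt")
    manifest["stages"]["detect"] = {
        "params": dataclasses.asdict(best),
        "optimizer_diagnostics": detect_diag,
        "n_detections": len(selections),
        "status": "completed",
    }

    # -- features ----------------------------------------------------------
    log.info("features: %d selections", len(selections))
    feat_rows, meta_rows = [], []
    for wav_path, group in selections.groupby("wav_path", sort=True):
        wave, rate = read_wav(wav_path)
        wave19, rate19 = preprocess(wave, rate)
        for _, row in group.iterrows():
            try:
                feats = extract_features(
                    wave19, rate19,
                    begin=row["Begin Time (s)"], end=row["End Time (s)"],
                )
            except ValueError:
                continue  # too-short detection
            feat_rows.append(feats)
            meta_rows.append(
                {k: row[k] for k in
                 ("individual", "flock", "age_class", "block", "session")}
            )
    table = feature_table(feat_rows, pd.DataFrame(meta_rows))
    table.to_csv(out / "features.csv", index=False)
    manifest["stages"]["features"] = {
        "n_calls": len(table),
        "status": "completed",
    }

    # -- space -------------------------------------------------------------
    seed = stage_seed(config.master_seed, "space")
    scaled = scale_features(table)
    from .features import FEATURE_NAMES

    emb = embed(
        scaled[FEATURE_NAMES],
        perplexity=min(config.perplexity, max(5.0, (len(scaled) - 1) / 3.5)),
        iterations=config.tsne_iterations,
        seed=seed,
    )
    emb_df = pd.DataFrame(emb.coords, columns=["dim1", "dim2"])
    emb_df.insert(0, "call", np.arange(len(emb_df)))
    emb_df.to_csv(out / "embedding.csv", index=False)
    manifest["stages"]["space"] = {
        "seed": seed,
        "perplexity": emb.perplexity,
        "iterations": emb.iterations,
        "status": "completed",
    }

    # -- metrics -----------------------------------------------------------
    log.info("metrics: KDE spaces and overlap statistics")
    vocal = compute_vocal_metrics(
        emb.coords,
        table[["individual", "flock", "age_class", "block"]],
        grid_resolution=config.grid_resolution,
        hdr_level=config.hdr_level,
    )
    vocal.to_csv(out / "vocal_metrics.csv", index=False)
    manifest["stages"]["metrics"] = {
        "hdr_level": config.hdr_level,
        "n_rows": len(vocal),
        "status": "completed",
    }

    # -- network -----------------------------------------------------------
    net_rows = []
    if events is not None and snapshots is not None and len(recordings):
        for flock, rec_sub in recordings.groupby("flock"):
            birds = sorted(rec_sub["individual"].unique())
            age = rec_sub["age_class"].iloc[0]
            ev = events[events["flock"] == flock] if "flock" in events else events
            sn = (snapshots[snapshots["flock"] == flock]
                  if "flock" in snapshots else snapshots)
            nets = [
                proximity_edges(sn, birds,
                                threshold_cm=config.proximity_threshold_cm,
                                flock=flock),
                interaction_edges(ev, "affiliation", birds,
                                  period=config.network_period, flock=flock),
                interaction_edges(ev, "agonism", birds,
                                  period=config.network_period, flock=flock),
            ]
            for net in nets:
                m = network_metrics(net).assign(age_class=age)
                net_rows.append(m)
                net.adjacency.to_csv(
                    out / f"adjacency_{flock}_{net.dimension}.csv"
                )
        net_metrics = pd.concat(net_rows, ignore_index=True)
        net_metrics.to_csv(out / "network_metrics.csv", index=False)
        manifest["stages"]["network"] = {
            "n_rows": len(net_metrics),
            "status": "completed",
        }
    else:
        net_metrics = None
        manifest["stages"]["network"] = {"status": "skipped"}

    # -- models ------------------------------------------------------------
    log.info("models: fitting the battery")
    battery = fit_battery(
        vocal_metrics=vocal,
        network_metrics=net_metrics,
        alpha=config.interaction_alpha,
    )
    battery.to_csv(out / "models.csv", index=False)
    battery.to_json(out / "models.json", orient="records", indent=1)
    manifest["stages"]["models"] = {
        "n_terms": len(battery),
        "status": "completed",
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
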