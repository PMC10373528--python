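"""End-to-end orchestration: configuration validation, stage sequencing,
and run manifests."""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundary import accept_all, accept_none, classify_boundary
from .bursts import call_bursts, realign_and_average
from .config import CONSTRUCTS, HeatShockParams, ModeParams, NoiseParams, SimConfig
from .datatypes import ConfigError
from .synthetic import simulate_dataset
from .timer_test import run_timer_threshold_analysis
from .traces import preprocess_embryo

_SCHEMA: dict = {
    "construct": "endogenous",
    "seed": 0,
    "simulate": {
        "n_embryos": 1,
        "n_stripes": 3,
        "nuclei_per_row": 18,
        "rows": 16,
        "frame_interval": 20.0,
        "t_start": -60.0,
        "t_end": 10.0,
        "protein_ratio_pb_ab": 4.0,
        "mrna_ratio_pb_ab": 50.0,
        "divergence_time": -30.0,
        "activation_model": "timer",
        "timer_mean": -15.0,
        "timer_sd": 3.0,
        "threshold_level": 1.2,
        "second_gene": False,
        "second_gene_offset": 10.0,
        "background": 0.2,
        "heat_shock": None,
        "low_mode": {"mean_intensity": 0.4, "intensity_sd": 0.08,
                     "burst_duration_mean": 2.0, "burst_duration_max": 5.0,
                     "interburst_mean": 3.0, "interburst_min": 1.0},
        "high_mode": {"mean_intensity": 1.1, "intensity_sd": 0.12,
                      "burst_duration_mean": 8.0, "burst_duration_max": 20.0,
                      "interburst_mean": 2.0, "interburst_min": 1.0},
        "noise": {"protein_sd": 0.05, "spot_sd": 0.05,
                  "detection_dropout_prob": 0.05, "protein_amp_sd": 0.15,
                  "time_shift_sd": 4.0, "position_sd": 0.2},
    },
    "preprocess": {
        "target_interval_s": 20.0,
        "smooth_window_min": 4.0,
        "background": None,
        "motion_correct": False,
    },
    "classify": {"acceptor": "none", "diag1_fraction": 0.25},
    "ensembles": {"min_nuclei": 25, "min_dots": 3,
                  "quantities": ["protein", "mrna_rate", "active_fraction"]},
    "timer_test": {"tolerance": 0.05, "max_permutations": 10000,
                   "alpha": 0.05, "stripe": None, "enabled": False},
}

_POSITIVE_KEYS = {
    "frame_interval", "target_interval_s", "smooth_window_min", "rows",
    "nuclei_per_row", "n_stripes", "n_embryos", "max_permutations",
    "min_nuclei", "min_dots",
}


_MISSING = object()


def _merge(schema, doc, path=""):
    if doc is _MISSING:
        return schema
    if isinstance(schema, dict):
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path or 'document'} must be a mapping")
        unknown = set(doc) - set(schema)
        if unknown:
            raise ConfigError(f"unknown keys at {path or 'top level'}: {sorted(unknown)}")
        return {k: _merge(schema[k], doc.get(k, _MISSING),
                          f"{path}{k}." if path else f"{k}.")
                for k in schema}
    if schema is None:
        return doc  # nullable slots (heat_shock, background override, stripe)
    if doc is None:
        raise ConfigError(f"{path[:-1]}: null is not a valid value")
    if isinstance(schema, bool):
        if not isinstance(doc, bool):
            raise ConfigError(f"{path[:-1]}: expected a boolean, got {doc!r}")
        return doc
    if isinstance(schema, (int, float)):
        if isinstance(doc, bool) or not isinstance(doc, (int, float)):
            raise ConfigError(f"{path[:-1]}: expected a number, got {doc!r}")
        key = path[:-1].rsplit(".", 1)[-1]
        if key in _POSITIVE_KEYS and doc <= 0:
            raise ConfigError(f"{path[:-1]}: must be positive, got {doc!r}")
        return doc
    if isinstance(schema, str):
        if not isinstance(doc, str):
            raise ConfigError(f"{path[:-1]}: expected a string, got {doc!r}")
        return doc
    if isinstance(schema, list):
        if not isinstance(doc, list):
            raise ConfigError(f"{path[:-1]}: expected a list, got {doc!r}")
        return doc
    return doc


def validate_config(document: dict | None) -> dict:
    """Normalize a YAML/JSON configuration document.

    Defaults are injected (20 s interval, 4 min smoothing, participation
    minima 25/3, 5% tolerance, 10000-permutation cap, alpha 0.05); unknown
    keys and type mismatches are rejected.
    """
    cfg = _merge(_SCHEMA, document or {})
    if cfg["construct"] not in CONSTRUCTS:
        raise ConfigError(
            f"construct must be one of {CONSTRUCTS}, got {cfg['construct']!r}"
        )
    sim = cfg["simulate"]
    if cfg["preprocess"]["background"] is None:
        cfg["preprocess"]["background"] = sim["background"]
    hs = sim.get("heat_shock")
    if hs is not None:
        allowed = {"start", "pulse_duration", "amplitude", "peak_delay"}
        unknown = set(hs) - allowed
        if unknown:
            raise ConfigError(f"unknown heat_shock keys: {sorted(unknown)}")
    return cfg


def sim_config_from(cfg: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a normalized configuration document."""
    sim = cfg["simulate"]
    hs = sim.get("heat_shock")
    return SimConfig(
        construct=cfg["construct"],
        n_stripes=int(sim["n_stripes"]),
        nuclei_per_row=int(sim["nuclei_per_row"]),
        rows=int(sim["rows"]),
        frame_interval=float(sim["frame_interval"]),
        t_start=float(sim["t_start"]),
        t_end=float(sim["t_end"]),
        protein_ratio_pb_ab=float(sim["protein_ratio_pb_ab"]),
        mrna_ratio_pb_ab=float(sim["mrna_ratio_pb_ab"]),
        low_mode=ModeParams(**sim["low_mode"]),
        high_mode=ModeParams(**sim["high_mode"]),
        divergence_time=float(sim["divergence_time"]),
        activation_model=sim["activation_model"],
        timer_mean=float(sim["timer_mean"]),
        timer_sd=float(sim["timer_sd"]),
        threshold_level=float(sim["threshold_level"]),
        second_gene=bool(sim["second_gene"]),
        second_gene_offset=float(sim["second_gene_offset"]),
        heat_shock=None if hs is None else HeatShockParams(**hs),
        noise=NoiseParams(**sim["noise"]),
        background=float(sim["background"]),
        rng_seed=int(cfg["seed"] if seed is None else seed),
    ).validate()


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None, outdir: str | Path, seed: int | None = None) -> dict:
    """Run simulate -> preprocess -> classify -> bursts -> ensembles (and the
    timer test when enabled), writing stage outputs and a run manifest.

    Returns the manifest dictionary.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    def stage(name):
        manifest["stages"][name] = {"t0": time.time()}
        return name

    def done(name):
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("t0"), 3
        )

    stage("simulate")
    sim_cfg = sim_config_from(cfg)
    sims = simulate_dataset(sim_cfg, int(cfg["simulate"]["n_embryos"]), base_seed=cfg["seed"])
    truth_tables = []
    trace_tables = []
    for embryo, truth in sims:
        trace_tables.append(embryo.to_table())
        tt = truth.nuclei.copy()
        tt.insert(0, "embryo", embryo.embryo_id)
        truth_tables.append(tt)
    manifest["outputs"]["traces.tsv"] = _write_tsv(
        pd.concat(trace_tables, ignore_index=True), outdir / "traces.tsv"
    )
    manifest["outputs"]["ground_truth.tsv"] = _write_tsv(
        pd.concat(truth_tables, ignore_index=True), outdir / "ground_truth.tsv"
    )
    done("simulate")

    pp = cfg["preprocess"]
    stage("preprocess")
    processed = [
        preprocess_embryo(
            e, background=pp["background"], target_interval=pp["target_interval_s"],
            smooth_window_min=pp["smooth_window_min"],
        )
        for e, _ in sims
    ]
    done("preprocess")

    stage("classify")
    acceptor = accept_all if cfg["classify"]["acceptor"] == "all" else accept_none
    pairs = []
    assign_rows = []
    for emb in processed:
        assignment = classify_boundary(
            emb, acceptor=acceptor,
            diag1_increase_fraction=cfg["classify"]["diag1_fraction"],
            expected_stripes=int(cfg["simulate"]["n_stripes"]),
        )
        pairs.append((emb, assignment))
        for nid, c in sorted(assignment.classes.items()):
            assign_rows.append(
                (emb.embryo_id, nid, c, assignment.stripe_number.get(nid, 0))
            )
    manifest["outputs"]["assignment.tsv"] = _write_tsv(
        pd.DataFrame(assign_rows, columns=["embryo", "nucleus", "class", "stripe"]),
        outdir / "assignment.tsv",
    )
    done("classify")

    stage("bursts")
    burst_rows = []
    for emb, assignment in pairs:
        for nid in assignment.pb + assignment.ab:
            for b in call_bursts(emb.traces[nid].spot, emb.frame_interval, nid, emb.t):
                burst_rows.append(
                    (emb.embryo_id, nid, assignment.classes[nid], b.start, b.end,
                     round(b.duration, 4), round(b.mean_intensity, 5))
                )
    manifest["outputs"]["bursts.tsv"] = _write_tsv(
        pd.DataFrame(
            burst_rows,
            columns=["embryo", "nucleus", "class", "start", "end",
                     "duration_min", "mean_intensity"],
        ),
        outdir / "bursts.tsv",
    )
    done("bursts")

    stage("ensembles")
    ens_rows = []
    for quantity in cfg["ensembles"]["quantities"]:
        for cls in ("PB", "AB"):
            ens = realign_and_average(
                pairs, quantity, cls=cls,
                min_nuclei=int(cfg["ensembles"]["min_nuclei"]),
                min_dots=int(cfg["ensembles"]["min_dots"]),
            )
            for j in range(len(ens.t_rel)):
                ens_rows.append(
                    (quantity, cls, round(float(ens.t_rel[j]), 4), int(ens.n[j]),
                     float(ens.mean[j]),
                     float(ens.sd[j]) if ens.sd is not None else float("nan"))
                )
    manifest["outputs"]["ensembles.tsv"] = _write_tsv(
        pd.DataFrame(ens_rows, columns=["quantity", "class", "t_rel_min", "n", "mean", "sd"]),
        outdir / "ensembles.tsv",
    )
    done("ensembles")

    if cfg["timer_test"]["enabled"]:
        stage("timer_test")
        tt = cfg["timer_test"]
        report = run_timer_threshold_analysis(
            pairs, stripe=tt["stripe"], construct=cfg["construct"],
            tolerance=float(tt["tolerance"]), max_perm=int(tt["max_permutations"]),
            alpha=float(tt["alpha"]), seed=cfg["seed"],
        )
        (outdir / "timer_test.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["outputs"]["timer_test.json"] = "written"
        manifest["verdict"] = report.verdict
        done("timer_test")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
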