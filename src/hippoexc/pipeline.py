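"""Config-driven end-to-end synthetic study.

Chains the pipeline stages on generated data: a two-genotype LFP cohort
with planted interictal-spike rates -> detection -> per-animal rates; a
simulated neuron family -> morpho-electric features -> z-scored k-means
clustering with bootstrap stability and membership residuals; synthetic
counts -> DE contrasts -> the six-criterion candidate filter.  Every run
writes tidy TSV/JSON outputs plus a resolved-config snapshot and run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._rng import stream
from .clustering import (CANONICAL_FEATURES, FeatureMatrix, bootstrap_stability,
                         fit_kmeans, label_clusters, membership_residuals,
                         zscore_features)
from .ephys import RampProtocol, StepProtocol, extract_features
from .genes import lognormalize, multilevel_filter, qc_filter, standard_contrasts
from .lfp import detect_iis, estimate_baseline_sd, iis_rate, preprocess_lfp
from .simulate import (LfpSimConfig, NeuronModelParams, SynthCountConfig,
                       simulate_counts, simulate_current_clamp, simulate_lfp,
                       standard_planted_patterns)

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["lfp", "ephys", "cluster", "genes"],
    "lfp": {
        "n_per_genotype": 4,
        "duration_s": 60.0,
        "fs_hz": 5000.0,
        "rate_per_min": {"E3": 1.0, "E4": 6.0},
        "amplitude_sd": 8.0,
        "width_ms": 30.0,
        "threshold_sd": 5.0,
        "min_ms": 10.0,
        "max_ms": 100.0,
    },
    "ephys": {
        "n_neurons": 30,
        "step_start_pa": 20.0,
        "step_increment_pa": 20.0,
        "n_steps": 20,
        "noise_sd_mv": 0.0,
    },
    "cluster": {"k": 2, "n_iter": 200, "train_frac": 0.8},
    "genes": {
        # arms large enough that the |logFC| gate, not raw p alone, decides
        # the "not DE" criteria (see docs/methods.md)
        "cells_per_group": 8000,
        "n_genes": 150,
        "planted_lfc": 1.0,
        "target_cluster": "c1",
    },
}

_STAGE_ORDER = ["lfp", "ephys", "cluster", "genes"]


def _merge(base: dict, override: dict, path="") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ValueError(f"unknown config key: {path + k}")
        if isinstance(v, dict) and isinstance(base[k], dict):
            out[k] = _merge(base[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the requested stages in dependency order; return a summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    summary: dict = {"version": __version__, "seed": seed}

    for stage in config["stages"]:
        if stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage: {stage}")

    if "cluster" in config["stages"] and "ephys" not in config["stages"]:
        raise ValueError("stage 'cluster' requires upstream stage 'ephys'")

    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    features_df = None
    for stage in _STAGE_ORDER:
        if stage not in config["stages"]:
            continue
        if stage == "lfp":
            summary["lfp"] = _stage_lfp(config["lfp"], seed, outdir)
        elif stage == "ephys":
            features_df = _stage_ephys(config["ephys"], seed, outdir)
            summary["ephys"] = {"n_neurons": len(features_df)}
        elif stage == "cluster":
            summary["cluster"] = _stage_cluster(config["cluster"], seed, outdir,
                                                features_df)
        elif stage == "genes":
            summary["genes"] = _stage_genes(config["genes"], seed, outdir)

    (outdir / "run_log.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _stage_lfp(cfg: dict, seed: int, outdir: Path) -> dict:
    rng = stream(seed, "pipeline")
    rows = []
    for gt, rate in cfg["rate_per_min"].items():
        for m in range(cfg["n_per_genotype"]):
            n_events = int(round(rate * cfg["duration_s"] / 60.0))
            # evenly spaced onsets with jitter, guaranteed non-overlapping
            slots = np.linspace(1.0, cfg["duration_s"] - 1.0, max(n_events, 1))
            events = [
                (float(t + rng.uniform(-0.2, 0.2)), cfg["amplitude_sd"],
                 cfg["width_ms"], 1)
                for t in slots[:n_events]
            ]
            rec = simulate_lfp(LfpSimConfig(
                duration_s=cfg["duration_s"], fs_hz=cfg["fs_hz"],
                events=events, seed=int(rng.integers(2**31 - 1))))
            # already at analysis rate; high-pass only (no decimation/smoothing)
            rec = preprocess_lfp(rec, target_fs=None, smooth_ms=None)
            sd = estimate_baseline_sd(rec)
            evs = detect_iis(rec, sd, cfg["threshold_sd"], cfg["min_ms"], cfg["max_ms"])
            rr = iis_rate(evs, rec.activity_mask, rec.fs_hz, region="CA3")
            rows.append({"genotype": gt, "mouse": f"{gt}_{m}",
                         "planted_per_min": rate, "n_events": rr.n_events,
                         "rate_per_min": rr.rate})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "iis_rates.tsv", sep="\t", index=False)
    return {"mean_rate": df.groupby("genotype")["rate_per_min"].mean().to_dict()}


def _stage_ephys(cfg: dict, seed: int, outdir: Path) -> pd.DataFrame:
    rng = stream(seed, "pipeline")
    rows = []
    for i in range(cfg["n_neurons"]):
        hyper = i < cfg["n_neurons"] // 2
        r_in = rng.uniform(180, 260) if hyper else rng.uniform(100, 150)
        c_m = rng.uniform(70, 110) if hyper else rng.uniform(140, 220)
        params = NeuronModelParams(
            r_in_mohm=r_in, c_m_pf=c_m,
            v_thresh_mv=-50.0 if hyper else -46.0,
            noise_sd_mv=cfg["noise_sd_mv"], seed=int(rng.integers(2**31 - 1)))
        steps = simulate_current_clamp(params, StepProtocol(
            cfg["step_start_pa"], cfg["step_increment_pa"], cfg["n_steps"]))
        ramp = simulate_current_clamp(params, RampProtocol())
        passive = simulate_current_clamp(params, StepProtocol(-50.0, 0.0, 1))
        f = extract_features(steps, ramp, passive)
        rows.append({"cell_id": f"cell{i:03d}", "group": "hyper" if hyper else "normal",
                     "gain": f.gain, "rheobase": f.rheobase_pa,
                     "spike_latency": f.spike_latency_ms, "c_m": f.c_m_pf,
                     "r_in": f.r_in_mohm, "rmp": f.rmp_mv,
                     "true_r_in": r_in, "true_c_m": c_m})
    df = pd.DataFrame(rows)
    io.write_features(outdir / "features.tsv", df)
    return df


def _stage_cluster(cfg: dict, seed: int, outdir: Path, features: pd.DataFrame) -> dict:
    if features is None:
        raise ValueError("stage 'cluster' requires upstream stage 'ephys' output")
    fm = FeatureMatrix(features[CANONICAL_FEATURES].to_numpy(),
                       CANONICAL_FEATURES, groups=features[["group"]])
    z = zscore_features(fm)
    model = label_clusters(fit_kmeans(z, cfg["k"], seed=seed))
    stab = bootstrap_stability(z, cfg["k"], n_iter=cfg["n_iter"],
                               train_frac=cfg["train_frac"], seed=seed, model=model)
    memb = membership_residuals(model, z, retention=stab.retention_probability)
    out = features[["cell_id", "group"]].copy()
    out["cluster"] = memb.assigned_name
    out["residual"] = memb.residual
    out["retention_p"] = stab.retention_probability
    out.to_csv(outdir / "membership.tsv", sep="\t", index=False)
    (outdir / "model.json").write_text(json.dumps({
        "k": model.k, "centroids": model.centroids.tolist(),
        "features": model.feature_names,
        "labels": {str(k): v for k, v in model.cluster_names.items()},
        "mean_retention": stab.mean_retention, "stable": bool(stab.stable),
    }, indent=1))
    return {"mean_retention": stab.mean_retention, "stable": bool(stab.stable)}


def _stage_genes(cfg: dict, seed: int, outdir: Path) -> dict:
    planted, _ = standard_planted_patterns(cfg["planted_lfc"])
    sc = SynthCountConfig(n_genes=cfg["n_genes"],
                          cells_per_group=int(cfg["cells_per_group"]),
                          planted_genes=planted, gene_names=tuple(planted),
                          seed=seed)
    cm, meta = simulate_counts(sc)
    cm, meta = qc_filter(cm, meta, gene_lo=0, gene_hi=10**9, umi_lo=0, umi_hi=10**9,
                         mito_max=1.0)
    io.write_mtx(outdir / "counts", cm, meta)
    norm = lognormalize(cm)
    tables = standard_contrasts(norm, meta, cm.genes)
    for k, t in tables.items():
        t.table.to_csv(outdir / f"de_{k}.tsv", sep="\t", index=False)
    report = multilevel_filter(tables, cfg["target_cluster"])
    report.flags.to_csv(outdir / "candidate_flags.tsv", sep="\t")
    (outdir / "candidates.json").write_text(json.dumps({
        "target_cluster": report.target_cluster,
        "candidates": report.candidates,
        "successive_counts": report.successive_counts.to_dict(),
        "planted": sorted(planted),
    }, indent=1))
    return {"candidates": report.candidates, "planted": sorted(planted)}
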