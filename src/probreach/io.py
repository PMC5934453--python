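"""On-disk session format and the end-to-end pipeline.

A session directory holds a YAML manifest (condition, seed, workspace
and parameter values) plus plain CSV tables: reaches, kinematics,
spikes, neurons, and a separate ground-truth table for synthetic
sessions. The manifest seed reproduces the session exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import (Workspace, TaskParams, BehaviorParams, SessionData,
                   simulate_session)
from . import behavior as _behavior
from . import neurons as _neurons
from . import glm as _glm
from . import popmaps as _popmaps
from . import decoder as _decoder

__all__ = ["write_session", "read_session", "run_pipeline", "SchemaError"]

TABLES = ("reaches", "kinematics", "spikes", "neurons", "truth")


class SchemaError(ValueError):
    pass


def write_session(session: SessionData, path):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(session.manifest(), fh, sort_keys=True)
    for name in TABLES:
        df = getattr(session, name)
        if df is not None:
            df.to_csv(path / f"{name}.csv", index=False)
    return path


def read_session(path) -> SessionData:
    path = Path(path)
    mf = path / "manifest.yaml"
    if not mf.exists():
        raise SchemaError(f"missing manifest.yaml in {path}")
    with open(mf) as fh:
        man = yaml.safe_load(fh)
    session = SessionData(
        condition=man["condition"], seed=man["seed"],
        workspace=Workspace(**man["workspace"]),
        task_params=TaskParams(**man["task_params"]),
        behavior_params=BehaviorParams(**man["behavior_params"]),
    )
    for name in TABLES:
        f = path / f"{name}.csv"
        if f.exists():
            # round_trip parsing keeps write-read-write byte-identical
            setattr(session, name, pd.read_csv(f, float_precision="round_trip"))
    _validate(session)
    return session


def _validate(session: SessionData):
    if session.reaches is None:
        raise SchemaError("session has no reaches table")
    required = {"reach_id", "trial_id", "index_in_trial", "start_x", "start_y",
                "target_x", "target_y", "target_onset_time", "phi_p", "phi_t"}
    missing = required - set(session.reaches.columns)
    if missing:
        raise SchemaError(f"reaches table missing columns {sorted(missing)}")
    if session.kinematics is not None:
        t = session.kinematics["t_ms"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise SchemaError("kinematics times are not monotone")
    if session.spikes is not None and session.neurons is not None:
        known = set(session.neurons["neuron_id"])
        bad = set(session.spikes["neuron_id"]) - known
        if bad:
            raise SchemaError(
                f"spikes reference unknown neuron ids {sorted(bad)[:5]}")


def run_pipeline(config: dict, out_dir, stages=("simulate", "behavior", "glm",
                                                "maps", "decode")):
    """Run the requested stages end to end on one synthetic session.

    Config keys (all optional): seed, n_trials, condition ("baseline" or
    "vr"), task/behavior parameter overrides, population sizes, n_boot.
    Writes the session directory plus summary CSV/JSON files; returns a
    dict of the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    results = {}

    ws = Workspace(**config.get("workspace", {}))
    tpk = dict(config.get("task_params", {}))
    if config.get("condition") == "vr":
        tpk.setdefault("vr_rotation_deg", 30.0)
    tp = TaskParams(**tpk)
    bp = BehaviorParams(**config.get("behavior_params", {}))

    session = simulate_session(int(config.get("n_trials", 200)), ws, tp, bp,
                               rng=rng, seed=seed)
    results["session"] = session

    pop_cfg = config.get("population", {})
    if any(s in stages for s in ("glm", "maps", "decode")):
        specs = _neurons.make_population(rng=rng, **pop_cfg)
        pmap = _neurons.estimate_probability_map(
            tp, ws, n_samples=int(config.get("pmap_samples", 5000)), rng=rng)
        _neurons.synthesize_spikes(specs, session, pmap, rng=rng)
        results["pmap"] = pmap
    write_session(session, out / "session")

    valid, log = _behavior.filter_reaches(session)
    results["exclusions"] = log
    summary = {"seed": seed, "condition": session.condition,
               "exclusions": log}

    if "behavior" in stages:
        stats = _behavior.phi_statistics(valid)
        valid = _behavior.measure_latencies(session, valid)
        lat = _behavior.latency_analyses(valid, stats.phi_star)
        results["phi_stats"] = stats
        results["latency"] = lat
        summary["phi_star"] = stats.phi_star
        summary["phi_resultant"] = stats.resultant
        summary["latency_r"] = lat["r"]
        summary["latency_p"] = lat["p"]
        valid.to_csv(out / "valid_reaches.csv", index=False)

    if "glm" in stages:
        table = _glm.classify_population(
            session, valid, rng=rng, n_boot=int(config.get("n_boot", 200)))
        table.to_csv(out / "neuron_classes.csv", index=False)
        results["classes"] = table
        summary["n_pr"] = int((table["label"] == "PR").sum())
        summary["n_sr"] = int((table["label"] == "SR").sum())

    if "maps" in stages and "classes" in results:
        pr_ids = results["classes"].loc[
            results["classes"]["label"] == "PR", "neuron_id"].tolist()
        cov = _glm.reach_covariates(session, valid)
        ce = _glm.spike_counts(session, valid, _glm.EARLY_WINDOW, pr_ids)
        cl = _glm.spike_counts(session, valid, _glm.LATE_WINDOW, pr_ids)
        pds = {}
        for nid in pr_ids:
            fit = _glm.estimate_pd(cl[nid], cov)
            if fit.reliable:
                pds[nid] = fit.phi_star
        if len(pds) >= 10:
            prof = _popmaps.relative_position_profile(session, valid, pds,
                                                      rng=rng)
            summary["profile_peak"] = prof.peak_angle
            xs, ys, m, p, r = _popmaps.summed_rotated_maps(
                session, valid, pds, results["pmap"])
            summary["summed_map_r"] = r
            results["profile"] = prof
        results["pds"] = pds

    if "decode" in stages:
        tunings = _decoder.fit_session_tunings(
            session, valid, rng=rng,
            n_boot=int(config.get("n_boot_decoder", 200)))
        results["tunings"] = tunings
        if tunings:
            stats = results.get("phi_stats") or _behavior.phi_statistics(valid)
            if "latency_ms" not in valid.columns:
                valid = _behavior.measure_latencies(session, valid)
            ana = _decoder.decoded_phi_analysis(session, valid, tunings,
                                                stats.phi_star, rng=rng)
            ana["decode_table"].to_csv(out / "decoded_reaches.csv", index=False)
            summary["decoded_phi_mean"] = ana["circ_mean"]
            results["decode"] = ana

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return results
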