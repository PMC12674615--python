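"""End-to-end runs: behavior scoring, photometry analysis, manifests.

Each run consumes a single config mapping (usually loaded from YAML),
writes plain CSV/JSON artifacts into an output directory, and records a
manifest listing every output with a content hash, the config hash, the
package version, and every exclusion the stages reported (dropped TTLs,
excluded bodyparts, unusable trials).  Runs are deterministic: the same
config and seed produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import photometry as phot
from . import pose, protocol, simulate, stats
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

_BUILDERS = {
    "habituation": protocol.build_habituation_schedule,
    "preconditioning": protocol.build_preconditioning_schedule,
    "conditioning": protocol.build_conditioning_schedule,
    "probe": protocol.build_probe_schedule,
}

# Fixed CSV float format so reruns are byte-identical across platforms.
_CSV_KW = {"index": False, "float_format": "%.10g"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    return cfg


def schedule_from_config(entry: dict) -> protocol.SessionSchedule:
    """Build a schedule from {'builder': ..., 'params': {...}}, a YAML path, or a full dict."""
    if "path" in entry:
        return protocol.SessionSchedule.from_yaml(entry["path"])
    if "builder" in entry:
        builder = _BUILDERS.get(entry["builder"])
        if builder is None:
            raise InvalidParameterError(
                f"unknown schedule builder {entry['builder']!r}; have {sorted(_BUILDERS)}"
            )
        return builder(**entry.get("params", {}))
    return protocol.SessionSchedule.from_dict(entry)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: dict, outputs: list[Path], notes: dict) -> Path:
    manifest = {
        "spckit_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        "exclusions_and_warnings": notes,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_spc_behavior(config: dict, outdir) -> dict:
    """Score freezing for a cohort and run the OFF/ON statistics.

    Config keys: ``schedule`` (builder mapping), ``fps``, ``px_per_cm``,
    ``freezing`` (FreezingParams fields), ``bin_s``, and either
    ``animals`` (list of {animal_id, group, pose_csv}) or ``simulate``
    ({n_per_group, immobile_fraction_off, immobile_fraction_on, seed}).
    Writes freezing_by_epoch.csv, binned_freezing.csv,
    stats_results.csv and manifest.json; returns the result tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = schedule_from_config(config["schedule"])
    fps = float(config.get("fps", 25.0))
    px_per_cm = float(config.get("px_per_cm", 30.0))
    params = pose.FreezingParams(**config.get("freezing", {}))
    bin_s = float(config.get("bin_s", 10.0))
    notes: dict = {}

    tracks: list[tuple[str, str, pose.PoseTrack]] = []
    if "animals" in config:
        for entry in config["animals"]:
            track = pose.read_pose_csv(entry["pose_csv"], fps=fps, px_per_cm=px_per_cm)
            tracks.append((entry["animal_id"], entry.get("group", "paired"), track))
    elif "simulate" in config:
        sim = config["simulate"]
        seed = int(sim.get("seed", config.get("seed", 0)))
        animal = 0
        for group, n in sim.get("n_per_group", {"paired": 4}).items():
            for _ in range(int(n)):
                animal += 1
                f_off = float(sim.get("immobile_fraction_off", 0.15))
                f_on = float(
                    sim.get("immobile_fraction_on", {}).get(group, f_off)
                    if isinstance(sim.get("immobile_fraction_on"), dict)
                    else sim.get("immobile_fraction_on", f_off)
                )
                # piecewise truth: OFF epochs at f_off, ON epochs at f_on
                intervals: list[tuple[float, float]] = []
                rng_seed = seed + 1000 * animal
                for i, ep in enumerate(schedule.epochs):
                    frac = f_on if ep.kind == "ON" else f_off
                    sub = simulate.make_behavior_truth(
                        ep.duration_s, frac, seed=rng_seed + i, fps=fps
                    )
                    intervals.extend(
                        (s + ep.start_s, e + ep.start_s) for s, e in sub.bout_intervals_s
                    )
                truth = simulate.BehaviorGroundTruth(
                    tuple(intervals), schedule.total_duration_s
                )
                track, _ = simulate.simulate_pose_track(
                    schedule, truth, fps=fps, px_per_cm=px_per_cm, seed=rng_seed
                )
                tracks.append((f"m{animal:03d}", group, track))
    else:
        raise InvalidParameterError("config needs 'animals' or 'simulate'")

    epoch_rows, bin_rows = [], []
    for animal_id, group, track in tracks:
        series = pose.score_track(track, params)
        for epoch in schedule.epochs:
            epoch_rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "phase": schedule.phase,
                    "epoch_label": epoch.label,
                    "epoch_kind": epoch.kind,
                    "percent_freezing": pose.percent_freezing(series, epoch),
                }
            )
        binned = pose.binned_freezing(series, bin_s, schedule.total_duration_s)
        binned.insert(0, "animal_id", animal_id)
        binned.insert(1, "group", group)
        bin_rows.append(binned)

    by_epoch = pd.DataFrame(epoch_rows)
    binned_all = pd.concat(bin_rows, ignore_index=True)

    # planned ON vs OFF comparison per group, BH-corrected jointly
    kind_table = (
        by_epoch[by_epoch.epoch_kind.isin(["OFF", "ON"])]
        .groupby(["animal_id", "group", "epoch_kind"], as_index=False)["percent_freezing"]
        .mean()
        .rename(columns={"epoch_kind": "epoch", "percent_freezing": "value"})
    )
    results = []
    if set(kind_table.epoch) == {"OFF", "ON"}:
        raw = []
        for group, sub in kind_table.groupby("group"):
            res = stats.gamma_glm_contrasts(
                sub,
                contrasts=[(f"{group}: ON vs OFF", "C(epoch)[T.ON] = 0")],
                formula="value ~ C(epoch)",
                zero_offset=float(config.get("zero_offset", 0.1)),
            )
            raw.append(res[0])
        adjusted = stats.bh_fdr([r.p_value for r in raw])
        results = [
            stats.TestResult(r.name, r.statistic, r.p_value, adj, r.df)
            for r, adj in zip(raw, adjusted)
        ]
    stats_table = stats.results_to_frame(results)

    outputs = []
    for name, table in (
        ("freezing_by_epoch.csv", by_epoch),
        ("binned_freezing.csv", binned_all),
        ("stats_results.csv", stats_table),
    ):
        p = outdir / name
        table.to_csv(p, **_CSV_KW)
        outputs.append(p)
    notes["n_animals"] = len(tracks)
    _write_manifest(outdir, config, outputs, notes)
    return {"by_epoch": by_epoch, "binned": binned_all, "stats": stats_table}


def run_photometry(config: dict, outdir) -> dict:
    """ΔF/F, PETHs and per-trial summaries for one or more sessions.

    Config keys: ``sessions`` (list of {session_id, rec_csv, ttl_csv}
    or {session_id, simulate: {...}}), ``schedule`` (optional; onsets
    default to each recording's own TTLs), and pipeline parameters
    (trim_s, despike_window, despike_n_mad, zscore, window_s,
    smooth_s, threshold).  Writes peth_mean.csv, trial_summary.csv,
    session_summary.csv and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trim_s = float(config.get("trim_s", 60.0))
    window_s = tuple(config.get("window_s", (-5.0, 10.0)))
    smooth_s = config.get("smooth_s")
    threshold = float(config.get("threshold", 2.0))
    notes: dict = {"dropped_onsets": {}}

    schedule = (
        schedule_from_config(config["schedule"]) if "schedule" in config else None
    )
    peth_frames, trial_rows, session_rows = [], [], []
    for sess in config["sessions"]:
        sid = sess["session_id"]
        if "simulate" in sess:
            sim = dict(sess["simulate"])
            seed = int(sim.pop("seed", config.get("seed", 0)))
            fs = float(sim.pop("fs", 100.0))
            if schedule is None:
                raise InvalidParameterError("simulated sessions need a schedule")
            truth = simulate.PhotometryGroundTruth(**sim)
            if not truth.transient_times_s:
                # default: 4x-noise-sd transients at every CS onset
                onsets = tuple(
                    ev.onset_s for ev in schedule.events if ev.modality != "shock"
                )
                truth = truth.with_amplitudes_in_noise_units(
                    tuple([4.0] * len(onsets)),
                    onsets,
                    trim_s=trim_s,
                    duration_s=schedule.total_duration_s,
                )
            rec, truth = simulate.simulate_photometry(schedule, truth, fs=fs, seed=seed)
        else:
            rec = phot.read_photometry_csv(sess["rec_csv"], sess.get("ttl_csv"))
        if len(rec.ttl_times_s) == 0:
            raise phot.EmptyPETHError(f"session {sid!r}: no TTL onsets")
        dff = phot.process_recording(
            rec,
            trim_s=trim_s,
            despike_window=int(config.get("despike_window", 11)),
            despike_n_mad=float(config.get("despike_n_mad", 5.0)),
            zscore=config.get("zscore", "whole-trace"),
        )
        onsets = rec.ttl_times_s
        peth = phot.build_peth(dff, onsets, window_s=window_s, smooth_s=smooth_s)
        notes["dropped_onsets"][sid] = int(len(onsets) - peth.n_trials)
        summary = phot.peak_response(peth, threshold=threshold)
        mean_df = pd.DataFrame(
            {"session_id": sid, "time_s": peth.time_s, "mean": peth.mean, "sem": peth.sem}
        )
        peth_frames.append(mean_df)
        tdf = summary.to_frame()
        tdf.insert(0, "session_id", sid)
        trial_rows.append(tdf)
        session_rows.append(
            {
                "session_id": sid,
                "n_trials": peth.n_trials,
                "n_suprathreshold": summary.n_suprathreshold,
                "mean_peak_post": float(np.mean(summary.peak_post)),
                "mean_peak_baseline": float(np.mean(summary.peak_baseline)),
            }
        )

    outputs = []
    for name, table in (
        ("peth_mean.csv", pd.concat(peth_frames, ignore_index=True)),
        ("trial_summary.csv", pd.concat(trial_rows, ignore_index=True)),
        ("session_summary.csv", pd.DataFrame(session_rows)),
    ):
        p = outdir / name
        table.to_csv(p, **_CSV_KW)
        outputs.append(p)
    _write_manifest(outdir, config, outputs, notes)
    return {
        "session_summary": pd.DataFrame(session_rows),
        "trial_summary": pd.concat(trial_rows, ignore_index=True),
    }


def run_stats_table(table: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Run the configured GLM contrasts on a tidy measurement table.

    ``design`` carries ``formula`` (default ``value ~ C(group) *
    C(epoch)``) and ``contrasts`` as a list of {name, constraint}.
    """
    contrasts = [
        (c["name"], c["constraint"]) if isinstance(c, dict) else (c, c)
        for c in design.get("contrasts", [])
    ]
    if not contrasts:
        raise InvalidParameterError("design lists no contrasts")
    results = stats.gamma_glm_contrasts(
        table,
        contrasts=contrasts,
        formula=design.get("formula", "value ~ C(group) * C(epoch)"),
        zero_offset=design.get("zero_offset"),
    )
    return stats.results_to_frame(results)
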