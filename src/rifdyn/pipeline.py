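"""End-to-end orchestration: simulate -> detect -> track -> kinetics/mobility.

Thin glue over the analysis modules; every stage reads and writes the plain
CSV/TIFF artifacts defined in :mod:`rifdyn.io`, so each can also be run in
isolation (or replaced by real recordings of the same shape).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, io, kinetics, mobility, simulate, track


def simulate_to_dir(config: simulate.SimulationConfig, outdir) -> dict:
    """Simulate an experiment and write movies, sidecars and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate.simulate_experiment(config)
    movie_paths = []
    for nid, stack in enumerate(result.movies):
        p = outdir / f"{config.condition}_nucleus{nid:03d}.tif"
        io.write_movie(stack, result.metadata(nid), p)
        movie_paths.append(p)
    truth_path = outdir / f"{config.condition}_truth.csv"
    result.truth.to_csv(truth_path, index=False, float_format="%.10g")
    return {"movies": movie_paths, "truth": truth_path, "result": result}


def detect_movies(movie_paths, params: detect.DetectionParams = detect.DetectionParams(),
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and detect across a list of single-nucleus movies."""
    nuc_frames, obs_frames = [], []
    for p in movie_paths:
        stack, meta = io.read_movie(p)
        nuclei, obs = detect.process_movie(stack, meta, params)
        nuc_frames.append(nuclei)
        if len(obs):
            obs_frames.append(obs)
    nuclei = pd.concat(nuc_frames, ignore_index=True)
    if obs_frames:
        observations = pd.concat(obs_frames, ignore_index=True)
    else:
        observations = detect.process_movie(
            np.zeros((0, 1, 1)), {"pixel_size_nm": 100.0,
                                  "recording_start_offset_min": 0.0})[1]
    observations = observations.astype({"nucleus_id": int, "frame": int})
    return nuclei, observations


def analyse_condition(nuclei: pd.DataFrame, observations: pd.DataFrame,
                      condition: str, frame_interval_s: float = 60.0,
                      max_step_nm: float = track.DEFAULT_MAX_STEP_NM,
                      max_gap: int = track.DEFAULT_MAX_GAP) -> dict:
    """Track foci and compute the per-condition kinetics and mobility outputs."""
    n_nuclei = int(nuclei["nucleus_id"].nunique())
    corrected = track.com_correct(observations, nuclei)
    tracks = track.link_tracks(corrected, max_step_nm, max_gap)
    out: dict = {
        "condition": condition,
        "tracks": tracks,
        "frequency": kinetics.focus_frequency_series(observations, n_nuclei,
                                                     condition=condition),
        "total_intensity": kinetics.total_intensity_series(observations, nuclei, condition),
        "relative_intensity": kinetics.relative_intensity_series(observations, nuclei,
                                                                 condition),
    }
    try:
        curve = mobility.compute_msd(track.filter_tracks(tracks),
                                     frame_interval_s=frame_interval_s,
                                     condition=condition)
        out["msd"] = curve
        out["subdiffusion"] = mobility.fit_subdiffusion(curve)
    except (mobility.MsdError, mobility.FitFailureError) as err:
        out["msd"] = None
        out["subdiffusion"] = None
        out["mobility_error"] = str(err)
    for label, window in (("early", kinetics.EARLY_WINDOW), ("late", kinetics.LATE_WINDOW)):
        try:
            out[f"area_{label}"] = kinetics.area_window_fit(observations, window)
        except kinetics.KineticsError:
            out[f"area_{label}"] = None
    return out


def run_all(run_config: io.RunConfig) -> dict:
    """Run every configured condition end to end and write a report bundle."""
    outdir = Path(run_config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    det_params = detect.DetectionParams(**run_config.detect)
    results: dict[str, dict] = {}
    for i, condition in enumerate(run_config.conditions):
        cfg = simulate.make_condition_preset(
            condition, n_nuclei=run_config.n_nuclei, n_frames=run_config.n_frames,
            seed=(run_config.seed * 1000 + i) % 2**31, **run_config.simulate)
        sim = simulate_to_dir(cfg, outdir / "movies")
        nuclei, observations = detect_movies(sim["movies"], det_params)
        res = analyse_condition(nuclei, observations, condition,
                                frame_interval_s=cfg.frame_interval_s,
                                **run_config.track)
        io.write_observations_csv(observations, outdir / f"{condition}_observations.csv")
        io.write_tracks_csv(res["tracks"], outdir / f"{condition}_tracks.csv")
        res["frequency"].to_frame().to_csv(
            outdir / f"{condition}_frequency.csv", index=False, float_format="%.10g")
        if res["msd"] is not None:
            res["msd"].to_frame().to_csv(
                outdir / f"{condition}_msd.csv", index=False, float_format="%.10g")
        results[condition] = res

    fits = {c: r["subdiffusion"].to_dict()
            for c, r in results.items() if r.get("subdiffusion") is not None}
    with open(outdir / "subdiffusion_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    if {"alpha", "gamma", "control"} <= set(results):
        pred = kinetics.additivity_prediction(
            results["alpha"]["frequency"], results["gamma"]["frequency"],
            results["control"]["frequency"])
        pred.to_frame().to_csv(outdir / "predicted_additive_frequency.csv",
                               index=False, float_format="%.10g")
        results["predicted_additive"] = {"frequency": pred}

    if run_config.plots:
        from . import report
        report.render_report(results, outdir)
    return results
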