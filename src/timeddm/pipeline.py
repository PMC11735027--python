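"""End-to-end synthetic pipeline: synthesis -> behavior -> ephys -> decoding -> DDM.

Each stage writes plain delimited text and records its inputs, seed,
and output hashes in a manifest, so a rerun with the same configuration
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import ddm as dd
from . import decoding as dec
from . import ephys as ep
from . import synth as syn
from .config import RunConfig, stage_seed

log = logging.getLogger("timeddm")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest (also written to ``manifest.json``).  Stage
    failures abort with the stage name; outputs of completed stages are
    retained.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or cfg["stages"])
    order = [s for s in ["synth", "behavior", "ddm", "ephys", "decode"]
             if s in stages]
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    state: dict = {}
    for stage in order:
        seed = stage_seed(cfg.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _STAGES[stage](cfg, seed, out, state)
        except Exception as exc:
            manifest["stages"][stage] = {"seed": seed, "error": str(exc)}
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_synth(cfg: RunConfig, seed: int, out: Path, state: dict
                 ) -> list[Path]:
    s = cfg["synth"]
    spec = syn.SynthBehaviorSpec(n_trials=int(s["n_trials"]),
                                 gamma_shape=s["gamma_shape"],
                                 gamma_rate=s["gamma_rate"],
                                 p_long=s["p_long"], seed=seed)
    events = syn.gen_event_log(spec)
    state["events"] = events
    p = out / "events.csv"
    _write(events, p)

    d = cfg["ddm"]
    run = dd.simulate_batch(dd.DDMParams(
        F=d["F"], b=d["b"], D=d["D"], sigma=d["sigma"], dt=d["dt"],
        t_max=d["t_max"], n_sims=max(int(d["n_sims"]),
                                     4 * int(s["n_ensemble_trials"])),
        seed=seed + 1, store_trajectories=True))
    ens = syn.gen_ensemble_ddm_linked(
        syn.SynthEnsembleSpec(n_units=int(s["n_units"]),
                              n_trials=int(s["n_ensemble_trials"]),
                              seed=seed + 2), run)
    state["ensemble"] = ens
    p2 = out / "ensemble_spikes.csv"
    _write(ens.to_frame(), p2)
    p3 = out / "ensemble_truth.csv"
    _write(pd.DataFrame({"trial": np.arange(ens.n_trials),
                         "switch_time_s": ens.t_star}), p3)
    return [p, p2, p3]


def _stage_behavior(cfg: RunConfig, seed: int, out: Path, state: dict
                    ) -> list[Path]:
    events = state.get("events")
    if events is None:
        events = pd.read_csv(out / "events.csv")
    records = beh.extract_switch_times(events)
    state["records"] = records
    p = out / "switch_records.csv"
    _write(records, p)
    fit = beh.fit_behavior_gamma(records["switch_time_s"].to_numpy())
    p2 = out / "behavior_gamma.csv"
    _write(pd.DataFrame([{"alpha": fit.alpha, "beta": fit.beta,
                          "mu": fit.mu, "cv": fit.cv, "r2": fit.r2,
                          "n": fit.n}]), p2)
    return [p, p2]


def _stage_ddm(cfg: RunConfig, seed: int, out: Path, state: dict
               ) -> list[Path]:
    d = cfg["ddm"]
    params = dd.DDMParams(F=d["F"], b=d["b"], D=d["D"], sigma=d["sigma"],
                          dt=d["dt"], t_max=d["t_max"],
                          n_sims=int(d["n_sims"]), seed=seed)
    run = dd.simulate_batch(params)
    p = out / "ddm_run.csv"
    _write(pd.DataFrame({"trial": np.arange(params.n_sims),
                         "switch_time_s": run.times,
                         "censored": run.censored}), p)
    fit = dd.fit_gamma(run.switch_times)
    r2 = dd.gamma_sample_r2(run.switch_times, fit, t_max=params.t_max)
    mu_s, cv_s = dd.summary_stats(params, n_repeats=int(d["n_repeats"]))
    p2 = out / "ddm_gamma.csv"
    _write(pd.DataFrame([{"alpha": fit.alpha, "beta": fit.beta,
                          "mu": fit.mu, "cv": fit.cv, "r2": r2,
                          "mu_S": mu_s, "cv_S": cv_s,
                          "threshold": params.threshold}]), p2)
    return [p, p2]


def _stage_ephys(cfg: RunConfig, seed: int, out: Path, state: dict
                 ) -> list[Path]:
    events = state.get("events")
    if events is None:
        events = pd.read_csv(out / "events.csv")
    # Reconstruct session-time trial starts from an assumed 30-s spacing:
    # the synthetic event log is trial-relative, so lay trials end to end.
    n_trials = events["trial_id"].nunique()
    trial_starts = np.arange(n_trials) * 30.0
    span = float(n_trials * 30.0)

    units = syn.gen_unit_population(n_msn=20, n_fsi=4, seed=seed)
    pcfg = ep.PETHConfig(**{
        "window": tuple(cfg["peth"]["window"]),
        "bin_width": cfg["peth"]["bin_width"],
        "bandwidth": cfg["peth"]["bandwidth"],
        "zscore": cfg["peth"]["zscore"],
        "analysis_interval": tuple(cfg["peth"]["analysis_interval"]),
    })
    rows, peths, slopes = [], [], []
    for u in units:
        st = syn.gen_ramping_unit(u, trial_starts, span)
        peth = ep.compute_peth(st, trial_starts, pcfg, unit_id=u.unit_id)
        peths.append(peth)
        fit = ep.glm_ramp_slope(st, trial_starts, unit_id=u.unit_id)
        slopes.append((u.unit_id, u.ramp_slope, fit.slope))
        rows.extend((u.unit_id, t, r) for t, r in
                    zip(peth.bin_centers_s, peth.rate))
    p = out / "peth.csv"
    _write(pd.DataFrame(rows, columns=["unit_id", "time_s", "zrate"]), p)
    pca = ep.pca_ensemble(peths,
                          tuple(cfg["peth"]["analysis_interval"]))
    p2 = out / "pca_scores.csv"
    _write(pd.DataFrame({"unit_id": [u.unit_id for u in units],
                         "pc1_score": pca.scores[:, 0],
                         "pc1_explained": pca.explained_fraction[0]}), p2)
    p3 = out / "slopes.csv"
    _write(pd.DataFrame(slopes,
                        columns=["unit_id", "true_slope", "glm_slope"]), p3)
    state["peths"] = peths
    return [p, p2, p3]


def _stage_decode(cfg: RunConfig, seed: int, out: Path, state: dict
                  ) -> list[Path]:
    ens = state.get("ensemble")
    if ens is None:
        raise RuntimeError("decode stage requires the synth stage")
    r = cfg["readout"]
    rcfg = dec.ReadoutConfig(kernel_w=r["kernel_w"],
                             grid_step=r["grid_step"],
                             threshold=r["threshold"],
                             accuracy_window=r["accuracy_window"],
                             ridge_c=r["ridge_c"], horizon=r["horizon"])
    fit = dec.fit_readout(ens, rcfg)
    surr = syn.gen_poisson_matched_surrogate(ens, seed=seed)
    fit_s = dec.fit_readout(surr, rcfg)
    p = out / "readout.csv"
    _write(pd.DataFrame({
        "trial": np.arange(ens.n_trials),
        "t_true": fit.t_true, "t_pred": fit.t_pred,
        "accurate": (np.abs(fit.t_pred - fit.t_true)
                     <= rcfg.accuracy_window)}), p)
    p2 = out / "readout_summary.csv"
    _write(pd.DataFrame([{"accuracy": fit.accuracy,
                          "surrogate_accuracy": fit_s.accuracy}]), p2)

    dcfg = dec.DecoderConfig(
        bin_width_s=cfg["decoder"]["bin_width_s"],
        window=tuple(cfg["decoder"]["window"]),
        min_trials_per_unit=min(int(cfg["decoder"]["min_trials_per_unit"]),
                                ens.n_trials - 1),
        rate_floor=cfg["decoder"]["rate_floor"])
    res = dec.bayes_decode_loocv(ens, dcfg)
    r2 = dec.decode_r2_by_epoch(res)
    p3 = out / "decode_r2.csv"
    _write(r2, p3)
    return [p, p2, p3]


_STAGES = {
    "synth": _stage_synth,
    "behavior": _stage_behavior,
    "ddm": _stage_ddm,
    "ephys": _stage_ephys,
    "decode": _stage_decode,
}
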