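"""End-to-end reproduction drivers.

Each study preset runs the training / evaluation / analysis chain for one
figure-level result and returns (and optionally writes) summary tables,
deterministic given the seed list.  ``scale='scaled'`` uses the fast
preset (blocks of 10, 2,000 trials); ``'full'`` uses the animal-protocol
schedule (blocks of 25, 10,000 trials).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import demixing as dmx
from . import generalization as gen
from .agents import AgentConfig
from .behavior import (collect_episodes, occupancy_profile, behavior_error,
                       q_profile, scripted_reference_profile)
from .maze import PerturbationSpec, SUBTASKS, configure_maze
from .spatial import build_rate_map, metric_table
from .training import (FULL_PRESET, SCALED_PRESET, build_schedule, train,
                       evaluate, subtask_success, block_success)

PRESETS = ("fig2_performance", "fig3_demixing", "fig4_behavior",
           "fig5_spatial", "fig6_qvalues", "fig7_stochastic",
           "fig8_generalization")


def _schedule(scale: str):
    if scale == "full":
        p = FULL_PRESET
    elif scale == "desk":
        from .studies import DESK_PRESET
        p = DESK_PRESET
    else:
        p = SCALED_PRESET
    return build_schedule(total_trials=p["total_trials"],
                          block_size=p["block_size"])


def _train_pair(scale: str, seeds, perturbation=None):
    """Train hcDRQN and hcDQN across seeds; returns {arch: [TrainResult]}."""
    sched = _schedule(scale)
    out = {}
    for arch in ("recurrent", "feedforward"):
        cfg = AgentConfig(architecture=arch)
        out[arch] = [train(cfg, sched, seed=s, perturbation=perturbation)
                     for s in seeds]
    return out


def _eval_table(results, n_trials, seed, perturbation=None) -> pd.DataFrame:
    rows = []
    for arch, runs in results.items():
        cfg = AgentConfig(architecture=arch)
        for i, res in enumerate(runs):
            rates = evaluate(cfg, res.final, n_trials, seed + i,
                             perturbation=perturbation)
            for label, rate in rates.items():
                rows.append({"model": arch, "seed_index": i,
                             "subtask": label, "success": rate})
    return pd.DataFrame(rows)


def reproduce(study_preset: str, scale: str = "scaled", seeds=(0, 1, 2),
              out_dir: Optional[str] = None, n_eval: int = 50) -> dict:
    """Run one study preset; returns a dict of result tables."""
    if study_preset not in PRESETS:
        raise ValueError(f"unknown preset {study_preset!r}; "
                         f"choose from {PRESETS}")
    if scale not in ("full", "desk", "scaled"):
        raise ValueError("scale must be 'full', 'desk' or 'scaled'")
    fn = globals()["_run_" + study_preset]
    tables = fn(scale, list(seeds), n_eval)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"{study_preset}_{name}.tsv", sep="\t",
                       index=False)
        manifest = {"preset": study_preset, "scale": scale,
                    "seeds": list(seeds), "n_eval": n_eval,
                    "tables": sorted(tables),
                    "config_hash": hashlib.sha256(
                        json.dumps([study_preset, scale, list(seeds),
                                    n_eval]).encode()).hexdigest()[:16]}
        (out / f"{study_preset}_manifest.json").write_text(
            json.dumps(manifest, indent=1))
    return tables


def _run_fig2_performance(scale, seeds, n_eval):
    results = _train_pair(scale, seeds)
    rows = []
    for arch, runs in results.items():
        for i, res in enumerate(runs):
            for label, rate in subtask_success(res.log).items():
                rows.append({"model": arch, "seed_index": i,
                             "subtask": label, "train_success": rate})
    curves = []
    for arch, runs in results.items():
        for i, res in enumerate(runs):
            bs = block_success(res.log)
            bs["model"] = arch
            bs["seed_index"] = i
            curves.append(bs)
    return {"train_success": pd.DataFrame(rows),
            "block_curves": pd.concat(curves, ignore_index=True),
            "eval_success": _eval_table(results, n_eval, seed=1000)}


def _run_fig3_demixing(scale, seeds, n_eval):
    sched = _schedule(scale)
    cfg = AgentConfig(architecture="recurrent")
    rows = []
    for i, s in enumerate(seeds):
        res = train(cfg, sched, seed=s)
        snap = res.intermediate if res.intermediate is not None else res.final
        ds = dmx.record_activations(cfg, snap, n_per_subtask=60,
                                    seed=2000 + i, eps=0.05)
        data = dmx.fill_missing(dmx.align_and_bin(ds))
        cs = dmx.fit_demixed(data)
        for m in dmx.MARGINALIZATIONS:
            rows.append({"seed_index": i, "marginalization": m,
                         "variance_fraction": cs.marginal_fractions[m],
                         "combined_explained": cs.combined_explained(m)})
    return {"variance_fractions": pd.DataFrame(rows)}


def _run_fig4_behavior(scale, seeds, n_eval):
    results = _train_pair(scale, seeds)
    layout = configure_maze()
    rows = []
    for arch, runs in results.items():
        cfg = AgentConfig(architecture=arch)
        for i, res in enumerate(runs):
            for trial in SUBTASKS:
                eps_ = collect_episodes(cfg, res.final, trial, n_eval,
                                        seed=3000 + i)
                prof = occupancy_profile(eps_, layout, trial)
                ref = scripted_reference_profile(layout, trial)
                err = (behavior_error(prof, ref)
                       if np.isfinite(prof.ratios).all() else np.nan)
                rows.append({"model": arch, "seed_index": i,
                             "subtask": trial.label, "behavior_error": err,
                             **{f"ratio_{k}": r
                                for k, r in enumerate(prof.ratios)}})
    return {"state_ratios": pd.DataFrame(rows)}


def _run_fig5_spatial(scale, seeds, n_eval):
    results = _train_pair(scale, seeds)
    layout = configure_maze()
    rows = []
    for arch, runs in results.items():
        cfg = AgentConfig(architecture=arch)
        for i, res in enumerate(runs):
            from .training import make_agent, run_trial
            from .maze import TMazeEnv
            agent = make_agent(cfg, res.final)
            env = TMazeEnv(rng=np.random.default_rng(4100 + i))
            rng = np.random.default_rng(4200 + i)
            pos_all, act_all = [], []
            for trial in SUBTASKS:
                for _ in range(n_eval // 4 or 1):
                    rec = {}
                    run_trial(agent, env, trial, 0.05, rng, learn=False,
                              record=rec)
                    pos_all.extend(rec["positions"][1:])
                    act_all.extend(rec["ca1"])
            rm = build_rate_map(pos_all, np.asarray(act_all), layout.shape)
            mt = metric_table(rm)
            mt["model"] = arch
            mt["seed_index"] = i
            rows.append(mt)
    return {"place_metrics": pd.concat(rows, ignore_index=True)}


def _run_fig6_qvalues(scale, seeds, n_eval):
    results = _train_pair(scale, seeds)
    rows = []
    for arch, runs in results.items():
        cfg = AgentConfig(architecture=arch)
        for i, res in enumerate(runs):
            for trial in SUBTASKS:
                qp = q_profile(cfg, res.final, trial)
                for k in range(len(qp.path)):
                    rows.append({"model": arch, "seed_index": i,
                                 "subtask": trial.label, "state": k,
                                 "mean_q": qp.mean_q[k],
                                 "rel_var": qp.rel_var[k]})
    return {"q_profiles": pd.DataFrame(rows)}


def _run_fig7_stochastic(scale, seeds, n_eval):
    sched = _schedule(scale)
    cfg = AgentConfig(architecture="recurrent")
    det = [train(cfg, sched, seed=s) for s in seeds]
    prob = [train(cfg, sched, seed=s + 500,
                  perturbation=PerturbationSpec("probabilistic_cues",
                                                cue_prob=0.8))
            for s in seeds]
    rows = []
    for name, runs in (("deterministic", det), ("prob0.8", prob)):
        for i, res in enumerate(runs):
            tbl = gen.evaluate_variants(cfg, res.final, gen.cue_prob_grid(),
                                        n_eval, seed=5000 + i)
            tbl["training"] = name
            tbl["seed_index"] = i
            rows.append(tbl)
    return {"cue_probability": pd.concat(rows, ignore_index=True)}


def _run_fig8_generalization(scale, seeds, n_eval):
    results = _train_pair(scale, seeds)
    variants = (gen.corridor_grid() + gen.cue_removal_grid()
                + gen.distractor_variant() + gen.noise_grid())
    rows = []
    for arch, runs in results.items():
        cfg = AgentConfig(architecture=arch)
        for i, res in enumerate(runs):
            tbl = gen.evaluate_variants(cfg, res.final, variants, n_eval,
                                        seed=6000 + i)
            tbl["model"] = arch
            tbl["seed_index"] = i
            rows.append(tbl)
    return {"variants": pd.concat(rows, ignore_index=True)}
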