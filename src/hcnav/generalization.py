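"""Inference-time and training-time robustness battery.

Evaluates trained checkpoints greedily (learning off) across the
generalization grids: longer start corridors, cue-removal subsets, a
distractor cue, Gaussian cue noise, and per-step probabilistic cue
visibility.
"""

from __future__ import annotations

from itertools import combinations
import numpy as np
import pandas as pd

from . import maze
from .maze import (PerturbationSpec, CUE_CODES, SUBTASKS, configure_maze,
                   TMazeEnv)
from .training import evaluate, make_agent, run_trial

CORRIDOR_GRID = (4, 8, 12, 16, 20, 24, 28, 32)
NOISE_GRID = tuple(range(1, 16, 2))
CUE_PROB_GRID = tuple(round(p, 1) for p in np.arange(1.0, 0.05, -0.1))


def _eval_perturbed(config, snapshot, perturbation, n_trials, seed,
                    subtasks=SUBTASKS, view_mode="3x3") -> dict:
    if perturbation is not None and perturbation.kind == "corridor_length":
        # longer maze: rebuild the layout, episode cap scales with it
        agent = make_agent(config, snapshot)
        layout = configure_maze(perturbation=perturbation)
        ss = np.random.SeedSequence(seed)
        env_seed, explore_seed = ss.spawn(2)
        env = TMazeEnv(layout=layout, view_mode=view_mode,
                       rng=np.random.default_rng(env_seed),
                       max_steps=max(maze.DEFAULT_MAX_STEPS,
                                     4 * perturbation.length))
        rng = np.random.default_rng(explore_seed)
        out = {}
        for trial in subtasks:
            wins = sum(run_trial(agent, env, trial, 0.0, rng,
                                 learn=False)["success"]
                       for _ in range(n_trials))
            out[trial.label] = wins / n_trials
        return out
    return evaluate(config, snapshot, n_trials, seed, subtasks=subtasks,
                    view_mode=view_mode, perturbation=perturbation)


def evaluate_variants(config, snapshot, variants, n_trials: int, seed: int,
                      subtasks=SUBTASKS, view_mode: str = "3x3") -> pd.DataFrame:
    """Greedy evaluation over a list of (name, PerturbationSpec|None).

    Returns one row per variant x subtask with the success rate, its
    binomial standard error, and the trial count.
    """
    rows = []
    for i, (name, pert) in enumerate(variants):
        res = _eval_perturbed(config, snapshot, pert, n_trials, seed + i,
                              subtasks, view_mode)
        for label, rate in res.items():
            se = np.sqrt(max(rate * (1 - rate), 0.0) / n_trials)
            rows.append({"variant": name, "subtask": label,
                         "success": rate, "se": se, "n": n_trials})
    return pd.DataFrame(rows)


def corridor_grid(lengths=CORRIDOR_GRID):
    return [(f"corridor_{L}",
             PerturbationSpec("corridor_length", length=L)) for L in lengths]


def cue_removal_grid():
    """All 2^4 cue subsets, named by the number removed."""
    variants = []
    for k in range(5):
        for subset in combinations(CUE_CODES, k):
            tag = "".join(str(int(c)) for c in subset) or "none"
            variants.append((f"remove{k}_{tag}",
                             PerturbationSpec("cue_removal",
                                              removed_cues=subset)))
    return variants


def distractor_variant():
    return [("distractor", PerturbationSpec("distractor"))]


def noise_grid(sigmas2=NOISE_GRID):
    return [(f"noise_{s}", PerturbationSpec("gaussian_noise", noise_var=s))
            for s in sigmas2]


def cue_prob_grid(probs=CUE_PROB_GRID):
    return [(f"cueprob_{p}", PerturbationSpec("probabilistic_cues",
                                              cue_prob=p)) for p in probs]


def summarize_by_count(removal_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate exhaustive cue-removal subsets by number removed."""
    t = removal_table.copy()
    t["n_removed"] = t["variant"].str.extract(r"remove(\d)").astype(int)
    return (t.groupby(["n_removed", "subtask"])["success"]
            .mean().reset_index())


def longest_corridor_above_chance(config, snapshot, n_trials: int, seed: int,
                                  lengths=CORRIDOR_GRID,
                                  chance: float = 0.5) -> int:
    """Longest corridor at which the mean success over all four subtasks
    stays above chance."""
    best = 0
    for i, L in enumerate(lengths):
        res = _eval_perturbed(config, snapshot,
                              PerturbationSpec("corridor_length", length=L),
                              n_trials, seed + i)
        if float(np.mean(list(res.values()))) > chance:
            best = L
    return best
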