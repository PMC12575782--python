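"""Cohort-level study helpers shared by the acceptance checks and the
analysis drivers.

The "desk" scale used for reproducing printed quantities trains 4,000
trials per seed (blocks of 10, same alternation pattern as the full
10,000-trial protocol).  At this scale the recurrent agent converges on
all four subtasks across seeds; the 2,000-trial scaled preset remains the
fast setting for property suites.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import demixing as dmx
from .agents import AgentConfig
from .generalization import CUE_PROB_GRID, _eval_perturbed
from .maze import PerturbationSpec
from .training import TrainResult, build_schedule, evaluate, train

DESK_PRESET = {"block_size": 10, "total_trials": 4_000}

# activation-recording budget per subtask; 4 x 200 = 800 trials, the same
# order as the behavioural sessions the analysis emulates
RECORD_TRIALS_PER_SUBTASK = 200
RECORD_EPS = 0.05


def desk_schedule():
    return build_schedule(total_trials=DESK_PRESET["total_trials"],
                          block_size=DESK_PRESET["block_size"])


def train_cohort(architecture: str, seeds: Sequence[int],
                 perturbation: Optional[PerturbationSpec] = None,
                 schedule=None) -> list:
    cfg = AgentConfig(architecture=architecture)
    sched = schedule if schedule is not None else desk_schedule()
    return [train(cfg, sched, seed=int(s), perturbation=perturbation)
            for s in seeds]


def cohort_mean_success(cfg: AgentConfig, cohort: Sequence[TrainResult],
                        n_trials: int, seed: int,
                        perturbation: Optional[PerturbationSpec] = None
                        ) -> float:
    """Mean greedy success over seeds and the four subtasks (fraction)."""
    vals = []
    for i, res in enumerate(cohort):
        rates = evaluate(cfg, res.final, n_trials, seed + i,
                         perturbation=perturbation)
        vals.append(np.mean(list(rates.values())))
    return float(np.mean(vals))


def corridor_success_by_length(cfg: AgentConfig, cohort, lengths,
                               n_trials: int, seed: int) -> dict:
    out = {}
    for j, L in enumerate(lengths):
        pert = PerturbationSpec("corridor_length", length=int(L))
        vals = []
        for i, res in enumerate(cohort):
            rates = _eval_perturbed(cfg, res.final, pert, n_trials,
                                    seed + 100 * j + i)
            vals.append(np.mean(list(rates.values())))
        out[int(L)] = float(np.mean(vals))
    return out


def longest_corridor_above_chance(by_length: dict, chance: float = 0.5) -> int:
    longest = 0
    for L in sorted(by_length):
        if by_length[L] > chance:
            longest = L
    return longest


def probabilistic_improvement(cfg: AgentConfig, det_cohort, prob_cohort,
                              n_trials: int, seed: int,
                              grid=CUE_PROB_GRID) -> float:
    """Mean success under probabilistic-cue testing (over the visibility
    grid) of the stochastically-trained cohort minus the deterministically
    trained one, in percentage points."""
    means = []
    for cohort in (det_cohort, prob_cohort):
        grid_vals = []
        for j, p in enumerate(grid):
            pert = PerturbationSpec("probabilistic_cues", cue_prob=float(p))
            grid_vals.append(cohort_mean_success(cfg, cohort, n_trials,
                                                 seed + 100 * j,
                                                 perturbation=pert))
        means.append(np.mean(grid_vals))
    return float(100.0 * (means[1] - means[0]))


def intermediate_fractions(cfg: AgentConfig, cohort, seed: int,
                           n_per_subtask: int = RECORD_TRIALS_PER_SUBTASK,
                           eps: float = RECORD_EPS) -> dict:
    """Demixed variance fractions of CA1 activity at the intermediate-
    learning checkpoint, averaged over seeds (percent)."""
    acc = {m: [] for m in dmx.MARGINALIZATIONS}
    for i, res in enumerate(cohort):
        snap = res.intermediate if res.intermediate is not None else res.final
        ds = dmx.record_activations(cfg, snap, n_per_subtask,
                                    seed=seed + i, eps=eps)
        data = dmx.fill_missing(dmx.align_and_bin(ds))
        cs = dmx.fit_demixed(data)
        for m in dmx.MARGINALIZATIONS:
            acc[m].append(cs.marginal_fractions[m])
    return {m: float(100.0 * np.mean(v)) for m, v in acc.items()}
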