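"""Behaviour profiles: state-occupancy maps, the optimal-path dwell-time
profile with state-to-end ratios, the model-reference behaviour error, and
Q-value certainty along the path.

The maze is summarized by the ordered states of the optimal start-to-
reward trajectory (7 states under the default geometry).  Dwell time in a
state counts every step spent there, including rotations in place and,
by default, the post-terminal steps in the final state (they model the
behaviour right after reward consumption; a toggle excludes them).
The action-certainty proxy is the relative Q-value variance: the
population variance of the three action values at a state divided by
their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import maze
from .maze import TMazeEnv, TrialSpec, optimal_path
from .training import make_agent, run_trial


@dataclass
class OccupancyProfile:
    time_map: np.ndarray             # grid of total steps spent per cell
    path: list                       # ordered optimal-path cells
    path_times: np.ndarray           # dwell per path state (mean per episode)
    ratios: np.ndarray               # dwell / final-state dwell


def occupancy_profile(episodes, layout, trial: TrialSpec,
                      count_post_terminal: bool = True) -> OccupancyProfile:
    """Aggregate per-cell dwell over episodes of one subtask.

    ``episodes``: list of dicts with 'positions' (per-step cells, the
    reset cell first) and optionally 'terminal_index' marking the step
    entering the terminal.  Episodes that never reach the terminal enter
    the map but are excluded from the ratio profile.
    """
    time_map = np.zeros(layout.shape)
    path = optimal_path(layout, trial)
    idx = {cell: i for i, cell in enumerate(path)}
    per_ep = []
    for ep in episodes:
        positions = ep["positions"]
        t_idx = ep.get("terminal_index")
        if t_idx is None:
            t_idx = next((i for i, p in enumerate(positions)
                          if p in (layout.terminal_cells["east"],
                                   layout.terminal_cells["west"])), None)
        limit = len(positions) if count_post_terminal else \
            (t_idx + 1 if t_idx is not None else len(positions))
        dwell = np.zeros(len(path))
        for p in positions[:limit]:
            time_map[p] += 1
            if p in idx:
                dwell[idx[p]] += 1
        if t_idx is not None and positions[t_idx] == path[-1]:
            per_ep.append(dwell)
    if per_ep:
        path_times = np.mean(per_ep, axis=0)
        ratios = path_times / path_times[-1]
    else:
        path_times = np.zeros(len(path))
        ratios = np.full(len(path), np.nan)
    return OccupancyProfile(time_map=time_map, path=path,
                            path_times=path_times, ratios=ratios)


def behavior_error(profile_model, profile_reference) -> float:
    """Mean squared error between two state-to-end ratio vectors."""
    a = np.asarray(getattr(profile_model, "ratios", profile_model),
                   dtype=float)
    b = np.asarray(getattr(profile_reference, "ratios", profile_reference),
                   dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratio vectors differ in length")
    return float(np.mean((a - b) ** 2))


@dataclass
class QProfile:
    path: list
    q: np.ndarray                    # states x 3 action values
    mean_q: np.ndarray
    rel_var: np.ndarray              # population variance / mean, NaN if
                                     # the mean is not positive


def q_profile(config, snapshot, trial: TrialSpec,
              layout: Optional[maze.MazeLayout] = None,
              view_mode: str = "3x3") -> QProfile:
    """Q-value triples along a greedy rollout of the optimal path.

    The agent is rolled out greedily (recurrent hidden state carried
    along); at the first visit of each optimal-path state the Q-values of
    the three actions are recorded.  States the rollout never reaches
    keep NaN entries.
    """
    agent = make_agent(config, snapshot)
    env = TMazeEnv(layout=layout, view_mode=view_mode,
                   rng=np.random.default_rng(0))
    layout = env.layout
    path = optimal_path(layout, trial)
    idx = {cell: i for i, cell in enumerate(path)}
    q = np.full((len(path), 3), np.nan)
    obs = env.reset(trial)
    agent.begin_trial(trial.head)
    agent.learning = False
    done = False
    while not done:
        qv = agent.q_values(obs)
        cell = env.state.position
        if cell in idx and np.isnan(q[idx[cell]]).all():
            q[idx[cell]] = qv
        obs, _, done = env.step(int(np.argmax(qv)))
    mean_q = q.mean(axis=1)
    var = q.var(axis=1)              # population variance (n denominator)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean_q > 0, var / mean_q, np.nan)
    return QProfile(path=path, q=q, mean_q=mean_q, rel_var=rel)


def collect_episodes(config, snapshot, trial: TrialSpec, n_episodes: int,
                     seed: int, view_mode: str = "3x3",
                     eps: float = 0.0,
                     perturbation=None) -> list:
    """Greedy rollouts returning the position traces used by
    :func:`occupancy_profile`."""
    agent = make_agent(config, snapshot)
    ss = np.random.SeedSequence(seed)
    env_seed, explore_seed = ss.spawn(2)
    env = TMazeEnv(view_mode=view_mode, perturbation=perturbation,
                   rng=np.random.default_rng(env_seed))
    rng = np.random.default_rng(explore_seed)
    episodes = []
    for _ in range(n_episodes):
        rec = {}
        out = run_trial(agent, env, trial, eps, rng, learn=False, record=rec)
        episodes.append({"positions": rec["positions"],
                         "terminal_index": (out["terminal_step"] + 1
                                            if out["terminal_step"] is not None
                                            else None),
                         "success": out["success"]})
    return episodes


def scripted_reference_profile(layout, trial: TrialSpec,
                               junction_dwell: int = 3,
                               terminal_dwell: int = 4) -> OccupancyProfile:
    """Synthetic animal-like reference: one pass along the optimal path
    with extra dwell (rotation pauses) at the decision point and a longer
    stay at the terminal, mimicking reward consumption."""
    path = optimal_path(layout, trial)
    positions = []
    for cell in path[:-1]:
        positions.append(cell)
        if cell == layout.junction:
            positions.extend([cell] * (junction_dwell - 1))
    positions.extend([path[-1]] * terminal_dwell)
    ep = {"positions": positions, "terminal_index": len(positions) - terminal_dwell}
    return occupancy_profile([ep], layout, trial)
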