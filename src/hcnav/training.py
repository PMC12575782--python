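"""Block-wise multi-task curriculum and training-loop orchestration.

The curriculum mirrors the animal protocol: blocks of trials under a
single (rule, start arm) combination, with allocentric north/south blocks
alternated four times before switching to egocentric blocks, the whole
pattern repeating until the scheduled number of trials is reached.  The
full-scale schedule is 400 blocks of 25 trials (10,000 trials); a scaled
preset (blocks of 10, 2,000 trials) preserves the same alternation
pattern for fast runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import maze
from .maze import TMazeEnv, TrialSpec, SUBTASKS
from .agents import Agent, AgentConfig, select_action

FULL_PRESET = {"block_size": 25, "total_trials": 10_000}
SCALED_PRESET = {"block_size": 10, "total_trials": 2_000}


@dataclass
class Schedule:
    trials: pd.DataFrame            # columns: trial, block, rule, start_arm, head
    block_size: int
    total_trials: int

    def __len__(self):
        return self.total_trials


def build_schedule(total_trials: int = 10_000, block_size: int = 25,
                   alternations: int = 4, ego_mode: str = "alternating",
                   allo_reward_side: str = "east") -> Schedule:
    """Explicit ordered list of (trial, block, rule, start_arm).

    One super-cycle is ``2 * alternations`` allocentric blocks (north/south
    alternated) followed by the same number of egocentric blocks.
    ``ego_mode='alternating'`` alternates north/south egocentric blocks
    like the allocentric ones; ``'fixed_north'``/``'fixed_south'`` keep a
    single start for the whole egocentric phase.
    """
    if total_trials % block_size != 0:
        raise ValueError("total_trials must be divisible by block_size")
    n_blocks = total_trials // block_size
    pattern = []
    for i in range(2 * alternations):
        pattern.append(("allocentric", "north" if i % 2 == 0 else "south"))
    for i in range(2 * alternations):
        if ego_mode == "alternating":
            arm = "north" if i % 2 == 0 else "south"
        elif ego_mode == "fixed_north":
            arm = "north"
        elif ego_mode == "fixed_south":
            arm = "south"
        else:
            raise ValueError(f"unknown ego_mode {ego_mode!r}")
        pattern.append(("egocentric", arm))

    rows = []
    for b in range(n_blocks):
        rule, arm = pattern[b % len(pattern)]
        for t in range(block_size):
            rows.append((b * block_size + t, b, rule, arm,
                         "allo" if rule == "allocentric" else "ego"))
    df = pd.DataFrame(rows, columns=["trial", "block", "rule", "start_arm",
                                     "head"])
    df.attrs["allo_reward_side"] = allo_reward_side
    return Schedule(trials=df, block_size=block_size,
                    total_trials=total_trials)


def trial_spec(row, allo_reward_side: str = "east") -> TrialSpec:
    side = allo_reward_side if row.rule == "allocentric" else "right"
    return TrialSpec(row.rule, row.start_arm, side)


def run_trial(agent: Agent, env: TMazeEnv, trial: TrialSpec, eps: float,
              rng: np.random.Generator, learn: bool = True,
              record: Optional[dict] = None) -> dict:
    """One episode: act, store transitions, learn until the terminal
    transition; post-terminal steps are executed and recorded but never
    learned from.  Returns per-trial summary fields."""
    obs = env.reset(trial)
    agent.begin_trial(trial.head)
    agent.learning = learn
    done = False
    terminal_step = None
    steps = 0
    if record is not None:
        record["positions"] = [env.state.position]
        record["orientations"] = [env.state.orientation]
        record["ca1"] = []
        record["q"] = []
    while not done:
        was_active = env.state.phase == "active"
        q = agent.q_values(obs)
        a = select_action(q, eps, rng)
        obs2, r, done = env.step(a)
        steps += 1
        if record is not None:
            record["ca1"].append(agent.last_ca1.copy())
            record["q"].append(q.copy())
            record["positions"].append(env.state.position)
            record["orientations"].append(env.state.orientation)
        if was_active:
            entered_terminal = env.state.phase != "active"
            truncated = done and not entered_terminal
            if learn:
                agent.store(a, r, obs2, entered_terminal or truncated)
            if entered_terminal:
                terminal_step = steps - 1   # index of the entering step
        obs = obs2
    return {"success": int(env.succeeded), "steps": steps,
            "terminal_step": terminal_step,
            "terminal": env.state.reached_terminal}


@dataclass
class TrainResult:
    log: pd.DataFrame
    final: dict                      # parameter snapshot at the last trial
    intermediate: Optional[dict]     # snapshot in the target success band
    intermediate_trial: Optional[int]
    config: AgentConfig


def train(config: AgentConfig, schedule: Schedule, seed: int,
          view_mode: str = "3x3",
          perturbation: Optional[maze.PerturbationSpec] = None,
          intermediate_band=(0.70, 0.85), intermediate_window: int = 100,
          consolidation=None) -> TrainResult:
    """Train one agent through the schedule.

    Seeds three independent streams (environment, agent initialization,
    exploration).  The "intermediate stage of learning" checkpoint is the
    first parameter snapshot whose windowed success rate (trailing
    ``intermediate_window`` trials, taken after at least one full
    super-cycle so both rules have been seen) falls inside
    ``intermediate_band``.
    """
    ss = np.random.SeedSequence(seed)
    env_seed, agent_seed, explore_seed = ss.spawn(3)
    env = TMazeEnv(view_mode=view_mode, perturbation=perturbation,
                   rng=np.random.default_rng(env_seed))
    rng = np.random.default_rng(explore_seed)
    agent = Agent(config, seed=int(agent_seed.generate_state(1)[0] % 2**31))
    agent.consolidation = consolidation

    allo_side = schedule.trials.attrs.get("allo_reward_side", "east")
    total = schedule.total_trials
    min_trial = 16 * schedule.block_size    # one full super-cycle
    successes = np.zeros(total, dtype=int)
    rows = []
    inter = None
    inter_trial = None
    prev_head = None
    for row in schedule.trials.itertuples(index=False):
        if (consolidation is not None and prev_head is not None
                and row.head != prev_head):
            consolidation.consolidate(agent)
        prev_head = row.head
        spec = trial_spec(row, allo_side)
        eps = config.epsilon(row.trial, total)
        out = run_trial(agent, env, spec, eps, rng, learn=True)
        successes[row.trial] = out["success"]
        rows.append((row.trial, row.block, row.rule, row.start_arm,
                     out["success"], out["steps"], eps))
        if inter is None and row.trial + 1 >= max(min_trial,
                                                  intermediate_window):
            w = successes[row.trial + 1 - intermediate_window:row.trial + 1]
            rate = float(w.mean())
            if intermediate_band[0] <= rate <= intermediate_band[1]:
                inter = agent.state_dict()
                inter_trial = int(row.trial)
    log = pd.DataFrame(rows, columns=["trial", "block", "rule", "start_arm",
                                      "success", "steps", "epsilon"])
    return TrainResult(log=log, final=agent.state_dict(), intermediate=inter,
                       intermediate_trial=inter_trial, config=config)


def make_agent(config: AgentConfig, snapshot: dict) -> Agent:
    agent = Agent(config, seed=0)
    agent.load_state_dict(snapshot)
    agent.learning = False
    return agent


def evaluate(config: AgentConfig, snapshot: dict, n_trials: int, seed: int,
             subtasks=SUBTASKS, view_mode: str = "3x3",
             perturbation: Optional[maze.PerturbationSpec] = None,
             eps: float = 0.0, max_steps: int = maze.DEFAULT_MAX_STEPS) -> dict:
    """Greedy (eps=0) evaluation with learning off.

    Returns {subtask label: success rate} over ``n_trials`` per subtask.
    """
    agent = make_agent(config, snapshot)
    ss = np.random.SeedSequence(seed)
    env_seed, explore_seed = ss.spawn(2)
    env = TMazeEnv(view_mode=view_mode, perturbation=perturbation,
                   rng=np.random.default_rng(env_seed), max_steps=max_steps)
    rng = np.random.default_rng(explore_seed)
    out = {}
    for trial in subtasks:
        wins = 0
        for _ in range(n_trials):
            res = run_trial(agent, env, trial, eps, rng, learn=False)
            wins += res["success"]
        out[trial.label] = wins / n_trials
    return out


def block_success(log: pd.DataFrame) -> pd.DataFrame:
    g = log.groupby("block").agg(success=("success", "mean"),
                                 rule=("rule", "first"),
                                 start_arm=("start_arm", "first"))
    return g.reset_index()


def subtask_success(log: pd.DataFrame, last_frac: float = 0.5) -> dict:
    """Mean training success per subtask over the last ``last_frac`` of
    trials (the block-averaged measure used for learning-pattern checks)."""
    cut = log["trial"].max() * (1.0 - last_frac)
    tail = log[log["trial"] >= cut]
    out = {}
    for (rule, arm), grp in tail.groupby(["rule", "start_arm"]):
        label = ("allo" if rule == "allocentric" else "ego") + "-" + arm
        out[label] = float(grp["success"].mean())
    return out


def drop_recovery(block_means: np.ndarray) -> tuple:
    """Performance drop and recovery around a task switch.

    ``block_means`` are block-averaged success rates for the segment that
    starts at a switch.  Drop = mean of the first block minus the minimum
    of the remaining blocks; recovery = mean of the last two blocks minus
    that same minimum.
    """
    b = np.asarray(block_means, dtype=float)
    if b.size < 3:
        raise ValueError("need at least 3 blocks to compute drop/recovery")
    rest_min = b[1:].min()
    drop = b[0] - rest_min
    recovery = b[-2:].mean() - rest_min
    return float(drop), float(recovery)
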