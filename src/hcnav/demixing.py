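"""Demixed analysis of CA1 population activity.

Trial activity is aligned to the terminal (reward-sensor) crossing,
converted to seconds at 200 ms per step, and averaged into a
neurons x strategy(4) x decision(2) x time(30) condition tensor spanning
-2 s to +4 s around the crossing.  The tensor is decomposed into additive
marginalizations tied to the task variables --- time, strategy (+ its
time interaction), decision (+ its time interaction), and the remaining
strategy x decision (mixed) terms --- and demixed components are obtained
per marginalization by regularized reduced-rank regression of the
marginal data onto the full data, following the demixed-PCA procedure.

The marginalizations are orthogonal, so their squared norms partition the
variance of the centered tensor exactly; the per-marginalization variance
fractions reported here are that partition.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from . import maze
from .maze import TMazeEnv, SUBTASKS
from .training import make_agent, run_trial
from .agents import AgentConfig, select_action

DT = 0.2                       # seconds per bin; one env step = 200 ms
PRE_BINS = 10                  # -2 s
POST_BINS = 20                 # +4 s
N_BINS = PRE_BINS + POST_BINS

STRATEGY_LEVELS = ("allo-north", "allo-south", "ego-north", "ego-south")
DECISION_LEVELS = ("correct", "incorrect")
MARGINALIZATIONS = ("time", "strategy", "decision", "interaction")


@dataclass
class ActivationDataset:
    """Per-trial CA1 activation matrices with condition labels."""
    trials: list                     # each: (units x steps) array
    strategy: np.ndarray             # index into STRATEGY_LEVELS
    decision: np.ndarray             # 0 correct, 1 incorrect
    terminal_step: np.ndarray        # step index of the terminal crossing

    def __post_init__(self):
        units = {t.shape[0] for t in self.trials}
        if len(units) > 1:
            raise ValueError("unit count differs across trials")

    @property
    def n_units(self) -> int:
        return self.trials[0].shape[0]


@dataclass
class ConditionTensor:
    data: np.ndarray                 # units x 4 x 2 x N_BINS
    counts: np.ndarray               # 4 x 2 trial counts
    missing: np.ndarray              # 4 x 2 bool, zero-trial cells

    @property
    def n_units(self) -> int:
        return self.data.shape[0]


def record_activations(config: AgentConfig, snapshot: dict,
                       n_per_subtask: int, seed: int,
                       view_mode: str = "3x3", eps: float = 0.0,
                       post_steps: int = POST_BINS) -> ActivationDataset:
    """Greedy rollouts with learning off, recording CA1 activity.

    Post-terminal exploration is extended to ``post_steps`` steps so the
    +4 s analysis window is covered (the agent keeps acting; no learning
    occurs after the terminal transition).
    """
    agent = make_agent(config, snapshot)
    ss = np.random.SeedSequence(seed)
    env_seed, explore_seed = ss.spawn(2)
    env = TMazeEnv(view_mode=view_mode, post_terminal_steps=post_steps,
                   rng=np.random.default_rng(env_seed))
    rng = np.random.default_rng(explore_seed)
    trials, strat, dec, term = [], [], [], []
    for s_idx, spec in enumerate(SUBTASKS):
        for _ in range(n_per_subtask):
            rec = {}
            out = run_trial(agent, env, spec, eps, rng, learn=False,
                            record=rec)
            if out["terminal_step"] is None:
                continue               # never reached a terminal: unusable
            trials.append(np.asarray(rec["ca1"]).T)   # units x steps
            strat.append(s_idx)
            dec.append(0 if out["success"] else 1)
            term.append(out["terminal_step"])
    return ActivationDataset(trials, np.asarray(strat), np.asarray(dec),
                             np.asarray(term))


def align_and_bin(dataset: ActivationDataset, pre_bins: int = PRE_BINS,
                  post_bins: int = POST_BINS) -> ConditionTensor:
    """Trial-average activity into the condition tensor.

    Each trial is windowed to ``[terminal - pre_bins, terminal + post_bins)``
    steps; trials shorter than the window are edge-padded (first/last
    recorded activation held).  Condition cells with zero trials are
    flagged missing, never silently zero-filled.
    """
    n_bins = pre_bins + post_bins
    U = dataset.n_units
    sums = np.zeros((U, 4, 2, n_bins))
    counts = np.zeros((4, 2), dtype=int)
    for act, s, d, t0 in zip(dataset.trials, dataset.strategy,
                             dataset.decision, dataset.terminal_step):
        T = act.shape[1]
        idx = np.clip(np.arange(t0 - pre_bins, t0 + post_bins), 0, T - 1)
        sums[:, s, d, :] += act[:, idx]
        counts[s, d] += 1
    missing = counts == 0
    data = np.zeros_like(sums)
    nz = ~missing
    for s in range(4):
        for d in range(2):
            if nz[s, d]:
                data[:, s, d, :] = sums[:, s, d, :] / counts[s, d]
    return ConditionTensor(data=data, counts=counts, missing=missing)


def fill_missing(tensor: ConditionTensor) -> np.ndarray:
    """Complete the tensor by substituting, for a missing (strategy,
    decision) cell, the mean over that strategy's observed decisions
    (masked averaging rather than zero fill)."""
    data = tensor.data.copy()
    for s in range(4):
        obs = [d for d in range(2) if not tensor.missing[s, d]]
        if not obs:
            raise ValueError(f"strategy level {s} has no trials at all")
        fill = data[:, s, obs, :].mean(axis=1)
        for d in range(2):
            if tensor.missing[s, d]:
                data[:, s, d, :] = fill
    return data


def marginalize(data: np.ndarray) -> dict:
    """ANOVA-style decomposition of a units x S x D x T tensor.

    Removes the per-unit grand mean, then splits the remainder into the
    four orthogonal marginalizations used throughout: time {t}, strategy
    {s, st}, decision {d, dt}, interaction {sd, sdt}.  The marginals plus
    the grand mean reconstruct the tensor exactly.
    """
    mean = data.mean(axis=(1, 2, 3), keepdims=True)
    X = data - mean

    def avg(arr, axes):
        return arr.mean(axis=axes, keepdims=True)

    m_t = avg(X, (1, 2))                                  # main time
    m_s = avg(X, (2, 3))                                  # main strategy
    m_d = avg(X, (1, 3))                                  # main decision
    m_st = avg(X, (2,)) - m_s - m_t
    m_dt = avg(X, (1,)) - m_d - m_t
    m_sd = avg(X, (3,)) - m_s - m_d
    m_sdt = X - (m_t + m_s + m_d + m_st + m_dt + m_sd)
    full = np.broadcast_to
    shape = X.shape
    return {
        "time": full(m_t, shape).copy(),
        "strategy": full(m_s + m_st, shape).copy(),
        "decision": full(m_d + m_dt, shape).copy(),
        "interaction": full(m_sd + m_sdt, shape).copy(),
        "_mean": mean,
    }


def variance_fractions(data: np.ndarray) -> dict:
    """Exact partition of centered variance across the marginalizations."""
    marg = marginalize(data)
    total = float(np.sum((data - marg["_mean"]) ** 2))
    if total == 0:
        return {m: 0.0 for m in MARGINALIZATIONS}
    return {m: float(np.sum(marg[m] ** 2)) / total for m in MARGINALIZATIONS}


@dataclass
class Component:
    marginalization: str
    index: int
    encoder: np.ndarray              # units
    decoder: np.ndarray              # units
    timecourse: np.ndarray           # S x D x T projection of the data
    explained_var: float             # fraction of total centered variance


@dataclass
class ComponentSet:
    components: list
    marginal_fractions: dict         # exact variance partition
    lam: float
    mean: np.ndarray

    def by_marg(self, marg: str):
        return [c for c in self.components if c.marginalization == marg]

    def combined_explained(self, marg: str) -> float:
        return float(sum(c.explained_var for c in self.by_marg(marg)))


def fit_demixed(data: np.ndarray, lam: float = 1e-6,
                n_components: int = 5) -> ComponentSet:
    """Demixed components via ridge-regularized reduced-rank regression.

    For each marginalization X_m the full-rank ridge map
    ``B = X_m X' (X X' + lam * ||X||_F^2 I)^{-1}`` is rank-reduced through
    the SVD of ``B X``; the top left singular vectors give the encoders F
    and ``D = F' B`` the decoders, minimizing ||X_m - F D X||^2 + ridge.
    ``lam`` is expressed relative to the total variance, matching the
    convention of the reference grid-search values.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    marg = marginalize(data)
    U = data.shape[0]
    X = (data - marg["_mean"]).reshape(U, -1)
    total = float(np.sum(X ** 2))
    if total == 0:
        warnings.warn("all-constant tensor; no components")
        return ComponentSet([], variance_fractions(data), lam, marg["_mean"])
    G = X @ X.T + lam * total * np.eye(U)
    comps = []
    for m in MARGINALIZATIONS:
        Xm = marg[m].reshape(U, -1)
        B = np.linalg.solve(G, X @ Xm.T).T        # Xm X' G^{-1}
        BX = B @ X
        rank = min(n_components, U, np.linalg.matrix_rank(BX))
        if rank < n_components:
            warnings.warn(f"{m}: rank-deficient, keeping {rank} components")
        Uv, sv, Vt = np.linalg.svd(BX, full_matrices=False)
        for i in range(rank):
            F = Uv[:, i]
            Dv = F @ B
            proj = Dv @ X
            Xhat = np.outer(F, proj)
            ev = float((2 * np.sum(X * Xhat) - np.sum(Xhat ** 2)) / total)
            comps.append(Component(m, i, F.copy(), Dv.copy(),
                                   proj.reshape(data.shape[1:]), ev))
    return ComponentSet(comps, variance_fractions(data), lam, marg["_mean"])


def grid_search_lambda(data: np.ndarray, grid=None, n_components: int = 5,
                       n_folds: int = 5, seed: int = 0) -> float:
    """Pick lam by held-out unit reconstruction error over a log grid."""
    if grid is None:
        grid = np.logspace(-7, -2, 11)
    U = data.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(U)
    folds = np.array_split(order, n_folds)
    errs = []
    for lam in grid:
        err = 0.0
        for hold in folds:
            keep = np.setdiff1d(order, hold)
            cs = fit_demixed(data[keep], lam, n_components)
            Xh = data[hold] - data[hold].mean(axis=(1, 2, 3), keepdims=True)
            Xh = Xh.reshape(len(hold), -1)
            # project held-out units onto the fitted condition time courses
            P = np.array([c.timecourse.ravel() for c in cs.components])
            if P.size == 0:
                err += np.sum(Xh ** 2)
                continue
            coef, *_ = np.linalg.lstsq(P.T, Xh.T, rcond=None)
            err += float(np.sum((Xh - (P.T @ coef).T) ** 2))
        errs.append(err)
    return float(grid[int(np.argmin(errs))])


def component_mse(y_model: np.ndarray, y_reference: np.ndarray) -> float:
    """Normalized MSE between two component time courses.

    Both series are min-max normalized to [0, 1] before averaging the
    squared differences; a constant series (max == min) is mapped to the
    all-0.5 series with a warning.
    """
    a = np.asarray(y_model, dtype=float).ravel()
    b = np.asarray(y_reference, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("component time courses differ in length")

    def norm(v):
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn("constant series in component_mse; using 0.5")
            return np.full_like(v, 0.5)
        return (v - lo) / (hi - lo)

    an, bn = norm(a), norm(b)
    return float(np.mean((an - bn) ** 2))


def strategy_separability(dataset: ActivationDataset, comps: ComponentSet,
                          pre_bins: int = PRE_BINS,
                          post_bins: int = POST_BINS) -> float:
    """Accuracy of a linear classifier separating allo from ego trials in
    the space of the two leading strategy-component scores."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    strat = comps.by_marg("strategy")[:2]
    if len(strat) < 2:
        raise ValueError("need at least two strategy components")
    feats, labels = [], []
    for act, s, t0 in zip(dataset.trials, dataset.strategy,
                          dataset.terminal_step):
        T = act.shape[1]
        idx = np.clip(np.arange(t0 - pre_bins, t0 + post_bins), 0, T - 1)
        win = act[:, idx] - comps.mean[:, 0, 0, :]
        feats.append([c.decoder @ win.mean(axis=1) for c in strat])
        labels.append(0 if s < 2 else 1)    # allo vs ego
    clf = LinearDiscriminantAnalysis()
    X = np.asarray(feats)
    y = np.asarray(labels)
    clf.fit(X, y)
    return float(clf.score(X, y))
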