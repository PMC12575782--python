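"""Synthetic CA1 firing-rate datasets with planted factorial structure.

Emulates the statistics of the tetrode recordings the demixing pipeline
was designed for: ~612 simultaneously analysed CA1 neurons, firing rates
in 0.2 s bins spanning -2 s to +4 s around a reward-sensor crossing, with
trial labels for strategy (allocentric/egocentric x north/south start)
and decision (correct/incorrect).  Condition-mean activity is built as a
grand mean plus low-rank components confined to each marginalization ---
a decaying time course, step-like decision components that diverge before
the terminal and persist after it, and strategy offsets separating
allocentric from egocentric trials --- scaled so the marginal variance
fractions of the noiseless tensor match the planted fractions exactly.
Trials add Gaussian rate noise (or Poisson counts) and are floored at 0.

The time courses are parameterized as exponential decays and logistic
steps; these functional forms are fixtures for testing the pipeline, not
claims about the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demixing import (marginalize, variance_fractions, N_BINS, PRE_BINS,
                       DT, STRATEGY_LEVELS, DECISION_LEVELS)


@dataclass
class GeneratorParams:
    n_neurons: int = 612
    n_trials_per_condition: int = 40
    n_bins: int = N_BINS
    fractions: dict = field(default_factory=lambda: {
        "strategy": 0.37, "interaction": 0.17, "decision": 0.06,
        "time": 0.40})
    baseline_rate: float = 2.0       # Hz grand mean
    signal_sd: float = 1.0           # rms amplitude of the planted signal
    noise_sd: float = 1.0            # per-trial additive rate noise
    noise_model: str = "gaussian"    # or "poisson"
    n_components: int = 2            # planted components per marginalization
    missing_ego_incorrect: bool = False

    def validate(self):
        fr = self.fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("planted fractions must be >= 0")
        if sum(fr.values()) > 1.0 + 1e-12:
            raise ValueError("planted fractions must sum to <= 1")
        if self.n_neurons < self.n_components:
            raise ValueError("need at least one neuron per planted component")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _center(arr, axis):
    return arr - arr.mean(axis=axis, keepdims=True)


def _time_courses(n_bins, kind, rng):
    t = np.arange(n_bins) / n_bins
    term = PRE_BINS / n_bins
    if kind == "time":
        # temporally decaying population dynamics
        return np.exp(-3.0 * t) * (1 + 0.2 * rng.standard_normal())
    if kind == "step":
        # diverges before the terminal and persists after it
        k = 12.0 + 4.0 * rng.random()
        return 1.0 / (1.0 + np.exp(-k * (t - term + 0.1)))
    raise ValueError(kind)


def _condition_means(params: GeneratorParams, rng) -> np.ndarray:
    U, S, D, T = params.n_neurons, 4, 2, params.n_bins
    mean = np.full((U, S, D, T), params.baseline_rate)

    def planted(marg):
        """Raw low-rank pattern confined to one marginalization."""
        out = np.zeros((U, S, D, T))
        for _ in range(params.n_components):
            w = rng.standard_normal(U)
            if marg == "time":
                course = _time_courses(T, "time", rng)
                pat = _center(course, 0)[None, None, None, :]
                out += w[:, None, None, None] * np.broadcast_to(pat,
                                                                (U, S, D, T))
            elif marg == "strategy":
                # allo vs ego offset plus per-start modulation over time
                levels = _center(rng.standard_normal(S), 0)
                course = _time_courses(T, "time", rng) + 0.5
                out += (w[:, None, None, None] * levels[None, :, None, None]
                        * course[None, None, None, :])
            elif marg == "decision":
                levels = np.array([0.5, -0.5])
                course = _time_courses(T, "step", rng)
                out += (w[:, None, None, None] *
                        levels[None, None, :, None] *
                        course[None, None, None, :])
            elif marg == "interaction":
                pat = rng.standard_normal((S, D))
                pat = _center(_center(pat, 0), 1)
                course = 0.5 + _time_courses(T, "step", rng)
                out += (w[:, None, None, None] *
                        pat[None, :, :, None] * course[None, None, None, :])
        return out

    n_el = U * S * D * T
    for marg, frac in params.fractions.items():
        if frac == 0:
            continue
        raw = planted(marg)
        # project onto the marginalization subspace to keep the factorial
        # structure exact, then scale to the target variance share
        proj = marginalize(raw + params.baseline_rate)[marg]
        norm = np.sqrt(np.sum(proj ** 2))
        if norm == 0:
            raise ValueError(f"degenerate planted pattern for {marg}")
        target = params.signal_sd * np.sqrt(frac * n_el)
        mean += proj * (target / norm)
    return mean


def generate_dataset(params: GeneratorParams, seed: int = 0):
    """Draw a labelled trial tensor.

    Returns ``(rates, labels)`` with ``rates`` of shape
    trials x neurons x time and ``labels`` a DataFrame with ``strategy``
    (level index), ``strategy_name``, ``decision`` (0 correct,
    1 incorrect) and ``decision_name`` columns.  The condition means are
    recoverable exactly from the noiseless generator (see
    :func:`condition_means`).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    mean = _condition_means(params, rng)
    U, S, D, T = mean.shape
    trials, strat, dec = [], [], []
    for s in range(S):
        for d in range(D):
            if params.missing_ego_incorrect and s >= 2 and d == 1:
                continue
            for _ in range(params.n_trials_per_condition):
                if params.noise_model == "gaussian":
                    x = mean[:, s, d, :] + params.noise_sd * \
                        rng.standard_normal((U, T))
                    x = np.maximum(x, 0.0)
                else:
                    lam = np.maximum(mean[:, s, d, :], 0.0) * DT
                    x = rng.poisson(lam) / DT
                trials.append(x)
                strat.append(s)
                dec.append(d)
    labels = pd.DataFrame({
        "strategy": strat,
        "strategy_name": [STRATEGY_LEVELS[s] for s in strat],
        "decision": dec,
        "decision_name": [DECISION_LEVELS[d] for d in dec],
    })
    return np.asarray(trials), labels


def condition_means(params: GeneratorParams, seed: int = 0) -> np.ndarray:
    """The noiseless condition-mean tensor for the same seed (the planted
    marginal variance fractions of this tensor equal ``params.fractions``
    exactly)."""
    params.validate()
    rng = np.random.default_rng(seed)
    return _condition_means(params, rng)


def to_condition_tensor(rates: np.ndarray, labels: pd.DataFrame,
                        n_bins: int = N_BINS):
    """Average labelled trials into the neurons x 4 x 2 x T tensor the
    demixing module consumes (terminal crossing already at bin PRE_BINS)."""
    from .demixing import ConditionTensor
    U = rates.shape[1]
    sums = np.zeros((U, 4, 2, n_bins))
    counts = np.zeros((4, 2), dtype=int)
    for x, s, d in zip(rates, labels["strategy"], labels["decision"]):
        sums[:, s, d, :] += x
        counts[s, d] += 1
    missing = counts == 0
    data = np.zeros_like(sums)
    for s in range(4):
        for d in range(2):
            if not missing[s, d]:
                data[:, s, d, :] = sums[:, s, d, :] / counts[s, d]
    return ConditionTensor(data=data, counts=counts, missing=missing)
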