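"""Hippocampal-like value networks and the Q-learning machinery.

Architecture (all variants): a flattened egocentric observation feeds a
dentate-gyrus-like input layer, then a CA3 layer (a gated recurrent unit
bank in the recurrent variants, a rectified dense layer in the feedforward
one), a rectified CA1 layer, and per-task linear Q-value readouts (one
head for allocentric tasks, one for egocentric tasks; a single-head
variant instead appends a task-ID bit to the input).

Learning is online one-step Q-learning with a frozen target network:

    target = r                                  if the transition ends the trial
    target = r + gamma * max_a' Q(s', a'; theta-)  otherwise
    loss   = (target - Q(s, a; theta))^2

For the recurrent variants the gradient is backpropagated through time to
the start of the trial (window capped at ``bptt_max_window``); parameter
updates are applied every ``bptt_interval`` environment steps and at the
end of the trial, with Adam.  There is no experience replay (buffer size
1) and no state or gradient flow across trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nn import Adam, gru_forward, gru_backward, gru_step, relu

FEEDFORWARD = "feedforward"
RECURRENT = "recurrent"
RECURRENT_FIXED = "recurrent_fixed"

HEADS = ("allo", "ego")


@dataclass
class AgentConfig:
    architecture: str = RECURRENT
    input_size: int = 9                 # flattened view (9 partial, 81 full)
    ca3_size: int = 50
    ca1_size: int = 50
    n_actions: int = 3
    heads: str = "two_head"             # or "task_id_single_head"
    gamma: float = 0.9
    lr: float = 1e-3
    eps_start: float = 0.3
    eps_end: float = 0.05
    eps_decay_frac: float = 0.5         # linear decay over this fraction of trials
    bptt_interval: int = 2
    bptt_max_window: int = 128
    target_update: int = 25             # parameter updates between theta- refreshes

    def __post_init__(self):
        if self.architecture not in (FEEDFORWARD, RECURRENT, RECURRENT_FIXED):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if self.eps_end > self.eps_start:
            raise ValueError("eps_end must be <= eps_start")

    @property
    def recurrent(self) -> bool:
        return self.architecture in (RECURRENT, RECURRENT_FIXED)

    @property
    def task_id(self) -> bool:
        return self.heads == "task_id_single_head"

    @property
    def net_input(self) -> int:
        return self.input_size + (1 if self.task_id else 0)

    @property
    def n_heads(self) -> int:
        return 1 if self.task_id else 2

    def epsilon(self, trial: int, total_trials: int) -> float:
        """Linear decay from eps_start to eps_end over the first
        ``eps_decay_frac`` of scheduled trials, then constant."""
        horizon = max(1, int(total_trials * self.eps_decay_frac))
        frac = min(1.0, trial / horizon)
        return self.eps_start + frac * (self.eps_end - self.eps_start)


def _layout(config: AgentConfig):
    """(name, shape) blocks of the flat parameter vector."""
    D, H, M = config.net_input, config.ca3_size, config.ca1_size
    A, K = config.n_actions, config.n_heads
    if config.recurrent:
        blocks = [("Wx", (3 * H, D)), ("Uh", (3 * H, H)),
                  ("bi", (3 * H,)), ("bh", (3 * H,))]
    else:
        blocks = [("W1", (H, D)), ("b1", (H,))]
    blocks += [("W2", (M, H)), ("b2", (M,)),
               ("W3", (K, A, M)), ("b3", (K, A))]
    return blocks


def _views(theta: np.ndarray, config: AgentConfig) -> dict:
    out = {}
    i = 0
    for name, shape in _layout(config):
        n = int(np.prod(shape))
        out[name] = theta[i:i + n].reshape(shape)
        i += n
    assert i == theta.size
    return out


def n_params(config: AgentConfig) -> int:
    return sum(int(np.prod(s)) for _, s in _layout(config))


def select_action(q_values: np.ndarray, eps: float,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy with lowest-index tie-break on the greedy branch."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must be in [0, 1]")
    if eps > 0.0 and rng.random() < eps:
        return int(rng.integers(len(q_values)))
    return int(np.argmax(q_values))


class Agent:
    """One hippocampal Q-learning agent (hcDQN / hcDRQN / fixed-hcDRQN)."""

    def __init__(self, config: AgentConfig, seed: int):
        self.config = config
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(config.ca3_size)
        self.theta = rng.uniform(-k, k, n_params(config))
        self.theta_tgt = self.theta.copy()
        self.p = _views(self.theta, config)
        self.pt = _views(self.theta_tgt, config)
        self.opt = Adam(self.theta.size, lr=config.lr)
        self._grad = np.zeros_like(self.theta)
        self._g = _views(self._grad, config)
        self.update_count = 0
        self.learning = True
        self.consolidation = None       # optional ConsolidationPenalty
        self._reset_episode()

    # -- episode bookkeeping ------------------------------------------------

    def _reset_episode(self):
        H = self.config.ca3_size
        self.h = np.zeros(H)            # acting hidden state (online theta)
        self.h_tgt = np.zeros(H)        # target-network hidden state
        self.X = []                     # observations fed to the network
        self.pending = []               # (k, action, target) awaiting update
        self.head_idx = 0
        self._task_bit = 0.0
        self.last_ca1 = np.zeros(self.config.ca1_size)
        self._frozen = False            # set once the learning episode ends

    def begin_trial(self, head: str):
        """Reset recurrent state and buffers; select the active Q head."""
        if head not in HEADS:
            raise ValueError(f"unknown head {head!r}")
        self._reset_episode()
        if self.config.task_id:
            self.head_idx = 0
            self._task_bit = float(HEADS.index(head))
        else:
            self.head_idx = HEADS.index(head)

    def _prep(self, obs: np.ndarray) -> np.ndarray:
        x = np.asarray(obs, dtype=float).ravel()
        if x.size != self.config.input_size:
            raise ValueError(
                f"observation size {x.size} != configured "
                f"{self.config.input_size}")
        if self.config.task_id:
            x = np.append(x, self._task_bit)
        return x

    def _readout(self, h: np.ndarray, p: dict):
        ca1 = relu(p["W2"] @ h + p["b2"])
        q = p["W3"][self.head_idx] @ ca1 + p["b3"][self.head_idx]
        return q, ca1

    def q_values(self, obs: np.ndarray, advance: bool = True) -> np.ndarray:
        """Q-values of the active head for this observation.

        For recurrent variants this consumes the observation into the
        acting hidden state (and the target-network hidden state), so call
        it exactly once per environment step.
        """
        x = self._prep(obs)
        if self.config.recurrent:
            h_new = gru_step(self.p["Wx"], self.p["Uh"], self.p["bi"],
                             self.p["bh"], x, self.h)
            if advance:
                self.h = h_new
                self.h_tgt = gru_step(self.pt["Wx"], self.pt["Uh"],
                                      self.pt["bi"], self.pt["bh"], x,
                                      self.h_tgt)
                self.X.append(x)
            h = h_new
        else:
            h = relu(self.p["W1"] @ x + self.p["b1"])
            if advance:
                self.h = h
                self.X.append(x)
        q, ca1 = self._readout(h, self.p)
        if advance:
            self.last_ca1 = ca1
        if not np.all(np.isfinite(q)):
            raise FloatingPointError("non-finite Q-values (diverged)")
        return q

    def act(self, obs: np.ndarray, eps: float,
            rng: np.random.Generator) -> int:
        return select_action(self.q_values(obs), eps, rng)

    # -- learning -----------------------------------------------------------

    def _target_q(self, x_next: np.ndarray) -> float:
        if self.config.recurrent:
            h = gru_step(self.pt["Wx"], self.pt["Uh"], self.pt["bi"],
                         self.pt["bh"], x_next, self.h_tgt)
        else:
            h = relu(self.pt["W1"] @ x_next + self.pt["b1"])
        q, _ = self._readout(h, self.pt)
        return float(np.max(q))

    def store(self, action: int, reward: float, next_obs: np.ndarray,
              done: bool) -> None:
        """Record the transition for the most recent acted observation and
        trigger an update every ``bptt_interval`` stored steps (and at
        ``done``).  No-op once the learning episode has ended."""
        if not self.learning or self._frozen:
            return
        k = len(self.X) - 1             # index of s in the episode sequence
        x_next = self._prep(next_obs)
        if done:
            target = float(reward)
        else:
            target = float(reward) + self.config.gamma * self._target_q(x_next)
        self.pending.append((k, int(action), target))
        if len(self.pending) >= self.config.bptt_interval or done:
            self._update()
        if done:
            self._frozen = True
            if self.consolidation is not None:
                self.consolidation.end_episode(self)

    def _update(self):
        cfg = self.config
        self._grad[:] = 0.0
        grad = self._grad
        g = self._g
        last_k = max(k for k, _, _ in self.pending)
        start = max(0, (last_k + 1) - cfg.bptt_max_window)
        X = np.asarray(self.X[start:last_k + 1])
        if cfg.recurrent:
            h0 = np.zeros(cfg.ca3_size)
            Hs, R, Z, Nc, HH = gru_forward(self.p["Wx"], self.p["Uh"],
                                           self.p["bi"], self.p["bh"], X, h0)
            dH = np.zeros((X.shape[0], cfg.ca3_size))
            for k, a, target in self.pending:
                t = k - start
                h = Hs[t + 1]
                dh = self._readout_backward(h, a, target, g)
                dH[t] += dh
            dWx, dUh, dbi, dbh = gru_backward(self.p["Wx"], self.p["Uh"], X,
                                              Hs, R, Z, Nc, HH, dH)
            g["Wx"] += dWx
            g["bi"] += dbi
            if cfg.architecture == RECURRENT_FIXED:
                pass                    # CA3 recurrent weights stay frozen
            else:
                g["Uh"] += dUh
                g["bh"] += dbh
        else:
            for k, a, target in self.pending:
                x = self.X[k]
                pre1 = self.p["W1"] @ x + self.p["b1"]
                h = relu(pre1)
                dh = self._readout_backward(h, a, target, g)
                dpre = dh * (pre1 > 0)
                g["W1"] += np.outer(dpre, x)
                g["b1"] += dpre
        self.pending = []
        if self.consolidation is not None:
            self.consolidation.accumulate(self, grad)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient (diverged)")
        theta_before = self.theta.copy()
        self.opt.step(self.theta, grad)
        if self.consolidation is not None:
            self.consolidation.post_step(self, theta_before, grad)
        self.update_count += 1
        if self.update_count % cfg.target_update == 0:
            self._refresh_target()

    def _readout_backward(self, h, action, target, g) -> np.ndarray:
        """Backward through CA1 and the active head; returns dLoss/dh."""
        i = self.head_idx
        pre2 = self.p["W2"] @ h + self.p["b2"]
        ca1 = relu(pre2)
        q = self.p["W3"][i] @ ca1 + self.p["b3"][i]
        dq = 2.0 * (q[action] - target)
        dca1 = dq * self.p["W3"][i, action]
        dpre2 = dca1 * (pre2 > 0)
        g["W3"][i, action] += dq * ca1
        g["b3"][i, action] += dq
        g["W2"] += np.outer(dpre2, h)
        g["b2"] += dpre2
        return self.p["W2"].T @ dpre2

    def _refresh_target(self):
        self.theta_tgt[:] = self.theta
        if self.config.recurrent and self.X:
            # replay the episode prefix through the refreshed target network
            X = np.asarray(self.X)
            Hs, *_ = gru_forward(self.pt["Wx"], self.pt["Uh"], self.pt["bi"],
                                 self.pt["bh"], X, np.zeros(self.config.ca3_size))
            self.h_tgt = Hs[-1]

    def td_loss(self, obs, action, reward, next_obs, done) -> float:
        """Squared TD error of a single transition under the current
        parameters (diagnostic; does not update anything)."""
        q = self.q_values(obs, advance=False)
        if done:
            target = float(reward)
        else:
            target = float(reward) + self.config.gamma * \
                self._target_q(self._prep(next_obs))
        return float((target - q[int(action)]) ** 2)

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict:
        return {"theta": self.theta.copy(),
                "theta_tgt": self.theta_tgt.copy(),
                "opt": self.opt.state_dict(),
                "update_count": self.update_count}

    def load_state_dict(self, d: dict) -> None:
        self.theta[:] = d["theta"]
        self.theta_tgt[:] = d["theta_tgt"]
        self.opt.load_state_dict(d["opt"])
        self.update_count = int(d["update_count"])
        self._reset_episode()

    def clone_for_eval(self) -> "Agent":
        other = Agent(self.config, seed=0)
        other.load_state_dict(self.state_dict())
        other.learning = False
        return other


# -- continual-learning penalties -------------------------------------------

def consolidation_penalty(theta: np.ndarray, anchor: np.ndarray,
                          omega: np.ndarray, importance: float) -> float:
    """Quadratic anchor penalty  lambda_c * sum_w Omega_w (theta_w - theta*_w)^2.

    Used by both elastic weight consolidation (Omega = diagonal Fisher
    information accumulated at task end) and synaptic intelligence (Omega =
    normalized online path integral)."""
    d = theta - anchor
    return float(importance * np.sum(omega * d * d))


def consolidation_grad(theta, anchor, omega, importance):
    return 2.0 * importance * omega * (theta - anchor)


class ConsolidationPenalty:
    """EWC / SI regularizer attached to an :class:`Agent`.

    ``method='ewc'``: call :meth:`consolidate_ewc` at a task boundary with
    recorded TD-loss gradients; the diagonal Fisher is their mean square.
    ``method='si'``: importances accumulate online as omega_w +=
    -g_w * delta_theta_w during training, normalized by squared parameter
    displacement at :meth:`consolidate_si`.
    Default importance weights: EWC 800, SI 30.
    """

    def __init__(self, method: str, importance: Optional[float] = None,
                 xi: float = 1e-3):
        if method not in ("ewc", "si"):
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.importance = importance if importance is not None else \
            (800.0 if method == "ewc" else 30.0)
        self.xi = xi
        self.anchor = None
        self.omega = None
        self._w = None                  # SI path integral
        self._theta_task_start = None
        self._fisher_acc = None
        self._fisher_n = 0

    def penalty(self, agent: Agent) -> float:
        if self.anchor is None:
            return 0.0
        return consolidation_penalty(agent.theta, self.anchor, self.omega,
                                     self.importance)

    # hooks called by Agent._update -----------------------------------------

    def accumulate(self, agent: Agent, grad: np.ndarray) -> None:
        if self.anchor is not None:
            grad += consolidation_grad(agent.theta, self.anchor, self.omega,
                                       self.importance)
        if self.method == "ewc":
            if self._fisher_acc is None:
                self._fisher_acc = np.zeros_like(grad)
            self._fisher_acc += grad * grad
            self._fisher_n += 1

    def post_step(self, agent: Agent, theta_before, grad) -> None:
        if self.method == "si":
            if self._w is None:
                self._w = np.zeros_like(agent.theta)
                self._theta_task_start = theta_before.copy()
            self._w += -grad * (agent.theta - theta_before)

    def end_episode(self, agent: Agent) -> None:
        pass

    # task-boundary consolidation --------------------------------------------

    def consolidate(self, agent: Agent) -> None:
        if self.method == "ewc":
            fisher = (self._fisher_acc / max(1, self._fisher_n)
                      if self._fisher_acc is not None
                      else np.zeros_like(agent.theta))
            self.omega = fisher if self.omega is None else self.omega + fisher
            self._fisher_acc = None
            self._fisher_n = 0
        else:
            if self._w is None:
                self._w = np.zeros_like(agent.theta)
                self._theta_task_start = agent.theta.copy()
            disp = agent.theta - self._theta_task_start
            contrib = self._w / (disp * disp + self.xi)
            self.omega = contrib if self.omega is None else self.omega + contrib
            self._w = None
            self._theta_task_start = None
        self.anchor = agent.theta.copy()
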