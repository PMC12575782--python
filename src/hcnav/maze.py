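"""Grid-world plus-maze converted per trial into a T-maze.

The maze is a static plus shape on a (2L+1) x 9 grid of scalar cell codes,
where L is the length (in steps) of each start corridor.  Two start arms
(north / south) run vertically into a central junction; two short terminal
arms (east / west, 2 steps each) hold the rewarded and unrewarded goals.
Each trial walls off the start arm the agent does not use, turning the plus
into a T.  Four cues sit on wall cells flanking the start corridors: key and
square mark the north start, lava and ball the south one, so the initial
egocentric view disambiguates the starting position.

Observations are egocentric V x V windows with the agent at the bottom
centre, covering the cells ahead and to the sides but never behind.  Inside
a terminal arm every entry except the agent's own cell is masked, which is
what makes the task partially observable at the moment of commitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np

# Closed cell-code vocabulary.
EMPTY = 0.0
WALL = 1.0
CUE_KEY = 2.0      # north start, west wall
CUE_SQUARE = 3.0   # north start, east wall
CUE_LAVA = 4.0     # south start, west wall
CUE_BALL = 5.0     # south start, east wall
DISTRACTOR = 6.0
MASKED = -1.0
# Orientation of the agent, marked only in the full (allocentric) view.
AGENT_CODES = (7.0, 8.0, 9.0, 10.0)  # facing N, E, S, W

CUE_CODES = (CUE_KEY, CUE_SQUARE, CUE_LAVA, CUE_BALL)

# Orientations: 0=N, 1=E, 2=S, 3=W; rotations are +-1 mod 4.
N, E, S, W = 0, 1, 2, 3
_FORWARD = {N: (-1, 0), E: (0, 1), S: (1, 0), W: (0, -1)}
_RIGHT = {N: E, E: S, S: W, W: N}

FORWARD, ROTATE_LEFT, ROTATE_RIGHT = 0, 1, 2
ACTIONS = (FORWARD, ROTATE_LEFT, ROTATE_RIGHT)

ARM_LENGTH = 2          # terminal arms never change length
DEFAULT_CORRIDOR = 4
DEFAULT_MAX_STEPS = 128
DEFAULT_POST_TERMINAL = 3


class GeometryError(ValueError):
    """Raised when a requested maze does not fit its grid."""


@dataclass(frozen=True)
class PerturbationSpec:
    """One generalization-test manipulation of the base maze.

    kind:
      - ``corridor_length``: longer start corridors (``length``), arms fixed.
      - ``cue_removal``: delete the listed cue codes for the whole trial.
      - ``distractor``: add one novel-code cell just below each cue pair.
      - ``gaussian_noise``: add N(0, sigma2) draws to cue codes in the
        emitted observation only, fresh every step.
      - ``probabilistic_cues``: each cue independently visible per step with
        probability ``cue_prob`` (invisible cues render as empty).
    """

    kind: str
    length: int = DEFAULT_CORRIDOR
    removed_cues: tuple = CUE_CODES
    noise_var: float = 1.0
    cue_prob: float = 1.0

    def __post_init__(self):
        kinds = ("corridor_length", "cue_removal", "distractor",
                 "gaussian_noise", "probabilistic_cues")
        if self.kind not in kinds:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass(frozen=True)
class TrialSpec:
    """Rule, start arm and reward side for one trial.

    ``reward_side`` is a world side ('east'/'west') under the allocentric
    rule and an agent-relative side ('right'/'left') under the egocentric
    rule.  Defaults follow the task: egocentric reward on the agent's right,
    allocentric reward on a fixed world arm (east by default) regardless of
    the start.
    """

    rule: str = "allocentric"
    start_arm: str = "north"
    reward_side: Optional[str] = None

    def __post_init__(self):
        if self.rule not in ("allocentric", "egocentric"):
            raise ValueError(f"bad rule {self.rule!r}")
        if self.start_arm not in ("north", "south"):
            raise ValueError(f"bad start arm {self.start_arm!r}")
        if self.reward_side is None:
            side = "east" if self.rule == "allocentric" else "right"
            object.__setattr__(self, "reward_side", side)

    @property
    def head(self) -> str:
        return "allo" if self.rule == "allocentric" else "ego"

    @property
    def label(self) -> str:
        return f"{self.head}-{self.start_arm}"


SUBTASKS = (
    TrialSpec("allocentric", "north"),
    TrialSpec("allocentric", "south"),
    TrialSpec("egocentric", "north"),
    TrialSpec("egocentric", "south"),
)


@dataclass
class MazeLayout:
    grid: np.ndarray                    # rows x cols of cell codes
    corridor_length: int
    junction: tuple
    start_cells: dict                   # {'north': (r,c), 'south': (r,c)}
    terminal_cells: dict                # {'east': (r,c), 'west': (r,c)}
    cue_cells: list = field(default_factory=list)   # [((r,c), code), ...]
    distractor_cells: list = field(default_factory=list)

    @property
    def shape(self):
        return self.grid.shape


def configure_maze(corridor_length: int = DEFAULT_CORRIDOR,
                   perturbation: Optional[PerturbationSpec] = None,
                   grid_shape: Optional[tuple] = None) -> MazeLayout:
    """Build the plus-maze layout, optionally perturbed.

    The grid autosizes to ``(2*corridor_length + 1, 9)`` unless an explicit
    ``grid_shape`` is given, in which case a corridor that does not fit
    raises :class:`GeometryError`.
    """
    length = corridor_length
    if perturbation is not None and perturbation.kind == "corridor_length":
        length = int(perturbation.length)
    if length < 1:
        raise GeometryError("corridor_length must be >= 1")
    n_rows = 2 * length + 1
    n_cols = 9
    if grid_shape is not None:
        if grid_shape[0] < n_rows or grid_shape[1] < n_cols:
            raise GeometryError(
                f"corridor_length {length} needs a grid of at least "
                f"({n_rows}, {n_cols}); got {grid_shape}")
        n_rows, n_cols = grid_shape

    grid = np.full((n_rows, n_cols), WALL)
    mid = length                       # junction row
    col = 4                            # corridor column
    grid[0:2 * length + 1, col] = EMPTY            # north+south corridors
    grid[mid, col - ARM_LENGTH:col + ARM_LENGTH + 1] = EMPTY   # E/W arms

    junction = (mid, col)
    start_cells = {"north": (0, col), "south": (2 * length, col)}
    terminal_cells = {"west": (mid, col - ARM_LENGTH),
                      "east": (mid, col + ARM_LENGTH)}

    cue_cells = [((1, col - 1), CUE_KEY), ((1, col + 1), CUE_SQUARE),
                 ((2 * length - 1, col - 1), CUE_LAVA),
                 ((2 * length - 1, col + 1), CUE_BALL)]

    layout = MazeLayout(grid=grid, corridor_length=length, junction=junction,
                        start_cells=start_cells, terminal_cells=terminal_cells,
                        cue_cells=cue_cells)

    if perturbation is not None:
        if perturbation.kind == "cue_removal":
            present = {code for _, code in layout.cue_cells}
            for code in perturbation.removed_cues:
                if code not in present:
                    warnings.warn(f"cue code {code} not present; ignoring")
            layout.cue_cells = [(pos, code) for pos, code in layout.cue_cells
                                if code not in perturbation.removed_cues]
        elif perturbation.kind == "distractor":
            # a single novel-code cell just below the existing (north) cue
            # pair, entering the start-corridor views of that arm
            layout.distractor_cells = [((2, col - 1), DISTRACTOR)]

    for (r, c), code in layout.cue_cells + layout.distractor_cells:
        layout.grid[r, c] = code
    return layout


@dataclass
class EnvState:
    position: tuple
    orientation: int
    step_count: int = 0
    phase: str = "active"               # active | post_terminal | finished
    post_steps_left: int = DEFAULT_POST_TERMINAL
    reached_terminal: Optional[str] = None   # 'east'/'west' once entered
    reward_collected: float = 0.0


def rewarded_terminal(trial: TrialSpec) -> str:
    """World side ('east'/'west') of the rewarded arm for this trial."""
    if trial.rule == "allocentric":
        return trial.reward_side
    # egocentric: relative to the agent's heading along the start corridor
    facing = S if trial.start_arm == "north" else N
    right = {S: "west", N: "east"}[facing]
    return right if trial.reward_side == "right" else \
        ("east" if right == "west" else "west")


def trial_grid(layout: MazeLayout, trial: TrialSpec) -> np.ndarray:
    """Grid with the opposite start arm walled off (plus-maze -> T-maze)."""
    g = layout.grid.copy()
    mid, col = layout.junction
    if trial.start_arm == "north":
        g[mid + 1:, col] = WALL
    else:
        g[:mid, col] = WALL
    return g


def _in_terminal_arm(layout: MazeLayout, pos) -> bool:
    mid, col = layout.junction
    return pos[0] == mid and pos[1] != col


def observe(layout: MazeLayout, grid: np.ndarray, state: EnvState,
            view_mode: str = "3x3",
            perturbation: Optional[PerturbationSpec] = None,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Egocentric V x V window (or the full grid for view_mode='full').

    Partial views place the agent at the bottom-centre cell of a
    forward-facing window; cells behind the agent are never included and
    out-of-grid cells are padded with the wall code.  Inside a terminal arm
    all entries except the agent's own cell carry the masked code.
    """
    g = grid
    if perturbation is not None and perturbation.kind == "probabilistic_cues":
        if rng is None:
            raise ValueError("probabilistic_cues needs an rng")
        g = g.copy()
        for (r, c), code in layout.cue_cells:
            if g[r, c] == code and rng.random() > perturbation.cue_prob:
                g[r, c] = EMPTY

    r0, c0 = state.position
    if view_mode == "full":
        view = g.copy()
        view[r0, c0] = AGENT_CODES[state.orientation]
    else:
        v = int(view_mode[0])
        fr, fc = _FORWARD[state.orientation]
        rr, rc = _FORWARD[_RIGHT[state.orientation]]
        view = np.full((v, v), WALL)
        for i in range(v):              # i = 0 front row ... v-1 agent row
            for j in range(v):
                d_fwd = v - 1 - i
                d_rgt = j - v // 2
                wr = r0 + d_fwd * fr + d_rgt * rr
                wc = c0 + d_fwd * fc + d_rgt * rc
                if 0 <= wr < g.shape[0] and 0 <= wc < g.shape[1]:
                    view[i, j] = g[wr, wc]
        if _in_terminal_arm(layout, state.position):
            own = view[v - 1, v // 2]
            view[:] = MASKED
            view[v - 1, v // 2] = own

    if perturbation is not None and perturbation.kind == "gaussian_noise":
        if rng is None:
            raise ValueError("gaussian_noise needs an rng")
        cue_mask = np.isin(view, CUE_CODES + (DISTRACTOR,))
        if cue_mask.any():
            view = view.astype(float, copy=True)
            view[cue_mask] += rng.normal(
                0.0, np.sqrt(perturbation.noise_var), cue_mask.sum())
    return view


def reset_trial(layout: MazeLayout, trial: TrialSpec,
                view_mode: str = "3x3",
                perturbation: Optional[PerturbationSpec] = None,
                rng: Optional[np.random.Generator] = None,
                post_terminal_steps: int = DEFAULT_POST_TERMINAL):
    """Place the agent at the trial's start cell facing the junction."""
    pos = layout.start_cells[trial.start_arm]
    ori = S if trial.start_arm == "north" else N
    state = EnvState(position=pos, orientation=ori,
                     post_steps_left=post_terminal_steps)
    grid = trial_grid(layout, trial)
    obs = observe(layout, grid, state, view_mode, perturbation, rng)
    return state, obs


def step(state: EnvState, layout: MazeLayout, trial: TrialSpec, action: int,
         grid: Optional[np.ndarray] = None, view_mode: str = "3x3",
         perturbation: Optional[PerturbationSpec] = None,
         rng: Optional[np.random.Generator] = None,
         max_steps: int = DEFAULT_MAX_STEPS):
    """Advance one step.  Returns (state, observation, reward, done).

    Forward moves one cell unless blocked by a wall (position unchanged);
    rotations change orientation only.  Entering the rewarded terminal
    yields reward 1, the unrewarded one 0; both start a post-terminal phase
    of free exploration, after which the episode finishes.  Hitting
    ``max_steps`` truncates with reward 0 (an incorrect trial).
    """
    if action not in ACTIONS:
        raise ValueError(f"invalid action {action!r}")
    if state.phase == "finished":
        raise RuntimeError("step() on a finished episode")
    if grid is None:
        grid = trial_grid(layout, trial)

    reward = 0.0
    if action == FORWARD:
        dr, dc = _FORWARD[state.orientation]
        nr, nc = state.position[0] + dr, state.position[1] + dc
        in_bounds = 0 <= nr < grid.shape[0] and 0 <= nc < grid.shape[1]
        if in_bounds and grid[nr, nc] != WALL:
            state.position = (nr, nc)
    elif action == ROTATE_LEFT:
        state.orientation = (state.orientation - 1) % 4
    else:
        state.orientation = (state.orientation + 1) % 4
    state.step_count += 1

    if state.phase == "active":
        for side, cell in layout.terminal_cells.items():
            if state.position == cell:
                state.phase = "post_terminal"
                state.reached_terminal = side
                if side == rewarded_terminal(trial):
                    reward = 1.0
                    state.reward_collected = 1.0
                break
    elif state.phase == "post_terminal":
        state.post_steps_left -= 1
        if state.post_steps_left <= 0:
            state.phase = "finished"

    if state.step_count >= max_steps and state.phase != "finished":
        state.phase = "finished"

    done = state.phase == "finished"
    obs = observe(layout, grid, state, view_mode, perturbation, rng)
    return state, obs, reward, done


def optimal_path(layout: MazeLayout, trial: TrialSpec) -> list:
    """Shortest start -> rewarded-terminal cell sequence (BFS).

    With the default geometry this is the 7-state trajectory used by the
    behaviour profiles; a corridor of length L gives L + 3 states.
    """
    from collections import deque
    grid = trial_grid(layout, trial)
    start = layout.start_cells[trial.start_arm]
    goal = layout.terminal_cells[rewarded_terminal(trial)]
    prev = {start: None}
    q = deque([start])
    while q:
        cell = q.popleft()
        if cell == goal:
            path = []
            while cell is not None:
                path.append(cell)
                cell = prev[cell]
            return path[::-1]
        for dr, dc in _FORWARD.values():
            nxt = (cell[0] + dr, cell[1] + dc)
            if (0 <= nxt[0] < grid.shape[0] and 0 <= nxt[1] < grid.shape[1]
                    and grid[nxt] != WALL and nxt not in prev):
                prev[nxt] = cell
                q.append(nxt)
    raise GeometryError("rewarded terminal unreachable from start")


class TMazeEnv:
    """Stateful wrapper bundling layout, observability and perturbation.

    ``post_terminal_steps`` defaults to 3; the activation-recording mode
    used by the demixing analysis extends it (learning is frozen at the
    terminal transition either way).
    """

    def __init__(self, layout: Optional[MazeLayout] = None,
                 view_mode: str = "3x3",
                 perturbation: Optional[PerturbationSpec] = None,
                 max_steps: int = DEFAULT_MAX_STEPS,
                 post_terminal_steps: int = DEFAULT_POST_TERMINAL,
                 rng: Optional[np.random.Generator] = None):
        self.layout = layout if layout is not None else configure_maze(
            perturbation=perturbation)
        self.view_mode = view_mode
        self.perturbation = perturbation
        self.max_steps = max_steps
        self.post_terminal_steps = post_terminal_steps
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.trial = None
        self.state = None
        self._grid = None

    @property
    def obs_size(self) -> int:
        if self.view_mode == "full":
            return int(np.prod(self.layout.shape))
        return int(self.view_mode[0]) ** 2

    def reset(self, trial: TrialSpec) -> np.ndarray:
        self.trial = trial
        self._grid = trial_grid(self.layout, trial)
        self.state = EnvState(
            position=self.layout.start_cells[trial.start_arm],
            orientation=S if trial.start_arm == "north" else N,
            post_steps_left=self.post_terminal_steps)
        return observe(self.layout, self._grid, self.state, self.view_mode,
                       self.perturbation, self.rng)

    def step(self, action: int):
        self.state, obs, reward, done = step(
            self.state, self.layout, self.trial, action, self._grid,
            self.view_mode, self.perturbation, self.rng, self.max_steps)
        return obs, reward, done

    @property
    def succeeded(self) -> bool:
        return self.state is not None and self.state.reward_collected > 0


def scripted_optimal_action(layout: MazeLayout, trial: TrialSpec,
                            state: EnvState) -> int:
    """Oracle policy: forward along the optimal path, rotating as needed."""
    path = optimal_path(layout, trial)
    try:
        i = path.index(state.position)
    except ValueError:
        return FORWARD
    if i + 1 >= len(path):
        return FORWARD
    nxt = path[i + 1]
    want = (nxt[0] - state.position[0], nxt[1] - state.position[1])
    facing = _FORWARD[state.orientation]
    if want == facing:
        return FORWARD
    if want == _FORWARD[_RIGHT[state.orientation]]:
        return ROTATE_RIGHT
    return ROTATE_LEFT


def scripted_turn_right_action(grid: np.ndarray, state: EnvState) -> int:
    """Fixed policy: forward when the cell ahead is open, else rotate right."""
    dr, dc = _FORWARD[state.orientation]
    nr, nc = state.position[0] + dr, state.position[1] + dc
    open_ahead = (0 <= nr < grid.shape[0] and 0 <= nc < grid.shape[1]
                  and grid[nr, nc] != WALL)
    return FORWARD if open_ahead else ROTATE_RIGHT
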