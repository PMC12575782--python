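"""Environment contracts: geometry, observability, rules, scripted policies."""

import numpy as np
import pytest

from hcnav import maze
from hcnav.maze import (ARM_LENGTH, CUE_CODES, EMPTY, MASKED, WALL,
                        FORWARD, ROTATE_LEFT, ROTATE_RIGHT,
                        GeometryError, PerturbationSpec, TMazeEnv, TrialSpec,
                        SUBTASKS, configure_maze, observe, optimal_path,
                        reset_trial, rewarded_terminal,
                        scripted_optimal_action, scripted_turn_right_action,
                        trial_grid)


class TestConfigureMaze:
    def test_default_layout(self):
        lay = configure_maze()
        assert lay.grid.shape == (9, 9)
        assert lay.corridor_length == 4
        assert len(lay.cue_cells) == 4
        assert len(lay.terminal_cells) == 2
        codes = {c for _, c in lay.cue_cells}
        assert codes == set(CUE_CODES)

    def test_full_cue_removal_keeps_geometry(self):
        lay = configure_maze(perturbation=PerturbationSpec("cue_removal"))
        base = configure_maze()
        assert lay.cue_cells == []
        expected = base.grid.copy()
        for pos, _ in base.cue_cells:
            expected[pos] = WALL         # cue codes sit on wall cells
        assert np.array_equal(lay.grid, expected)

    def test_removing_absent_cue_warns(self):
        pert = PerturbationSpec("cue_removal", removed_cues=(99.0,))
        with pytest.warns(UserWarning):
            lay = configure_maze(perturbation=pert)
        assert len(lay.cue_cells) == 4

    @pytest.mark.parametrize("length", [1, 4, 12, 32])
    def test_corridor_length_bfs_oracle(self, length):
        # breadth-first path length = corridor + rotation-free arm steps
        lay = configure_maze(
            perturbation=PerturbationSpec("corridor_length", length=length))
        for trial in SUBTASKS:
            path = optimal_path(lay, trial)
            assert len(path) == length + ARM_LENGTH + 1

    def test_corridor_too_long_for_grid(self):
        with pytest.raises(GeometryError):
            configure_maze(corridor_length=8, grid_shape=(9, 9))

    def test_distractor_added_next_to_cues(self):
        lay = configure_maze(perturbation=PerturbationSpec("distractor"))
        assert len(lay.cue_cells) == 4
        assert len(lay.distractor_cells) == 1
        cue_rows = {pos[0] for pos, _ in lay.cue_cells}
        (r, c), code = lay.distractor_cells[0]
        assert code == maze.DISTRACTOR
        assert min(abs(r - cr) for cr in cue_rows) == 1

    def test_single_connected_path_from_each_start(self):
        lay = configure_maze()
        for trial in SUBTASKS:
            path = optimal_path(lay, trial)
            assert path[0] == lay.start_cells[trial.start_arm]
            assert path[-1] == lay.terminal_cells[rewarded_terminal(trial)]


class TestRules:
    def test_egocentric_reward_right_of_start(self):
        # facing south from the north start, the agent's right is west
        assert rewarded_terminal(TrialSpec("egocentric", "north")) == "west"
        assert rewarded_terminal(TrialSpec("egocentric", "south")) == "east"

    def test_allocentric_same_terminal_for_both_starts(self):
        t_n = TrialSpec("allocentric", "north", "west")
        t_s = TrialSpec("allocentric", "south", "west")
        assert rewarded_terminal(t_n) == rewarded_terminal(t_s) == "west"

    def test_opposite_arm_blocked(self):
        lay = configure_maze()
        g = trial_grid(lay, TrialSpec("allocentric", "north"))
        assert (g[lay.corridor_length + 1:, 4] == WALL).all()
        g = trial_grid(lay, TrialSpec("allocentric", "south"))
        assert (g[:lay.corridor_length, 4] == WALL).all()


class TestObservation:
    def test_partial_and_full_sizes(self):
        lay = configure_maze()
        for trial in SUBTASKS:
            _, obs = reset_trial(lay, trial, view_mode="3x3")
            assert obs.size == 9
            _, obs = reset_trial(lay, trial, view_mode="full")
            assert obs.size == 81

    def test_cues_visible_at_start_only_for_own_arm(self):
        lay = configure_maze()
        _, obs_n = reset_trial(lay, TrialSpec("allocentric", "north"))
        assert maze.CUE_KEY in obs_n and maze.CUE_SQUARE in obs_n
        assert maze.CUE_LAVA not in obs_n and maze.CUE_BALL not in obs_n
        _, obs_s = reset_trial(lay, TrialSpec("allocentric", "south"))
        assert maze.CUE_LAVA in obs_s and maze.CUE_BALL in obs_s

    def test_masked_inside_terminal_arm(self):
        lay = configure_maze()
        trial = TrialSpec("egocentric", "north")
        state = maze.EnvState(position=(4, 3), orientation=maze.W)
        view = observe(lay, trial_grid(lay, trial), state)
        assert view[2, 1] != MASKED          # own cell kept
        assert (view.ravel() == MASKED).sum() == 8

    def test_terminal_reward_not_observable(self):
        # the emitted codes never encode which arm is rewarded
        lay = configure_maze()
        obs_by_side = []
        for side in ("east", "west"):
            trial = TrialSpec("allocentric", "north", side)
            _, obs = reset_trial(lay, trial)
            obs_by_side.append(obs)
        assert np.array_equal(*obs_by_side)

    def test_aliasing_of_junction_approach(self):
        # the 3x3 views approaching the junction from either start match
        lay = configure_maze()
        g_n = trial_grid(lay, TrialSpec("allocentric", "north"))
        g_s = trial_grid(lay, TrialSpec("allocentric", "south"))
        s_n = maze.EnvState(position=(3, 4), orientation=maze.S)
        s_s = maze.EnvState(position=(5, 4), orientation=maze.N)
        assert np.array_equal(observe(lay, g_n, s_n), observe(lay, g_s, s_s))

    def test_closed_code_vocabulary(self):
        lay = configure_maze(perturbation=PerturbationSpec("distractor"))
        allowed = {EMPTY, WALL, maze.DISTRACTOR, MASKED, *CUE_CODES}
        env = TMazeEnv(layout=lay, rng=np.random.default_rng(0))
        obs = env.reset(TrialSpec("egocentric", "south"))
        rng = np.random.default_rng(1)
        done = False
        while not done:
            assert set(np.unique(obs)) <= allowed
            obs, _, done = env.step(int(rng.integers(3)))


class TestStep:
    def test_forward_into_wall_keeps_position(self):
        env = TMazeEnv(rng=np.random.default_rng(0))
        env.reset(TrialSpec("allocentric", "north"))
        env.step(ROTATE_LEFT)           # face east toward the wall
        pos = env.state.position
        env.step(FORWARD)
        assert env.state.position == pos
        assert env.state.step_count == 2

    def test_rotation_cycle(self):
        env = TMazeEnv(rng=np.random.default_rng(0))
        env.reset(TrialSpec("allocentric", "north"))
        assert env.state.orientation == maze.S
        env.step(ROTATE_LEFT)
        assert env.state.orientation == maze.E
        env.step(ROTATE_RIGHT)
        assert env.state.orientation == maze.S

    def test_reward_and_post_terminal_phase(self):
        env = TMazeEnv(rng=np.random.default_rng(0))
        trial = TrialSpec("egocentric", "north")
        env.reset(trial)
        rewards = []
        done = False
        while not done:
            a = scripted_optimal_action(env.layout, trial, env.state)
            _, r, done = env.step(a)
            rewards.append(r)
            if env.state.phase == "post_terminal" and len(rewards) and \
                    rewards[-1] == 1.0:
                assert env.state.post_steps_left == 3
        assert sum(rewards) == 1.0
        # exactly 3 steps executed after the terminal entry
        assert env.state.step_count == 7 + 3

    def test_truncation_is_incorrect_trial(self):
        env = TMazeEnv(max_steps=10, rng=np.random.default_rng(0))
        env.reset(TrialSpec("allocentric", "north"))
        done = False
        while not done:
            _, r, done = env.step(ROTATE_LEFT)
        assert env.state.step_count == 10
        assert not env.succeeded

    def test_invalid_action_rejected(self):
        env = TMazeEnv(rng=np.random.default_rng(0))
        env.reset(TrialSpec("allocentric", "north"))
        with pytest.raises(ValueError):
            env.step(5)

    def test_reset_determinism(self):
        pert = PerturbationSpec("probabilistic_cues", cue_prob=0.5)
        a = TMazeEnv(perturbation=pert, rng=np.random.default_rng(3))
        b = TMazeEnv(perturbation=pert, rng=np.random.default_rng(3))
        trial = TrialSpec("allocentric", "south")
        assert np.array_equal(a.reset(trial), b.reset(trial))


class TestScriptedPolicies:
    def test_optimal_policy_step_count(self):
        # len(path)-1 forward moves plus exactly one rotation
        lay = configure_maze()
        for trial in SUBTASKS:
            env = TMazeEnv(rng=np.random.default_rng(0))
            env.reset(trial)
            n_actions = 0
            while env.state.phase == "active":
                a = scripted_optimal_action(lay, trial, env.state)
                env.step(a)
                n_actions += 1
            assert env.succeeded
            assert n_actions == len(optimal_path(lay, trial)) - 1 + 1

    def test_turn_right_policy_succeeds_on_exactly_three_subtasks(self):
        outcomes = {}
        for trial in SUBTASKS:
            env = TMazeEnv(rng=np.random.default_rng(0))
            env.reset(trial)
            done = False
            while not done:
                a = scripted_turn_right_action(env._grid, env.state)
                _, _, done = env.step(a)
            outcomes[trial.label] = env.succeeded
        assert sum(outcomes.values()) == 3
        assert not outcomes["allo-north"]


class TestOptimalPath:
    def test_default_has_seven_states(self):
        lay = configure_maze()
        for trial in SUBTASKS:
            assert len(optimal_path(lay, trial)) == 7

    def test_endpoints_are_start_and_reward(self):
        lay = configure_maze()
        t = TrialSpec("allocentric", "south")
        path = optimal_path(lay, t)
        assert path[0] == lay.start_cells["south"]
        assert path[-1] == lay.terminal_cells[rewarded_terminal(t)]

    def test_long_corridor_path_length(self):
        pert = PerturbationSpec("corridor_length", length=32)
        lay = configure_maze(perturbation=pert)
        assert len(optimal_path(lay, SUBTASKS[0])) == 7 + (32 - 4)


class TestPerturbedObservations:
    def test_probabilistic_cues_resampled_each_step(self):
        pert = PerturbationSpec("probabilistic_cues", cue_prob=0.5)
        env = TMazeEnv(perturbation=pert, rng=np.random.default_rng(0))
        trial = TrialSpec("allocentric", "north")
        seen = set()
        for _ in range(40):
            obs = env.reset(trial)
            seen.add(tuple(obs.ravel()))
        assert len(seen) > 1             # visibility varies across resets

    def test_gaussian_noise_touches_only_cues(self):
        pert = PerturbationSpec("gaussian_noise", noise_var=4.0)
        lay = configure_maze()
        trial = TrialSpec("allocentric", "north")
        g = trial_grid(lay, trial)
        state = maze.EnvState(position=lay.start_cells["north"],
                              orientation=maze.S)
        clean = observe(lay, g, state)
        noisy = observe(lay, g, state, perturbation=pert,
                        rng=np.random.default_rng(0))
        changed = clean != noisy
        assert changed.any()
        assert set(np.unique(clean[changed])) <= set(CUE_CODES)

    def test_zero_variance_noise_is_identity(self):
        pert = PerturbationSpec("gaussian_noise", noise_var=0.0)
        lay = configure_maze()
        trial = TrialSpec("allocentric", "north")
        g = trial_grid(lay, trial)
        state = maze.EnvState(position=lay.start_cells["north"],
                              orientation=maze.S)
        assert np.allclose(
            observe(lay, g, state),
            observe(lay, g, state, perturbation=pert,
                    rng=np.random.default_rng(0)))
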