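# Example run configuration: maze/task settings plus agent hyperparameters.
# Keys mirror AgentConfig field names; maze keys feed configure_maze /
# TMazeEnv; schedule keys feed build_schedule.

maze:
  corridor_length: 4
  view_mode: 3x3
  max_steps: 128
  post_terminal_steps: 3
  allo_reward_side: east
  perturbation: null          # e.g. {kind: probabilistic_cues, cue_prob: 0.8}

agent:
  architecture: recurrent     # recurrent | feedforward | recurrent_fixed
  input_size: 9
  ca3_size: 50
  ca1_size: 50
  heads: two_head             # or task_id_single_head
  gamma: 0.9
  lr: 0.001
  eps_start: 0.3
  eps_end: 0.05
  bptt_interval: 2
  bptt_max_window: 128
  target_update: 25

schedule:
  total_trials: 4000
  block_size: 10
  ego_mode: alternating

seed: 0
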