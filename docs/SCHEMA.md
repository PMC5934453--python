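# Session directory schema

A session is a directory of plain-text files written by
`probreach.write_session` and validated by `probreach.read_session`.

## manifest.yaml

| key | meaning |
| --- | --- |
| `condition` | `baseline` or `vr` |
| `seed` | RNG seed; replaying it with the stored parameters reproduces every table bit-for-bit (−1 when simulated without an explicit seed) |
| `workspace` | `half_width` (cm), `center` (x, y) |
| `task_params` | all `TaskParams` fields (distances cm, times ms, `vr_rotation_deg`) |
| `behavior_params` | all `BehaviorParams` fields |

## reaches.csv — one row per reach

| column | units | meaning |
| --- | --- | --- |
| `reach_id` | — | global 1-based index |
| `trial_id` | — | trial number (4 reaches per trial) |
| `index_in_trial` | — | 1–4; reach 1 is excluded from analyses |
| `start_x`, `start_y` | cm | hand/cursor position at target onset (screen frame) |
| `target_x`, `target_y` | cm | target location (screen frame) |
| `hold_start_time` | ms | landing on the previous target (hold begins) |
| `target_command_time` | ms | computer sends the target command |
| `target_onset_time` | ms | command + display delay; analyses align here |
| `move_start_time` | ms | onset + planted latency |
| `land_time` | ms | arrival on this reach's target |
| `phi_p` | deg | angular hand position re: workspace center |
| `phi_t` | deg | direction to the target (screen frame) |
| `phi_t_hand` | deg | movement direction in hand coordinates (differs from `phi_t` only under VR) |
| `dist` | cm | start-to-target distance |
| `r_center` | cm | start distance from the workspace center |
| `hold_duration_ms` | ms | achieved hold (< 200 marks a hold violation) |
| `move_duration_ms` | ms | onset to landing (> 1400 marks a timeout) |
| `v_max` | cm/s | peak hand speed of the reach |
| `latency_planted_ms` | ms | generative latency (simulator ground truth) |
| `valid` | bool | False for injected error reaches |
| `exclusion_reason` | — | empty, `hold_violation`, or `timeout` |

## kinematics.csv

`t_ms` (monotone), `hand_x`, `hand_y`, `screen_x`, `screen_y` (cm);
hand and screen coincide in the baseline condition.

## spikes.csv

`neuron_id`, `t_ms` — one row per spike, sorted within neuron; every
`neuron_id` must appear in neurons.csv.

## neurons.csv

`neuron_id`, `area` (`PMd` or `M1`) — observable metadata only.

## truth.csv (synthetic sessions only)

Ground-truth generator attributes, kept apart from observables:
`neuron_id`, `klass` (`PR`/`SR`/`M1-like`), `pd` (deg),
`baseline_rate`, `movement_gain` (sp/s), `movement_concentration`,
`prob_gain` (sp/s), `m1_decay_ms`.
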