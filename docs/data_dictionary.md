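# Output data dictionary

All files are written by `motorcargo.io.write_outputs` (and the CLI
subcommands that call it). Units follow the package convention:
nm, s, pN.

## trials.csv — one row per trial

| column | type | meaning |
|---|---|---|
| config_hash | str | 16-hex digest of the full world configuration |
| seed | int | master seed of the trial batch |
| trial | int | trial index (each trial has its own RNG substream) |
| bound / success | bool | binding protocols: did a motor attach before the trial ended |
| t_bind | float s | time of first attachment (NaN if never) |
| escaped | bool | free-binding protocols: trial ended by diffusing past the escape radius |
| t_end | float s | time at which the trial ended |
| run_length_nm | float | transport: net displacement of the cargo center along the plus direction |
| duration_s | float | transport: time from forced attachment to last detachment (or the cap) |
| censored | bool | transport: still attached when the time cap was reached |
| mean_velocity_nm_s | float | run_length / duration |
| mean_engaged | float | time-weighted mean number of attached motors in this trial |

## summary.json

Protocol-specific summary plus `config_hash`, `seed`, `n_trials`;
binding protocols add `fraction_bound`, `mean_t_bind`, `censored`
(true when fewer than 95% of trials bound); transport adds
`mean_run_length_nm`, `n_censored`, `mean_duration_s`; the census adds
`mean_engaged` and `engaged_time_s` (time spent at each engaged count,
index = count).

## events.jsonl — one JSON object per motor event (detailed runs)

| field | meaning |
|---|---|
| t | event time, s |
| motor_id | motor index |
| event | `attach`, `detach` or `step` |
| site_index | binding-site index (8 nm lattice; site i at y = 8·i nm) |
| tension_pN | cable tension at the event (0 for attach) |

## trajectory.csv — strided rigid-body trajectory (detailed runs)

| column | meaning |
|---|---|
| t | time, s |
| x, y, z | cargo center, nm (microtubule axis along y) |
| qw, qx, qy, qz | orientation quaternion, body→lab, scalar first |
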