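# mabumat

Plantar pressure-mat analysis for balance training in the horse stance
(*Mabu*), the wide isometric squat fundamental to Shaolin Kung Fu.  The
package implements the complete computational chain of a pressure-sensitive
training mat and its feedback game — without the hardware — for researchers
and developers working on baropodometric balance assessment, exergames and
remote skill training:

- frame I/O and high-pass filtering of a 12-bit pressure-sensor matrix
  (default 924 cells over a 1000 × 500 mm surface);
- left/right segmentation and center-of-pressure (COP) computation;
- foot-blob geometry: centroid, toe-out angle, heel/forefoot load split,
  stance width, center-line offsets, left/right load balance;
- calibrated validation of the stance against five entry criteria;
- real-time good/poor posture classification with virtual flags, four-band
  lean-severity feedback and a session state machine with a held-time timer;
- gamified scoring (levels, groups, leaderboard);
- a synthetic baropodometry simulator with ground-truth labels;
- session analytics with a from-scratch Mann–Whitney U test.

## The model

Each frame is a matrix *M* of raw 12-bit readings.  A zeroing high-pass
filter removes the foam-layer preload and noise floor: cells below a
threshold β (default 2 % of full scale) are set to zero.  The filtered frame
is split into the left and right half matrices *Ml*, *Mr*, and each COP is
the pressure-weighted centroid of cell-center coordinates:

```
COP_x = Σ v_ij · x_j / Σ v_ij ,   x_j = (j + ½) · pitch_x   (y analogous)
```

Calibration captures a reference frame *Mc* once the stance passes five
criteria (balanced left/right load, feet on the mat's center-line, stance
wider than shoulder width, toe-out between 0° and 45°, balanced heel/sole
pressure).  During training, each frame *Mt* is in the *good* state **Ms**
while every COP stays within a radius α (default 40 mm) of its calibrated
reference, tested per axis with strict bounds:

```
Ms:  COPx_c − α < COPx_t < COPx_c + α   and   COPy_c − α < COPy_t < COPy_c + α
```

applied to the overall, left-foot and right-foot COPs (a Euclidean
circle-region mode is also available).  Leaving any region — or drifting in
foot position, orientation or left/right balance — raises a virtual flag,
switches the frame to the *poor* state **Mp**, freezes the timer and ends
the session.  The normalized displacement d = max(|Δx|, |Δy|)/α drives the
feedback bands: balanced (grey, d ≤ 0.4), slight lean (yellow), severe lean
(red), broken (d ≥ 1, the avatar falls).  Held time converts to one level
per 10 s, grouped as beginner (levels 0–6), intermediate (7–12), veteran
(13–18) and expert (≥ 19).

See `docs/methods.md` for the estimators, the simulator's foot model and
all numerical choices.

## Worked example

```python
import mabumat as mm

config = mm.SensorConfig()
thresholds = mm.ValidationThresholds()
beta = mm.FilterParams()

# 1. render a noisy stance frame and validate the entry criteria
frame, truth = mm.synth_frame(mm.StanceSpec(body_mass_kg=80.0, noise_sd=8.0, seed=1))
filtered = mm.filter_frame(frame, beta)
report = mm.validate_entry_stance(filtered, thresholds, config)
print("entry criteria passed:", report.all_passed)
print("stance width: %.1f mm, toe-out: %.1f / %.1f deg, L/R balance: %.3f"
      % (report.measured["stance_width_mm"],
         report.measured["toe_angle_left_deg"],
         report.measured["toe_angle_right_deg"],
         report.measured["lr_balance"]))

# 2. calibrate, then run a scripted session that breaks by leaning out at 12 s
profile = mm.calibrate(filtered, thresholds, config)
print("calibrated COPo reference: (%.1f, %.1f) mm, alpha = %.0f mm"
      % (profile.cop_o_ref.x, profile.cop_o_ref.y, profile.alpha_mm))

script = mm.SessionScript(fps=20.0, hold_s=15.0, break_at_s=12.0,
                          break_mode="lean_out", seed=1)
frames, script_truth = mm.synth_session(mm.StanceSpec(noise_sd=8.0, seed=1),
                                        script, config)
record, events = mm.run_session(frames, thresholds, config)
print("session state: %s, held %.2f s (scripted break at %.2f s)"
      % (record.state, record.good_duration_s, script_truth.break_at_s))
print("terminal flags:", sorted(record.terminal_flags))
print("final level: %d (%s)" % (record.final_level, record.final_group))
```

prints

```
entry criteria passed: True
stance width: 449.9 mm, toe-out: 18.1 / 18.2 deg, L/R balance: 0.002
calibrated COPo reference: (499.5, 249.3) mm, alpha = 40 mm
session state: BROKEN, held 12.00 s (scripted break at 12.00 s)
terminal flags: ['cop_overall', 'lr_imbalance']
final level: 1 (beginner)
```

The stance enters cleanly (all five criteria pass, measured geometry within
a sensor pitch of the simulated ground truth), the monitor recovers the
scripted 12 s hold to the frame, and the sideways balance loss is flagged as
an overall-COP excursion with a left/right imbalance — not as a foot
movement.  Twelve seconds held yields Level 1 in the beginner group.

The same flow is available from the shell via the `mabumat` command
(`simulate`, `calibrate`, `validate`, `monitor`, `replay`, `leaderboard`,
`report`, `heatmap`); run `mabumat --help` for the options.

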