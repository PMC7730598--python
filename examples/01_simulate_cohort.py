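"""Generate a small synthetic treadmill cohort and look at its structure.

Each subject walks at 3-5 km/h (up to a subject-specific maximum) on both
legs; angles are 13-channel Fourier-series waveforms at 100 Hz and ground
reaction forces are double-hump stance profiles at 1000 Hz.
"""

import numpy as np

import kneeload as kl

cfg = kl.CohortConfig(n_subjects=5, speed_grid=(3, 4, 5), master_seed=7)
profiles = kl.make_cohort(cfg)
trials = kl.synthesize_cohort_trials(profiles, cfg)

print(f"cohort of {len(profiles)} subjects, {len(trials)} recordings\n")
for p in profiles:
    print(f"  {p.subject_id}: {p.age_group:7s} {p.mass:5.1f} kg, "
          f"max speed {p.max_speed} km/h, {p.shod}")

trial = trials[0]
peak_bw = trial.grf[1].max() / trial.subject.body_weight
print(f"\nfirst recording: {trial.subject.subject_id} {trial.side} at "
      f"{trial.speed:g} km/h")
print(f"  angles {trial.angles.shape} at {trial.angle_rate:g} Hz, "
      f"GRF {trial.grf.shape} at {trial.grf_rate:g} Hz")
print(f"  peak vertical GRF: {peak_bw:.2f} BW "
      "(grows with speed, swing is force-free)")
print(f"  knee flexion range: {trial.angle('knee_flexion').min():.1f} to "
      f"{trial.angle('knee_flexion').max():.1f} deg")
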