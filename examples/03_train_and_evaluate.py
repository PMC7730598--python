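"""Train the SVR surrogate bank and compare the two validation schemes.

LeaveTrialsOut lets a subject's stances appear on both sides of the split;
LeaveSubjectsOut holds out whole subjects.  The gap between the two is the
cost of predicting loads for a person the model has never seen.
"""

import kneeload as kl
from kneeload.evaluation import run_experiment
from kneeload.preprocess import build_tensor
from kneeload.regression import SVRConfig

cfg = kl.CohortConfig(n_subjects=6, speed_grid=(3, 4), master_seed=5)
trials = kl.synthesize_cohort_trials(kl.make_cohort(cfg), cfg)
tensor, report = build_tensor(trials)
print(f"{tensor.n_trials} stance slices, {len(tensor.feature_names)} input "
      f"features, {len(tensor.target_names)} targets "
      f"(dropped: {report['outputs_dropped']})\n")

svr_cfg = SVRConfig(max_train_rows=3000)
for scheme in ("LeaveTrialsOut", "LeaveSubjectsOut"):
    result = run_experiment(tensor, "svr", scheme, svr_cfg=svr_cfg, seed=0)
    mean = result.fold_mean()
    print(f"{scheme} (fold-averaged):")
    print(mean.round(3).to_string(), "\n")
print("R drops and NRMSE rises when whole subjects are held out: subject-"
      "specific gait style is the hard part of the mapping.")
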