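# Methods

`kneeload` is an end-to-end study of surrogate regression for knee joint
loading during treadmill walking: it generates a synthetic gait cohort,
computes medial and lateral tibiofemoral contact forces (KCFs) with a planar
musculoskeletal model, conditions the data into regression samples, trains
two surrogate families (a multi-output neural network and a bank of support
vector regressions), assesses them under two cross-validation schemes, and
measures their sensitivity to heavy-tailed outliers in the training data.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic cohort can and cannot tell you about real
motion-capture data.

## The synthetic cohort

Real multi-speed treadmill datasets with modelled knee loads are not
publicly deposited, so the package ships a generator whose output has the
statistical structure the downstream analysis assumes.

**Protocol.** Subjects walk at 3–7 km/h in 1 km/h steps, ~10 s per speed,
both legs recorded. Each subject has a maximum speed drawn from the
empirical stopping proportions (4, 13, 31, 5)/53 at 4/5/6/7 km/h: only a
small minority reaches 7 km/h, which matters for cohort-level statistics
(see *Peak trends* below). Angles are sampled at 100 Hz, ground reaction
forces (GRFs) at 1000 Hz.

**Waveforms.** Each of the 13 angle channels (lumbar, pelvis, hip, knee,
patella, ankle, subtalar) is a Fourier series of at most 6 harmonics of the
gait-cycle frequency. Cadence is 70 + 10·speed steps/min times a
subject factor; the stance fraction falls from ~0.68 at 3 km/h toward the
0.55 floor at the fastest speeds. Subject identity enters through
per-channel amplitude factors (±10%), offset and phase shifts, and through
cadence/stance/GRF style parameters — constant across a subject's speeds and
sides, which is exactly the structure that makes `LeaveSubjectsOut`
prediction harder than `LeaveTrialsOut`.

**Forces.** Vertical GRF has the classic double-hump stance profile
(sin πu + q·sin 3πu + asym·sin 2πu in stance progression u), with peak
1.02 + 0.09·(speed−3) body weights (BW), clipped to [1.01, 1.45]. The
anteroposterior channel is a braking/propulsion wave (~0.18 BW), the
mediolateral channel ~8% of BW tracking the vertical humps so the knee
adduction moment peaks with the compressive load. Swing is exactly
force-free; Gaussian measurement noise (defaults 0.5° and 5 N) applies to
angles everywhere and to forces only while the plate is loaded, so the
swing-phase zeros and the non-negativity of the vertical channel are
preserved. Left legs are generated with the mediolateral sign flipped
(left-handed convention), so the downstream mirroring step does real work.

**What it does not emulate.** Marker trajectories and soft-tissue artifact,
impact transients (everything is band-limited by construction), stride-to-
stride autocorrelation beyond the deterministic waveform-plus-noise
structure, asymmetries between legs, or fatigue/drift within a recording.
Consequently, a surrogate that excels here has been shown to learn a
smooth, deterministic kinematics→load map in the presence of realistic
inter-subject variation — not to survive the full messiness of raw mocap.

## Ground-truth contact forces: the planar model

The reference chain is inverse dynamics → static optimization → joint
reaction → frontal-plane contact split, implemented as a planar (sagittal)
reduction with three lumped knee-spanning muscle groups.

**Segments and geometry.** Foot and shank use Dempster-style fractions
(shank: 24.6% of height, 4.65% of mass, COM at 43.3% from the knee; foot:
15.2% of height, 1.45% of mass). Global segment angles follow the sagittal
chain: thigh = pelvis tilt + hip flexion, shank = thigh − knee flexion,
foot = shank + ankle flexion. The centre of pressure sits at a fixed
fraction (default 0.25) of foot length ahead of the ankle; the knee centre
is treated as inertially fixed (steady treadmill progression), and segment
accelerations are finite differences of the knee-relative kinematics. A
quasi-static flag drops the acceleration terms.

**Net moments.** The sagittal knee moment τ (extension-positive) balances
GRF, gravity and inertial terms about the knee. The frontal moment
(adduction-positive) is the mediolateral GRF times the knee-to-COP height,
plus an optional varus/valgus alignment bias (default 0°).

**Static optimization.** Muscle redundancy is resolved per time point by
the convex program

    min  Σ aᵢ² + w (τ_res/τ₀)²
    s.t. Σ rᵢ f_max,ᵢ aᵢ + τ_res = τ,   0 ≤ aᵢ ≤ 1,

with reserve weight w = 1000 and τ₀ = 1 N·m — the reserve actuator absorbs
any moment the muscles cannot produce, at a steep quadratic price. The
default muscle set is quadriceps (6000 N, +4.5 cm), hamstrings (3500 N,
−3.5 cm) and gastrocnemius (2500 N, −2.2 cm), with compressive fractions
0.92–0.97 (cosine of the line of action to the tibial axis). The per-point
solver is bounded linear least squares; the whole-trial path uses the
program's KKT structure (aᵢ = clip(qᵢλ, 0, 1) with λ solving a scalar
monotone equation) solved by vectorized bisection, and the two are
property-tested against each other. Tests also check the solver against a
hierarchical exhaustive grid search that profiles out the stiffest
activation in closed form — a naive box grid cannot resolve the narrow
valley the reserve penalty creates.

**Joint reaction and contact split.** The total knee force is the
intersegmental force plus muscle contributions (compression along the
tibial axis; residual shear anteroposterior, extensor pull anterior). The
compressive load F_y is shared by two frontal-plane contact points a
distance d apart: F_med + F_lat = F_y and (d/2)(F_med − F_lat) = M_frontal,
with negative solutions clamped to zero (unilateral contact; contact also
transmits no tension, so F_y is floored at zero). Shear is assigned to the
medial compartment with lateral x ≡ 0 — the planar model cannot apportion
non-frontal loads between compartments, and this choice reproduces the
dataset property that the lateral anteroposterior channel has no variance
and is dropped by the feature filter. The mediolateral component follows
the compressive shares.

**Contact spacing.** d defaults to 45 mm. A millimetre-scale spacing would
require couple forces an order of magnitude above the total compressive
load to balance a physiological adduction moment (~15–20 N·m), unloading
the lateral compartment for all of stance and flattening the lateral
channels to zero variance — inconsistent with healthy-gait lateral peaks of
~0.7–1.8 BW reported across the modelling literature. 45 mm yields a
medial share of roughly 60–70% at the load peaks.

With these defaults the cohort-mean medial first peak runs from ~2.4 BW at
3 km/h to ~3.3+ BW at 6–7 km/h with lateral peaks roughly half that —
consistent with healthy-knee modelling studies.

**Peak trends.** The first medial peak grows with speed in expectation.
Because so few subjects reach the top speeds, a single cohort's 7 km/h mean
is effectively a one-subject draw, and subject style legitimately spans
more than one speed increment; the monotonicity checks therefore pool
stance cycles over several independent cohorts.

## Preprocessing

Zero-phase 4th-order Butterworth low-pass at 6 Hz for angles and GRFs; GRFs
are then decimated 1000→100 Hz onto the angle grid. Forces are normalized
to body weight (mass × 9.81 m/s²). Left-leg mediolateral channels (GRF z,
KCF med_z/lat_z) are negated to match the right-leg convention; processed
trials carry `mirrored`/processed flags so the chain refuses to run twice.
Stance phases are threshold crossings of the filtered vertical GRF at
0.05 BW with 20 ms hysteresis on both states; intervals clipped by the
record edges are discarded. Each stance becomes one "trial" slice of the
ragged tensors X (16 inputs with GRFs, 13 without) and Y; features with
pooled standard deviation below 1e-6 are dropped (a dataset-level decision;
in practice exactly the lateral anteroposterior KCF). Slices are unfolded
row-per-time-point — cycles are deliberately *not* time-normalized for
regression, since an online predictor cannot wait for the cycle to finish.

## Surrogates

**Neural network.** One multi-output feed-forward network (5 outputs): two
hidden ReLU layers of 400 units, linear output, Adam (lr 1e-3, β 0.9/0.999),
MSE loss, minibatches of 256. 10% of the training rows form a validation
split; training stops when validation MSE has not improved for 10
consecutive epochs (or at `max_epochs`), and the best-validation weights
are restored. The epoch loop is explicit (scikit-learn `MLPRegressor` via
`partial_fit`), which makes the stopping rule exact and testable. Training
is deterministic given the config seed.

**SVR bank.** Five independent ε-insensitive support vector regressions
(one per target), Gaussian kernel with fixed scale s = 0.6 on standardized
inputs — K(u,v) = exp(−‖u−v‖²/(2s²)) by default; the ‖u−v‖²/s² convention
is selectable since "kernel scale" is not a universal definition. ε = 0.01
BW and C = 1 are fixed; hyperparameter search is deliberately avoided.
Kernel fitting is quadratic in rows, so training rows are capped (default
20 000) by even thinning within each stance slice.

Inputs are standardized inside both surrogates (a fixed kernel scale is
meaningless on mixed degree/BW units); targets stay in BW.

## Assessment

Three-fold cross-validation in two schemes: `LeaveTrialsOut` partitions
stance slices at random (a subject can appear on both sides) and
`LeaveSubjectsOut` partitions subjects (subject-disjointness is asserted at
run time, every fold). Metrics per target, pooled over all held-out time
points of a fold, then averaged over folds: RMSE (BW), NRMSE = RMSE/Δy ×
100% with Δy the target's dataset range (the original cohort's printed
ranges ship as a named preset), and Pearson's R. On synthetic cohorts the
schemes separate exactly as expected — e.g. SVR med_y R ≈ 0.98 under
`LeaveTrialsOut` versus ≈ 0.85 under `LeaveSubjectsOut` on an 8-subject
three-speed cohort — because subject style is the dominant unshared factor.

## Outlier robustness

Training rows are replaced, at proportions 5–30%, by draws from a zero-mean
Student-t with 2 degrees of freedom scaled by the per-variable standard
deviation of the original (uncontaminated) training fold; both inputs and
outputs of a selected row are replaced by default (the alternative modes
are configurable). Held-out folds are never touched, which the tests verify
byte-for-byte. The degradation study uses the network: its squared-error
loss is genuinely outlier-sensitive and its fold-averaged med_y R falls
roughly linearly with the contamination level (slope ≈ −0.2 per unit
proportion at the study sizes). A finding worth recording: the SVR bank is
nearly immune to this contamination — its ε-insensitive loss bounds each
sample's influence, and the inflated standardization scale from heavy-tailed
rows effectively widens the kernel, so its test R can even rise slightly —
so an SVR-based replication of the degradation curve would be uninformative.

## Problem sizes

Unit and property tests run on 4–8 subject cohorts at 2–4 speeds. The
learnability study uses a 20-subject noiseless right-leg cohort at 3–4 km/h
(~25 000 samples, ~325 stances); the scheme-ordering and contamination
studies use 6-subject cohorts over 3 seeds each (the contamination grid is
7 levels × 3 folds × 3 seeds of network retraining, with the network capped
at 30 epochs there). These sizes are the package's reference configurations
for its own checks; all are plain config values and scale up freely.

## Known limitations

- The planar reduction has no frontal-plane muscle moment arms, so the full
  external adduction moment is balanced by the contact couple; real models
  share it with muscles and ligaments. Absolute medial/lateral splits are
  therefore sensitive to the contact spacing d.
- Non-frontal load sharing between compartments is under-determined in this
  model class; the medial-shear assignment is one admissible convention.
- The reported accuracy figures describe the synthetic cohort only; they
  demonstrate that the pipeline's statistical machinery behaves correctly,
  not that the specific R/NRMSE levels transfer to any real dataset.
- Time normalization (quadratic interpolation to 100 stance points) is used
  for summaries and ensemble curves only, never for regression samples.
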