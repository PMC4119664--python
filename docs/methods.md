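# Methods

This note documents the models, conventions and numerical choices of
the `claudigait` pipeline, in the order the data flow.

## Angle conventions (kinematics)

Only marker positions are observed, so the four "joint angles" are
projections in the sagittal plane, defined once and used consistently:

* `q1` (upper body) and `q2` (femur): orientation of the
  acromion→ASIS and ASIS→fibular-head segments relative to the downward
  vertical, offset by π so a vertical segment reads π and forward
  inclination reads > π. Segment-vs-vertical (rather than
  segment-vs-segment) is an explicit package choice; nothing downstream
  depends on which of the two readings is used beyond a constant.
* `q3` (knee): interior angle at the fibular head between thigh and
  shank. Full extension reads π (180°), flexion reduces it. This
  makes "knee extended as much as possible" literally `q3 → π`.
* `q4` (ankle): interior angle at the lateral malleolus between the
  shank (pointing up) and the foot segment. Shank vertical + foot
  horizontal reads π/2; plantarflexion (toes down) increases `q4`,
  dorsiflexion decreases it. Under this convention a plantarflexed
  gait has a *large* mean ankle angle and a *short* gastrocnemius,
  which is the combination the PAD group exhibits.

All angles are radians in (0, 2π); degrees appear only in prose. The
angles are invariant to translation and uniform scaling of the marker
coordinates; mirroring x reflects each angle about its neutral value.

## Stance detection and the mean cycle

The start of stance is operationalized as the forward (x) extreme of
the fifth-metatarsal marker: a frame whose value is ≥ both neighbours
and above the series mean, plateau ties resolving to the earlier frame.
Because the forward extreme is a rounded plateau, frame-level noise can
split it into several nearby local maxima; candidates whose topographic
prominence is below 0.15 × the series range are therefore discarded
(noise bumps carry prominence of the noise scale, true per-cycle
extremes carry most of the stride's excursion). This guard is part of
the package's detection rule and is exercised by the tests at the
documented noise level.

Cycles run stance start → next stance start. Each is resampled to
L = 100 frames by linear interpolation and averaged pointwise; the mean
cycle is treated as periodic, so windows that precede the stance start
wrap around the cycle end. The mean original cycle length is kept so
that windows defined in raw frames can be rescaled (below).

## Reference skeleton and muscle lengths

Muscle lengths are not comparable across bodies, so angles are applied
to one fixed skeleton (femur 430 mm, shank 410 mm, foot 200 mm, trunk
500 mm) and origin-to-insertion distances are measured there. The
attachment geometry is an explicit order-of-magnitude anatomical
choice — gastrocnemius origin 30 mm proximal / 25 mm posterior of the
knee on the femur, insertion 50 mm posterior of the ankle (calcaneus);
quadriceps origin on the anterior pelvis near the hip (20 mm distal /
30 mm anterior along the trunk axis), insertion on the tibial
tuberosity (40 mm distal / 25 mm anterior of the knee) — because only
the *ordinal* angle–length behaviour reaches the classifier. Both
monotonicities are pinned by tests: plantarflexion shortens the
gastrocnemius; knee flexion lengthens the quadriceps.

The gastrocnemius path is a straight line. The quadriceps path wraps a
circular patellar surface (radius 25 mm) at the knee, and the wrap is
**one-sided**: the path must pass anterior to the knee, with the wrap
angle measured as the counter-clockwise sweep from insertion to origin.
A two-sided "shortest path avoiding the disk" would cut posterior to
the knee at deep flexion — anatomically impossible and non-monotone —
so the one-sided form is used. Radius 0 degenerates to the plain
distance. Lengths are reported in reference millimetres.

The input lists are exactly: gastrocnemius(knee, ankle) and
quadriceps(upper body, femur, knee). Fixing the quadriceps origin in
the pelvis (not the femur) is what makes the trunk–femur relative angle
enter the second list; a femur-fixed origin would silently drop it.

## The nine features

Per mean cycle: mean of `q4`; mean of `q3` over the window ending at
the stance start; peak-to-peak range of `q2` ("amplitude" read as
max − min — "amplitude" admits several readings and the peak-to-peak
range is the one this package fixes); and per-muscle maximum ("maximally
relaxed"), minimum ("maximally contracted") and range of motion, so
`rom = relaxed − contracted` holds exactly.

The knee window is defined as 4 raw frames before the stance start plus
the stance frame. On the resampled mean cycle the window is rescaled
by L / (mean original cycle length), rounded to the nearest frame
(minimum 1): at 30-frame cycles resampled to L = 100 the window spans
13 resampled frames, the same fraction of the cycle as 4 raw frames.

## Classifier bank

* Per-class one-vs-rest binary RBF-SVMs on the per-class feature
  subsets (5/4/4/6 features; PAD and L5 share the same four). Each
  classifier carries its own z-score normalization (population SD,
  ddof 0; constant features map to 0) fitted on training data only,
  and its own `(C, γ)` from an exhaustive grid search over
  `C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `γ ∈ {2⁻¹⁵, …, 2³}`, scored by stratified
  internal cross-validation (5 folds; 3 when the smallest class has
  < 5 training members; leave-one-out when < 3; splits whose training
  half holds a single class are skipped). Grid ties break to the
  smallest C, then the smallest γ. The multiclass decision is the
  argmax of raw decision values (no Platt scaling), ties resolving to
  the fixed class order normal, PAD, L5, L4.
* Baselines consume the full nine-feature z-scored vector: LDA and a
  seeded decision tree with library defaults; one-vs-one SVM
  (6 pairwise classifiers, majority vote, vote ties by summed decision
  values then class order); plain one-vs-rest SVM. The two SVM
  baselines share a single `(C, γ)` grid-searched on the accuracy of
  the whole multiclass scheme — per-pair tuning is a conceivable
  alternative, the shared form is the package's choice.
* Binary solving is delegated to libsvm through scikit-learn. Grid
  search scoring calls scikit-learn's low-level libsvm binding
  directly; a test asserts its decision values equal
  `SVC.decision_function` exactly, and every final model is a public
  `SVC` fit.

Leave-one-out evaluation refits everything — normalization, grid
search, training — on each 45-subject remainder, so no statistic of the
held-out subject can leak into its own fold (asserted by a perturbation
test).

## Synthetic cohort generator

The generator emulates the *feature-level* structure of the four
groups, not gait dynamics: waveforms are sums of ≤ 3 sinusoidal
harmonics per angle over a 30-frame cycle (30 frames/s, 10 cycles per
subject), with class signatures expressed as deviations from a neutral
gait: an additive ankle offset (PAD +0.12 rad, L5 −0.12 rad), a knee
angle held over the pre-stance window (L4: 3.10 rad ≈ 177.6°, within
5° of full extension; others ≈ 2.85 rad), a femur-amplitude scale
(normal largest), a leg-lift scale multiplying swing-phase knee flexion
and ankle excursion (normal largest, L5 smallest), and a
knee-extension bias that shortens the most-contracted quadriceps length
(L4). `effect_scale` interpolates all signatures toward neutral, so 0
yields four statistically identical classes. Between-subject
variability jitters each subject's waveform parameters
(σ = 0.03 rad on offsets, 3% on scales); frame noise is additive
Gaussian in angle space, σ = 0.02 rad by default, inside the quoted
0.007–0.04 rad measurement-accuracy band (angle-space noise is the
simpler and directly comparable choice; marker-space noise would mix
through the arctangents). Signature magnitudes are free parameters of
the generator — the source study reports directions of group
differences, not effect sizes — chosen once so that every documented
ordering holds for every subject at zero noise.

Treadmill walking is assumed: the ASIS marker is fixed and all markers
oscillate about fixed mean positions. Forward kinematics inverts the
angle conventions exactly, so marker round-trips recover angles to
machine precision.

What passing tests show, and what they do not: the pipeline recovers
class labels when the class contrasts are present at realistic noise,
and degrades to chance when they are absent. They do not show that
real patient gait satisfies these contrasts at these magnitudes — the
generator encodes the reported directions, so label-recovery results
are a check of the machinery, not clinical validation.

## Problem sizes and runtimes

Tests use the default 46-subject cohorts for end-to-end checks
(10 seeds for label recovery and 10 for the null), 12-subject cohorts
for equivalence and invariance properties, 100 random series/cycles for
geometry and feature oracles, and 20×20 angle grids for the muscle
model. The acceptance script evaluates one default cohort across all
five methods plus one null cohort.

## Known limitations

* 2-D sagittal projection only; no ground-reaction forces, 3-D
  kinematics or muscle activation dynamics.
* The reference skeleton's numeric geometry is a documented stand-in;
  absolute muscle lengths (mm) are meaningful only relative to this
  skeleton.
* The generator's waveform family is deliberately minimal; inter-joint
  timing, stride-time variability and asymmetry are not modelled.
* Video processing (marker detection) is out of scope; the pipeline
  starts at marker trajectories.
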