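# Methods

## The measurement model

One fly lives alone in a 150 × 150 × 150 mm cage (configurable) with a
food and a water station fixed on the floor. A stereo camera pair images
the cage; the fly appears as a bright blob on a dark background, and each
frame reduces to one 3D point in the cage frame (right-handed, origin at
the front-bottom-left corner, z up, millimetres). Recording is
round-robin over a 9-cage tray: each cage is sampled for a 60 s bout at
5 frames/s and then processed for 60 s before the recorder moves on, so a
given fly is revisited every `cages × (bout + process)` = 1080 s (18 min),
i.e. 2–3 one-minute bouts per clock hour, for the fly's whole life. A
bout is therefore 300 frame records; bouts are serialized as small
tab-separated text logs (one header line, one line per frame with index,
time offset, x/y/z to 0.001 mm, and a one-letter behavior code).

## Behavior classification

Classification is rule-based and deterministic, driven entirely by
inter-frame Euclidean displacements `d` (mm per 0.2 s):

1. `d ≤ δ_rest` → resting; `d ≥ δ_fly` → flying (per transition).
2. Transitions left pending are partitioned into tumbling windows of
   `N` frames aligned to the bout start (a transition belongs to the
   window holding its *later* frame; the final short window is judged on
   its actual span). If the net displacement between the window's first
   and last frame is `≤ δ_walk`, its pending transitions are
   micro-movement (large steps, little net motion — grooming-like),
   otherwise walking.
3. Each maximal run of ≥ `n_feed` consecutive resting frames whose
   positions all lie inside the food circle (radius `r_feed`) becomes
   feeding; likewise the water circle gives drinking. Overlapping
   station circles are a configuration error, so a run can never be both.
4. A fly classified as resting without interruption for ≥ `death_hours`
   (default 5 h) is flagged dead, the onset being the start of the
   terminal resting run. Because no frames exist between bouts, a gap is
   credited to a resting run only when it is bracketed by two all-resting
   bouts whose boundary positions agree within `δ_rest`; contiguous
   recordings (gap ≤ one frame period) only require label continuity.

Transition labels attach to the later frame; frame 0 inherits the first
transition's label. Tie handling is frozen as: resting uses `≤`, flying
`≥`, the window test `≤`.

Default thresholds: `δ_rest` = 1 mm, `δ_walk` = 5 mm, `δ_fly` = 20 mm,
`N` = 5 frames (1 s), `n_feed` = 25 frames (5 s), `r_feed` = `r_drink` =
10 mm, `death_hours` = 5. All are configuration-exposed; apart from the
5-hour death rule they are package defaults chosen to separate the
simulator's displacement kernels cleanly, not measured constants, and
should be re-tuned for real rigs.

## The synthetic-data generator

There is no public recording of this kind, so the package ships a
first-class generator that plays the role of ground truth. A fly is a
semi-Markov process over the six behaviors on a fixed 0.2 s step grid:

- **Resting** dominates. The exit rate is `λ(t) = w[hour] · a(day) /
  rest_mean_s`, sampled exactly as an inhomogeneous exponential over the
  piecewise-constant hourly profile.
- **Hourly weights** `w` encode the diurnal rhythm: lights-on hours
  (07:00–19:00) carry the overwhelming majority of the weight, the late
  afternoon (15:00–19:00) about half, with the single peak at 18:00 and
  night hours sharing a small remainder. The nominal weights are set
  slightly sharper than the intended realized distance shares (~90%
  lights-on, ~50% late afternoon) because busy hours saturate: time spent
  moving is unavailable for further rest exits, which deflates the
  realized share of the busiest hours by several percent relative to the
  nominal weights.
- **Age multiplier** `a(day)` rises as a gamma-like pulse to 1.0 at day
  18 (inside the 15–20 day window the apparatus is meant to resolve) and
  declines exponentially afterwards (τ = 12 d) above a floor of 0.25 —
  senescent decline is faster than the juvenile rise.
- **Activity episodes** on leaving rest are micro-movement, walking or
  flying (default mix 0.55/0.35/0.10) with exponential dwells (means 12,
  10 and 2 s). Displacement kernels are scaled to be separable by the
  classifier thresholds: resting is anchored (optional sub-δ_rest jitter,
  default 0), micro-movement oscillates across an anchor with ~1.2–1.6 mm
  amplitude (steps ≈ 3 mm, window net ≤ ~3 mm), walking takes persistent
  5.2–8 mm steps with a slowly wandering heading and billiard-wall
  reflection, and flying is modeled as darting repositioning jumps of
  60–130 mm anywhere in the cage (rejection-sampled), so every flying
  step exceeds δ_fly and no wall interaction can shrink one below it.
- **Station visits** (p = 0.02 each per rest exit) are teleport-free: the
  fly walks a straight approach to the station, dwells nearly motionless
  inside the circle (60 s / 40 s means), then walks off so the next rest
  does not sit inside the circle.
- **Death** occurs at a per-fly lifespan drawn N(60, 15) days (clipped
  ≥ 5; configurable or fixed); the position is frozen afterwards and no
  bouts are recorded after the death day.

Internally a lifetime is an *episode table*: dense per-step positions are
stored only for moving episodes, stationary episodes keep an anchor plus
a counter-hashed jitter stream, and episode boundaries are integer step
indices so sample times attribute to episodes exactly (float comparisons
at boundaries caused off-by-one-frame label errors). A 40-day lifetime
costs a few tens of MB at most and reconstructs any part of the
full-resolution path deterministically. A state change takes effect with
the first step into it: the instant shared by two episodes carries the
earlier label, which matches how the classifier attributes transition
labels to the later frame.

What the generator does **not** emulate: measurement noise and missed
detections, flight aerodynamics (flying is positional darting, not
ballistic), wall-walking geometry, social behavior, diet effects, and any
inter-individual variance structure beyond independent seeds and random
lifespans. Tests passing on this cohort therefore validate the
*pipeline*, not biological claims about real flies.

### Calibration targets of the default cohort

The packaged default cohort (8 flies, 40 days) is the generator's
reference condition: the diurnal profile, age pulse and episode kinetics
above were chosen once so that the full pipeline recovers a lights-on
distance share near 90%, a 15:00–19:00 share near 50%, a circadian peak
at 18:00 and a peak activity day inside 15–20 — the operating regime the
monitoring approach is designed to resolve. The acceptance script and
`tests/test_acceptance.py` recompute these from scratch.

## Analysis conventions

- **Hourly scaling.** Only 2–3 one-minute bouts exist per hour, so a day
  × hour cell is `sum over bouts × 3600 / seconds recorded`, a full-hour
  estimate. Hours with no recording are NaN and excluded from averages
  and normalizations. A bout belongs to the clock hour it starts in.
- **Daily totals** are the mean over a day's recorded hours × 24; age
  profiles average daily totals over the flies alive that day, so dead
  flies drop out rather than dragging the mean down.
- **Peak-day estimation** uses a 3-day centered rolling mean before the
  argmax: daily totals estimated from ~8 observed activity episodes per
  fly-day are noisy, and the raw argmax latches onto single-day
  excursions (the estimate still carries a ±2–3 day sampling error on an
  8-fly cohort).
- **"Normalized"** profiles are peak-normalized (max = 1) by default with
  a share mode (sum = 1) as the alternative.
- **Survival** is Kaplan–Meier; flies alive at study end enter censored.
- **Age groups** are 10-day intervals `(10k, 10(k+1)]` in days of life;
  a group profile is the mean over contributing flies of each fly's own
  6-behavior frame-share vector.
- **Optimal matching** uses the classical constant-cost scheme (sub 2,
  indel 1) by dynamic programming; with `sub ≥ 2·indel` it collapses to
  the LCS form `indel · (|a| + |b| − 2·LCS)`, which the tests exploit as
  a closed-form oracle. Representative sequences for OM comparison of
  age groups are the per-clock-hour modal labels (24 symbols per group).
- **Linkage** defaults to average; ward and complete are exposed. Ties
  follow the deterministic lowest-index convention of the underlying
  agglomeration. The automatic cluster count maximizes the relative gap
  `(h[n−k+1] − h[n−k]) / h[n−k]` over 2 ≤ k ≤ n−1.
- **Branch support** is bootstrap monophyly: resample flies with
  replacement, rebuild profiles and tree, count how often each original
  clade reappears. Replicates that lose an age group entirely are
  skipped. (This is a support measure, not a significance test.)

## Numerical and degenerate-input choices

- All times live on the 0.2 s step grid; bout sampling at 5 Hz is
  therefore lossless and exact.
- Serialized positions are rounded to 0.001 mm and times to 0.1 s; the
  log format round-trips bit-exactly at that precision.
- A cage with an all-zero activity profile is legal and produces a fly
  that rests forever; an empty schedule horizon yields an empty schedule,
  not an error.
- Bouts with fewer than 2 frames cannot be classified; empty cohorts,
  empty ethogram lists and out-of-range tree cuts raise validation
  errors naming the problem.
- Blob detection thresholds default to an Otsu split; a uniform image
  returns "no detection" rather than an arbitrary centroid.

## Problem sizes

The test suite and acceptance script run, by choice: 50 validation bouts
(15 000 frames) for classifier recall; an 8-fly × 40-day cohort
(~25 000 bouts) for circadian recovery; a 16-fly × 60-day three-phase
cohort for cluster recovery; 500 random bouts for oracle equivalence; and
all label-sequence pairs of length ≤ 4 for the OM oracle.

## Known limitations

- The classifier mislabels single frames at genuine kinematic boundaries
  (e.g. the frame where a walking step lands exactly as a rest begins)
  and inside windows mixing two pending behaviors; on threshold-separated
  data this costs well under 1% per behavior.
- Feeding/drinking are proximity-plus-stillness calls; a fly resting
  inside the food circle long enough *is* feeding by rule. This is a
  known weakness of station-proximity criteria.
- Death detection cannot see inside inter-bout gaps; the positional
  agreement requirement makes it conservative when a fly dies just after
  a partially active bout.
- The stereo module is an idealized rectified rig: no lens distortion,
  no calibration error, single blob, no identity maintenance.
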