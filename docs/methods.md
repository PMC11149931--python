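# Methods

This note documents the models and procedures implemented in
`swimscore`, the tunable parameters and their defaults, what the
synthetic trajectory generator does and does not emulate, and the design
choices made where the underlying assay description left the design
open.

## Coordinate frame and windows

Tracker output is a per-fish CSV of X/Y coordinates at 30 samples/s over
a 1-hr edited timeline (the 5-min injection pause removed, so
"minute 30" means injection time on the edited clock), in both pixels
and cm. Pixel coordinates are affinely recoded per axis so the box
center maps to 0, the odor-side short wall to Xc = +1 and the water-side
wall to −1; the long walls map to Yc = ±0.74, the box width/length ratio
(8.5/11.5), so one normalized unit means the same physical distance on
both axes. When the odor is injected on the left pixel side the X map is
mirrored, keeping the odor side at +1 — downstream code never needs to
know the physical side. Pixel extents of the arena come from configured
corner coordinates; as a fallback they are calibrated from the track's
own min/max, which is logged because a fish that never visits a wall
shrinks the frame.

Coordinates landing beyond the walls (tracking jitter) are clipped to
the wall and counted. Rationale: threshold-crossing counts downstream
must not be inflated by jitter outside the arena. The clip tolerance
(`clip_tol`, default 0.05 normalized units) only controls when a louder
warning is emitted.

Analysis windows are minutes 10–25 ("before") and 37–52 ("after"),
half-open in time. All parameter means are taken over the full window.

## Kinematic parameters

- **Mean X position**: arithmetic mean of Xc over every 30 Hz sample.
- **Mean speed**: Euclidean displacement between 5-s anchors in cm,
  divided by the step. Anchors are non-overlapping and start at the
  window start; a partial final step is discarded. Non-overlap is the
  natural reading of speed "between two time points"; it also makes the
  estimate an average of independent chords. Note this measures chord
  displacement: strongly curved or localized motion (tight circling, a
  fish stationed at the odor tube) legitimately reads slower than its
  path speed. That is a property of the metric, shared by any analysis
  built on it.
- **Round trips**: crossings of ±0.5 × (axis half-extent) counted over
  sample pairs strictly straddling the level, total divided by two. A
  sample exactly on the threshold does not create a crossing. No
  hysteresis or debounce is applied; tests quantify jitter sensitivity
  through the simulator instead. The Y thresholds default to ±0.37
  (0.5 × 0.74) so that X and Y trips are comparable excursion fractions;
  a `--literal-y-threshold` switch places them at the literal ±0.5
  (68% of the Y half-extent) for compatibility with the alternative
  reading of the counting rule.

## Swim patterns

The taxonomy is R (random swim), WF (wall following), C (circling), and
TX/TY (thigmotaxis: back-and-forth shuttling along a long-axis or
short-axis wall). A fish's pattern set for a window is the *union* of
elementary modes it expressed (fish commonly combine modes).

In the original workflow patterns were called by eye from track plots.
Here a rule-based classifier reproduces the call, and manual annotation
files can override it anywhere a pattern set is consumed (annotation
provenance takes priority in the pipeline). The classifier smooths
positions over 1 s, decimates to 1 Hz, cuts the window into overlapping
60-s segments (30-s stride), labels each segment, and returns the set of
labels present in > 20% of segments (falling back to {R}):

- **WF**: wall-band occupancy > 0.8 and net winding about the box
  center > 1.5 turns/min. The wall band is within 15% of each axis
  half-extent of a wall; winding uses the square-normalized coordinates
  so corners sweep angle at a comparable rate.
- **TX/TY**: single-wall band occupancy > 0.8, ≥ 2 debounced direction
  reversals/min along that wall (increments under 2% of the axis extent
  are ignored), and winding < 0.5 turns/min. A fish on a long wall
  shuttles along X (TX); on a short wall, along Y (TY).
- **C**: off-wall occupancy > 0.5 and net signed heading rotation
  > 2 turns/min with a consistent sign (net exceeding half the total
  absolute rotation). The sign-consistency requirement separates orbiting
  from random heading diffusion, whose absolute rotation is large but
  whose net rotation is not.
- **R**: anything else.

All thresholds live in `ClassifierParams` and are deliberately exposed:
they are this package's operationalization of a visual judgment, not
measured constants. On simulated pure-mode tracks with default noise the
classifier recovers the generating mode essentially always (tests assert
≥ 90% over 30 seeds per mode; observed 100%).

## Indexes, score, responder call

Each kinematic parameter uses the bounded contrast
(after − before)/(after + before), defined as 0 when both windows are 0
(a zero-activity fish shows no evidence of change). Position means live
on a signed scale where the raw ratio is unbounded near 0, so both means
are shifted by +1 onto [0, 2] before indexing; the shifted index is
positive iff the fish moved toward the odor side and saturates at ±1 for
a full wall-to-wall shift. An alternative half-difference contrast,
(after − before)/2, is available via `position_mode="half_difference"`.
Round trips are indexed on the combined X+Y count. The pattern-change
index is |after ∖ before| / |after|.

The individual olfactory score is the sum of the absolute values of the
three kinematic indexes plus the (already non-negative) pattern index,
range 0–4. The responder threshold is strict: score > 1.5. Responder
pooling for personality analyses keeps conditions whose responder
fraction strictly exceeds 0.4; an empty pool warns rather than raises.

## Cohort statistics

- **Paired before/after contrasts** use the Wilcoxon signed-rank test
  (the standard paired rank test; the assay literature's "paired
  Mann-Whitney" is read as exactly this, which is worth stating
  prominently since the two names are often conflated). Zero differences
  are dropped and counted; the exact null distribution is used for
  n ≤ 25 without ties, the tie-corrected normal approximation otherwise.
- **Between-group contrasts** use Mann–Whitney U, Bonferroni-multiplied
  and capped at 1.
- **Pattern composition** uses Fisher's exact test: exact hypergeometric
  two-sided p on 2×2 tables (probability-≤-observed rule by default; the
  tail-doubling rule is available via `two_sided_rule="doubling"`), and
  a seeded Monte-Carlo estimate over fixed-margin tables for larger
  ones, reported with its binomial standard error. The Monte-Carlo route
  is cross-checked in tests against an independent exact oracle.
- **Correspondence analysis** of a contingency table: SVD of the
  standardized residuals D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; principal
  coordinates are mass-rescaled singular vectors × singular values;
  total inertia equals χ²/n to 1e-9 and decomposes over
  min(rows, cols) − 1 dimensions. Confidence-ellipse rendering is out of
  scope; only coordinates and inertia are computed.
- **PVE** (percentage of score variation explained by a baseline
  personality predictor) is defined here as η² — the between-group share
  of the total sum of squares — for categorical predictors (pattern
  category) and the squared Pearson correlation for continuous ones
  (baseline speed), with a seeded permutation p-value (default 10⁴
  reps). This definition is the package's own choice; η²/R² is the
  natural "percentage of variation" statistic and the permutation test
  avoids distributional assumptions at small n.
- **Spearman correlations** report rho on average ranks with a two-sided
  Student-t p-value on n − 2 degrees of freedom (p = 0 at rho = ±1).

Standard test statistics and distributions are computed through
scipy.stats; the Monte-Carlo Fisher sampler, the PVE permutation test
and the correspondence analysis are implemented here.

## The trajectory simulator

The simulator generates what the analysis assumes and nothing more: 30
Hz positions in the 11.5 × 8.5 cm box over 60 min, driven by a per-second
mode program (a fixed sequence or a Markov chain with exponential
dwells), with a per-fish personality consisting of a baseline mode and
an individual swim speed, both fixed across simulated days.

Per-mode updates:

- **R** — persistent random walk: heading diffuses with Brownian
  increments (1.5 rad/√s), constant within-run speed; reflecting walls
  are implemented exactly by folding the free path into the box.
- **WF** — perimeter following at a 0.5 cm wall offset with a constant
  per-fish circulation direction and small arc-length noise.
- **C** — noisy circular orbit (radius 2 cm) away from the walls.
- **TX/TY** — sinusoidal shuttling along one wall (amplitude 80% of the
  usable half-span, period 12 s).

All positions receive 0.05 cm Gaussian tracking jitter and are clipped
to the box. Tracks are deterministic given the spec seed.

The odor response, applied from injection onset plus a 30-s latency,
has four independent knobs: an Ornstein–Uhlenbeck pull of X toward an
odor-side home position (a literal additive drift under reflecting walls
folds into oscillation and produces no net shift, whereas the OU pull
has the drift–equilibrium the assay expects — the fish ends up stationed
near the delivery point with spread set by its step size and the pull
rate); a speed multiplier; an excursion-restriction multiplier scaling R
steps in X, thigmotaxis amplitude and orbit radius (the
"reduced back-and-forth crossings" phenotype); and an optional
post-stimulus mode program (the "pattern switch" phenotype). The
attraction-pulled orbit centers on the odor delivery point, which sits
at mid-height of the odor-side short wall.

Presets encode the study conditions: baseline mode probabilities per
morphotype (SF: R 0.75, WF 0.10, TX 0.10, TY 0.05; CF: WF 0.70, R 0.15,
TX 0.10, TY 0.05; F2 between), matching the reported pattern of
three-quarters random-swimming surface fish and a wall-following
majority of cavefish, with circling treated as a post-stimulus rather
than baseline mode; morph mean speeds SF 1.4, CF 1.6, F2 1.5 cm/s
(cavefish hyperlocomotion; between-fish CV 0.15, draws clipped at ±2.5
SD); and a strong-attraction response preset (pull rate 0.05/s, speed
×1.5, restriction ×0.4, post-stimulus switch to odor-side circling —
responders in this assay characteristically station themselves near the
odor tube). The simulated injection latency is 30 s.

What the generator does *not* emulate: hydrodynamic odor plumes and
concentration-dependent response kinetics, partial or probabilistic
responses, drifting motivation within a session, tracking dropouts and
identity switches, and multi-fish interaction. Passing recovery tests
therefore show that the pipeline correctly measures the phenotypes the
generator encodes — attraction, restriction, speed change, pattern
switch — not that real fish produce them at these rates.

## Numerical choices and degenerate inputs

- Change indexes define 0/0 = 0; negative inputs are a caller error.
- Threshold crossings require a strict sign change; touching a level
  does not count, so counts are stable under exact-threshold samples.
- The Wilcoxon path warns (p = 1) when all differences are zero; PVE
  warns (0) on constant scores; pooling warns (empty) when no condition
  qualifies. None of these raise, since all occur in legitimate null
  data.
- Monte-Carlo p-values use the add-one estimator (hits + 1)/(reps + 1)
  and are bit-reproducible given (seed, reps).
- Simulated mode transitions snap the new mode's path to the nearest
  point of its template (perimeter, orbit phase, oscillation phase), so
  tracks are continuous up to a sub-offset adjustment at switches.

## Problem sizes

Default test and reproduction runs use desk-scale cohorts: 50 seeds per
condition for responder recovery, 50 fish per morph for baseline
majorities, 20 fish × 4 days for personality stability, 30 seeds per
mode for classifier accuracy, and 200–1000 random series for counting
oracles. These sizes give binomial confidence well inside the asserted
bounds while keeping a full run in tens of seconds.

## Known limitations

- The rule-based classifier is tuned to the simulator's clean geometry;
  real tracks with dropouts or reflections at the water surface will
  need threshold adjustment (all thresholds are config).
- The position index saturates at ±1 only for a full wall-to-wall shift
  of the mean; fish already resting at the odor-side wall at baseline
  have little headroom on this component (their response is carried by
  the other three, as intended by the individual-baseline design).
- Monte-Carlo Fisher p-values carry sampling error (reported); the exact
  network algorithm for R×C tables is not implemented.
- `large` vs `small` circles are not distinguished; clockwise vs
  counterclockwise wall following is likewise not separated.
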