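# Methods

This note documents the models, parameters and numerical choices behind
`locogear`, and what its synthetic-data tests do and do not establish.

## Coordinate model and units

Positions are continuous pixel coordinates with the origin at the arena's
top-left corner, x rightward, y downward (frame-grabber convention). The
default arena is 70 × 100 cm digitized at 320 × 435 px, so scaling is
anisotropic (0.21875 cm/px in x, ≈ 0.22989 cm/px in y); all speeds and
distances are computed in cm after per-axis conversion. The tracking file
dialect is a UTF-8 CSV `sample,x_px,y_px` with empty fields for missing
samples; coordinates round-trip bit-exactly.

## Artifact rejection

Four steps, each recording its invalidation count in a provenance log so
that (initially valid) = (finally valid, non-interpolated) + Σ (invalidated
per step) holds exactly:

1. **Spatial outliers** — samples outside the pixel raster are invalidated.
2. **Revisited pixels** — positions are binned to integer pixels (floor); a
   *visit* is a maximal run of consecutive valid samples on one pixel, and
   any pixel with ≥ 2 distinct visits is blacklisted, removing all its
   samples. This eliminates resting-spot jump artifacts (a jump away and
   back splits the resting visit in two, so the resting pixel itself is
   "visited twice" and removed). Counting *distinct visits* rather than raw
   sample occupancy is deliberate: occupancy counting would erase every
   slow traverse. Both modes are available (`revisit_mode`), and the rule
   can be disabled.
3. **Low-pass speed filter** — a forward pass flags any sample whose
   implied instantaneous speed against the last *consistent* sample exceeds
   80 cm/s; flagged samples never become the reference, so 1–3-sample
   teleport spikes are removed without cascading into the true path behind
   them. The reference set is all in-arena samples not themselves flagged,
   *including* samples the revisit rule removed: those were discarded for
   sitting on overused locations, not for untrustworthy coordinates, and
   excluding them would blind the filter to spikes inside removed resting
   stretches (the reference would lie seconds away, making any displacement
   look slow).
4. **Single-gap interpolation** — invalid runs of at most `max_interp_gap`
   samples (default 1) flanked by valid samples are filled by per-axis
   linear interpolation and marked `interpolated`; longer runs stay
   invalid. This is the only way an invalidated sample regains validity.

Each step is idempotent, and the default order (outliers → revisit rule →
low-pass → interpolation) is recorded in the provenance log.

## Speed, episodes and gears

Windowed speed uses a centered symmetric window of half-width
h = round(0.3 s × rate / 2) sample intervals (h = 2 at 12.8 Hz; the full
4-interval window spans ≈ 0.3125 s): speed at sample *i* is the cm
displacement between samples *i*−h and *i*+h divided by 2h/rate. Speed is
undefined wherever any window sample is invalid (for contiguous gaps this
coincides with requiring valid endpoints) and near the recording edges.
Endpoint displacement was chosen over averaging instantaneous speeds for
robustness to single-sample jitter.

Motion episodes are maximal runs of defined speed ≥ 4 cm/s (inclusive
comparison, fixed convention). Runs shorter than one full speed window
(2h + 1 samples) carry no well-defined windowed maximum and are discarded.
Per episode: dwell time (samples/rate), path length (sum of consecutive cm
displacements), maximal windowed speed, and log max-SD = log₁₀(max speed).

Gear assignment is the fixed threshold: gear 2 iff max speed ≥ 10 cm/s
(boundary inclusive, tested). The two-component Gaussian mixture — fitted
by EM in 1-D with 10 random restarts, tolerance 1e-8 on the relative
log-likelihood change, 500 iterations — is characterization-only and never
drives assignment, because mixture fits destabilize when the fast mode
flattens (the field observation that motivated the fixed split). Restarts
whose component standard deviation collapses below 1e-4 are discarded; if
no restart survives, a moment-matched result flagged `converged=False` is
returned rather than raising. Components are reported in ascending mean
order. The log max-SD density display uses a Gaussian KDE with Silverman's
bandwidth (configurable), renormalized to unit trapezoid integral on a grid
over [log₁₀ 4, log₁₀ 80].

## Endpoints

* Incidence of second gear: 100 × n₂ / n; NaN with zero episodes.
* Total distance: Σ path over *all* motion episodes, in meters.
* Mean maximal speed, mean dwell time and mean spatial spread per gear are
  arithmetic means over that gear's episodes; "spatial spread" is the
  within-episode covered path (a net-displacement variant would be a
  different endpoint; the covered-path reading parallels the distance
  endpoint). Missing gears yield NaN.
* Curvature: episodes are partitioned into consecutive non-overlapping
  windows of round(0.5 s × rate) intervals (6 at 12.8 Hz; trailing
  remainder dropped); per window the ratio of summed path to endpoint chord
  is formed, windows with chord < 0.1 cm are skipped (a closed loop has an
  unbounded ratio), and the episode value is the mean of (ratio − 1) × 100.
  Percent excess is reported because a raw ratio is ≥ 1 by construction;
  the raw-ratio output is available behind a flag. Non-overlapping windows
  avoid double-counting; the stride is configurable.
* Activity profile: motion seconds per 10-min bin; global activity phases
  are maximal runs of bins whose 3-bin moving average exceeds 20% of the
  peak bin. The phase criteria are quantitative conveniences for testing;
  the published analysis presented these phases graphically.

## Synthetic recordings

The generator emulates the study's recording conditions: 23 h at 12.8 Hz
(1,059,840 samples) in the 70 × 100 cm arena, alternating rest bouts and
motion episodes.

* **Episode schedule**: an inhomogeneous Poisson process (thinning) with a
  baseline rate (episodes/min) multiplied by a circadian profile over the
  24 h cycle; the default profile has two active phases separated by a
  quiescent phase. A minimum rest gap of one speed window keeps adjacent
  episodes unambiguous.
* **Episode speed**: a raised-cosine bump from a floor of 4.2 cm/s up to a
  per-episode maximum drawn as 10^N(center_g, sd_g) for the episode's gear
  (defaults 0.71/0.05 and 1.24/0.10 log₁₀ cm/s; gear 2 with probability
  0.5). The bump is rescaled so the *windowed* maximum of a straight-line
  realization equals the drawn value, which makes the recovered log max-SD
  distribution match the configured centers without window-smoothing bias.
  Episode durations are lognormal (σ = 0.3) around per-gear means (1.0 s
  and 1.3 s), truncated to [0.7 s, 8 × mean] so episodes stay detectable.
* **Paths**: correlated random walk; per-sample heading increments are
  N(0, σθ) with σθ = (1 − persistence) π. The default persistence 0.94 was
  set by forward simulation so the pre-lesion curvature endpoint lands near
  the published few-percent scale. Walls reflect the path (billiard
  folding), which keeps positions in-arena without distorting speeds.
* **Rest**: the animal rests where its episode ends, with sub-pixel jitter
  (±0.3 px around the pixel center) so rest never crosses the noise
  threshold and occupies a single pixel per bout. `rest_spots` (the four
  corners by default) give the initial position and the corner-jump
  artifact targets. Resting in place, rather than walking back to a corner
  after every episode, is deliberate: repeated return corridors would be
  blacklisted wholesale by the revisit rule, destroying genuine motion
  rather than resting-spot artifacts.
* **Ground truth**: episode ranges are labelled by applying the analysis
  definition (windowed speed ≥ 4 cm/s, minimum one full window) to the
  noiseless path, via an independent re-implementation of the windowed
  speed inside the generator. Gear labels and intended maxima come from the
  drawn parameters.
* **Artifacts**: bouts of 1–3 samples (probabilities 0.6/0.25/0.15),
  placed uniformly with ≥ 4-sample separation, defaulting to ≈ 0.3% of
  samples per type (≈ 1% total — the source analysis reports no artifact
  frequency; the default makes recovery tests meaningful). Out-of-arena
  bouts exceed the raster by 3–40 px; corner jumps land on the rest-spot
  pixel farthest from the current position; teleports land in-arena at
  ≥ 25 cm from both their predecessor and the underlying true position, so
  every teleport sample implies > 80 cm/s against its predecessor.
* One integer seed drives four deterministic sub-streams (schedule, motion,
  rest, artifacts) via `SeedSequence.spawn`.
* **Lesioned phenotype** (`lesioned_config`): p(second gear) 0.5 → 0.35,
  fast-gear center 1.24 → 1.175, dwell means (1.0, 1.3) → (1.5, 1.95) s,
  persistence lowered by 0.08 — mirroring the published direction and
  rough magnitude of change (incidence 50.6 → 36.4%, speed 19.9 → 17 cm/s,
  dwell 1.32 → 1.96 s, curvature roughly doubling).
* Stereology count tables: per-hemisphere, per-ROI estimates drawn
  lognormally (CV 0.2) around half the combined control means (SNc 5098,
  VTA 6318), with lesion reductions (0.95, 0.514) applied multiplicatively.

**What the synthetic tests do not show.** The generator produces idealized
kinematics — smooth symmetric speed bumps, stationary single-pixel rest, a
memoryless episode schedule, and no grooming, rearing or scanning
micro-behaviors. Passing recovery tests demonstrates that the analysis
chain is correct and well-calibrated under its own assumptions, not that it
would recover parameters equally well from real video tracking, where rest
is diffuse, speed profiles are asymmetric and artifact structure is richer.
In particular, heavy genuine pixel-revisiting (23 h recordings, favored
corners) removes real data by design; on long recordings this biases
detected episode counts downward and the second-gear fraction slightly
upward, exactly as it would have in the original analysis.

## Statistics

* Rank-sum comparisons use midranks for ties; the null distribution is
  exact (full enumeration) for n₁ + n₂ ≤ 12 without ties, otherwise the
  normal approximation with tie and continuity corrections. The reported
  statistic is the rank sum of the first sample. Pre/post contrasts use the
  unpaired test throughout, matching the stated method even where a paired
  test might seem natural.
* Benjamini–Hochberg adjustment is the standard step-up procedure, applied
  within each family.
* Bootstrap correlations resample pairs with replacement (default 5000
  iterations); the two-sided p value is the sign-crossing rule
  2 × min(frac(r* ≤ 0), frac(r* ≥ 0)) capped at 1, with a 95% percentile
  interval reported alongside. Degenerate resamples are redrawn. The
  bootstrapped statistic is the product-moment correlation (R values are
  what the endpoint–count analyses report); a slope mode is available.
  Empirical type-I error at nominal 0.05 sits near 0.05–0.06.
* The descriptive family is 2 groups × 6 endpoints × 4 contrasts = 48
  comparisons. The regression family over the 10 variables {SNc, VTA, LI,
  weight reduction (% of preoperative weight), 6 endpoints} is built as all
  unordered pairs *including* self-pairs — the lower triangle of the 10 × 10
  matrix, 10·11/2 = 55 entries, matching the published family size; the 10
  diagonal entries are degenerate (r = 1) and flagged `self_pair`, and
  `drop_self_pairs=True` gives the 45 off-diagonal pairs.

## Problem sizes used in the test suite

Recovery suites run on 30-minute recordings (23,040 samples): 20 clean
recordings at 15 episodes/min (≥ 300 episodes each) for parameter recovery,
5 corrupted recordings at 6 episodes/min for artifact recovery, 20 seed
pairs for the lesion-direction pattern, plus one full-scale 23 h recording
processed end to end. These sizes give per-recording sampling error well
inside the asserted tolerances (e.g. binomial error of the gear fraction at
n ≈ 350 episodes is ≈ 2.7 points).

## Known limitations

* The revisit rule removes genuinely revisited ground along with
  resting-spot artifacts; this is inherent to the method and quantified
  above, not corrected for.
* The EM fit assumes exactly two Gaussian components; no model selection
  over component counts is performed.
* The activity-phase criteria (20% of peak, 3-bin smoothing) are
  package-defined conveniences, configurable but not validated against an
  external standard.
* Curvature per episode is a heavy-tailed statistic (near-degenerate chords
  are skipped but moderately small chords still produce large ratios);
  group comparisons should rely on many episodes, as the endpoint means do.
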