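# Methods

## Gradient model

The gradient module treats each NaCl drop as an instantaneous point source
diffusing in two dimensions through an agar slab of depth `d`, giving the
free-space kernel `c(t, r) = 1e6·N/(4π d D t)·exp(−r²/(4Dt))` in mM with all
lengths in cm. The total field is the baseline medium concentration `C₀`
plus the superposed drop contributions, evaluated at assay start. The model
conserves mass exactly: integrating `c·d/1e6` over the plane returns the
drop's moles (verified by adaptive quadrature to relative error ≤ 1e-6).

Assumptions and limits:

- **Infinite-plane kernel.** No boundary condition is imposed at the plate
  wall, so the model slightly underestimates concentration near the wall at
  long times (salt that should reflect off the wall is allowed to leave).
  Over the ≤ 24 h between drop application and assay this matters little in
  the central region where worms are scored.
- **No evaporation or agar drying**, and a homogeneous, isotropic slab.
- **Agar depth** `d` is a plate-prep property, not a protocol constant; the
  default 0.35 cm is a typical NGM pour for a 50 mm plate and yields a
  ~57–85 mM span between plate center and peak for the standard drop
  schedule, matching the span the protocol targets. It is exposed as a
  config field because pours vary.
- **Drop timing.** The standard schedule uses elapsed times of 22 h (the
  midpoint of the 20–24 h window in which the first drop is applied), 5 h
  and 2 h, all measured to assay start.
- `r` is distance from the **salt peak** (the application point, 12.5 mm
  from plate center by default), not from the plate center;
  `predict_field` converts Cartesian plate coordinates accordingly.

Conductivity calibration is an exact two-point affine map through the
(reading, concentration) references — 50 and 100 mM plates in the standard
protocol — so it is exact at the references and linear everywhere, valid at
the room temperature the references were taken at.

### Key parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `diffusion_D_cm2_s` | cm²/s | 1.590e-5 | diffusion coefficient of 5 M NaCl in aqueous medium |
| `baseline_Co_mM` | mM | 50 | NaCl concentration of standard NGM |
| `agar_depth_cm` | cm | 0.35 | typical pour; see above |
| `peak_offset_cm` | cm | 1.25 | marked application point, 12.5 mm from center |
| plate radius | cm | 2.5 | 50 mm assay plate |

## Track simulator

The chemotaxis generator is a discrete-time run-and-tumble walk at the
recording cadence (3.75 fps, 7 min, release at plate center). Per frame the
worm advances `speed·Δt` along its heading; the heading diffuses with
Gaussian noise of scale `heading_noise·√Δt`; and with probability
`base_rate·Δt·max(0, 1 − β·dĈ/dt)` the worm pirouettes to a uniformly random
new heading. `dĈ/dt` is the temporal derivative of the concentration the
worm experiences, estimated as `(C − S)/τ` where `S` is an exponential
moving average of the sampled concentration with timescale `τ`
(`sensory_timescale_s`, default 2 s): klinokinetic gradient climbing needs a
temporal derivative, and a first-order sensory filter is the simplest
biologically sensible estimator. The gain `β` (s/mM) is 0 for an unbiased
walk; increasing it suppresses pirouettes while the sensed concentration is
rising and promotes them while it falls, producing net drift up the
gradient. The plate wall reflects: the radial coordinate folds at the wall
and the heading bounces off the local tangent.

Locomotion defaults (speed 0.15 mm/s, heading noise 0.2 rad/√s, base
pirouette rate 0.12 /s) are typical of adult hermaphrodites crawling on
food-free agar and give an unbiased walk whose 7-min spread stays well
inside a 50 mm plate.

Determinism: every worm draws from its own child stream spawned from the run
seed, so a worm's trajectory is byte-identical across runs and independent
of how many worms are simulated or what gain other runs used.

Detection gaps emulate tracker dropouts: a gap starts at any frame with a
configured per-frame probability and lasts a geometric number of frames;
the track id is retained across the gap (re-detection resumes the id), and
undetected frames get blank coordinates in the export, exactly the
missingness the analyzer must handle. The generator does not emulate worm
shape, two worms merging into one track, or tracking-algorithm biases —
passing tests show the analysis is correct for the stated missingness
model, not that any particular tracker is unbiased.

The secondary-assay generators are deliberately minimal: a sinusoid plus
Gaussian noise for bend angles; persistent ("roamer") versus localized
("dweller") walks for roaming; a two-state Markov chain per worm (constant
leave/return hazards) for lawn occupancy; and an expression-table generator
that honours explicit neuron→loci assignments exactly and adds independent
background expression.

## Chemotaxis outcome

Assay t = 0 is the first recorded frame. The scoring window is the final
`window_length_s` (default 60 s) of the recording, mapped to frame indices
`[round((T−60)·fps), round(T·fps) − 1]` — the last 225 frames at 3.75 fps ×
420 s. Missing frames are filled by carry-forward: the last detected
position repeats until re-detection, including a terminal gap running to the
end of the assay (a worm that left the camera field still contributes its
last position). Frames before a worm's first detection are excluded, never
back-filled. A worm with no detection at or before the window's end is
excluded from the plate summary and counted. Distances are Euclidean in
plate-plane mm with no agar-curvature correction, and plate aggregates
weight worms equally, not by frame counts.

## Behavior metrics

**Thrashing.** Manual scoring counts every flex of the body to one side, by
eye. The computational analogue registers a thrash each time the bend
angle, having moved at least the hysteresis gate (default 10°) in one
direction since the last registered extremum, reverses direction. On a
clean sinusoid this equals extremum counting (120/min at 1 Hz); on noisy
series the gate prevents noise-driven inflation as long as it exceeds the
noise amplitude.

**Roaming.** "Squares traversed" is read as distinct 3×3 mm grid squares
visited (set semantics) — the assay scores ink trails on the lawn, not a
path length. Consecutive positions are linearly interpolated so squares
crossed between frames are counted; a boundary-crossing count is available
as `method="crossings"` for the alternative reading. The grid anchors at
the plate center with a configurable origin offset for arbitrary overlay
placement.

**Aversion.** Per frame, the ratio of worms outside the lawn to all worms;
the scalar summary is the time-average of the per-frame ratio over the full
recording (the reduction over the ~1200 frames is not standardized; the
endpoint ratio is available as `ratios[-1]`).

## Co-transmission mapping

A cross labels a neuron iff its expressed-loci set contains both the driver
and the reporter locus — a commutative AND gate (what fluoresces differs
between FLP-on and split-GFP constructs, but the labeled set does not). A
neuron labeled by any cross in a panel counts once toward the
co-transmission tally (union semantics). Tallies operate on individual
neurons, not classes; percentages are rounded to integer percent, matching
printed-table precision. The bundled reference table transcribes only the
neuron identifications printed with the published crosses (with PDE kept as
one entry, as printed) plus single-transmitter padding; it cannot and does
not claim to reproduce genome-wide totals such as the 35-neuron roster,
which requires an atlas-derived table. Co-expression is a molecular
signature of co-transmission potential, not proof of co-release.

## Statistics

Routing: Shapiro-Wilk per group at α = 0.05; the parametric family is used
only if **every** group passes (the conservative aggregation). Groups need
n ≥ 3 and nonzero variance. Two groups → Student's t or Mann-Whitney; three
or more → one-way ANOVA with Dunnett's comparisons against the designated
control, or Kruskal-Wallis with Dunn's comparisons. All tests two-sided.

Numerical choices:

- **Exact Mann-Whitney** for pooled n ≤ 12: mid-ranks for ties, full
  enumeration of the C(n, n₁) label assignments, two-sided p = probability
  of a U at least as far from n₁n₂/2 as observed. Above 12, the
  tie-corrected normal approximation with continuity correction.
- **Dunn's test** is implemented directly (rank-sum z statistics with tie
  correction) with Bonferroni adjustment across the comparisons against the
  control; multiplicity-adjustment conventions differ between software
  packages, so the adjustment used here is stated rather than assumed
  equivalent to any other program's default.
- An **unequal-variance parametric route** (Welch's heteroscedastic ANOVA,
  with per-comparison Welch t tests Šidák-adjusted as a practical stand-in
  for Dunnett's T3 studentized-maximum-modulus comparisons) is selectable
  via `equal_var=False`.
- Significance annotation: ****, ***, **, * below 1e-4, 1e-3, 1e-2, 5e-2;
  NS otherwise.

Calibration: on a Gaussian null (3 groups of 10, 5000 simulations) the
routed omnibus pipeline rejects at 0.050 ± 0.01, verified in the test
suite. Simulation sizes throughout the suite (200 worms per gain setting
for the chemotaxis monotonicity check, 5000 null replicates for the type-I
calibration) were chosen to make sampling error small relative to the
effects being checked.

## Known limitations

- The gradient model ignores the plate wall and evaporation (above).
- The simulator's klinokinesis is one mechanism of chemotaxis; real worms
  also steer gradually (weathervaning), so simulated tracks are a test
  harness for the analysis pipeline, not a behavioral model of record.
- Track merging between intersecting worms is out of scope: the analyzer
  trusts track ids and handles missingness only.
- Dunn and T3 adjustments are documented choices, not bit-exact
  reproductions of any commercial package's post-hoc output.
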