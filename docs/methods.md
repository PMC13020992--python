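# Methods

This note documents the models, numerical choices and known limitations
of the package, in the order the pipeline uses them.

## Geometry and units

All locations are unit 3-vectors (sphere) or points in z = 0 (plane);
headings are unit tangent vectors.  Working in vectors avoids
latitude/longitude pole singularities; lat/lon appear only in CSV I/O.
Lengths are expressed in *degree units* throughout: 1 unit is the arc
subtended by 1° of great circle on the reference sphere, and the same
unit is used on the plane, so the 63.435° landmark spacing is literally
identical across the two surfaces.  A sphere at radius scale *s*
stretches every arc by *s* (an arc of *d* units spans *d/s* degrees of
central angle).  Positive turns are rightward — clockwise seen from
outside the sphere, or from above the plane.  The default absolute
tolerance on unit-sphere quantities is 1e-9; bearings to coincident or
antipodal points raise rather than guessing, since the shortest path is
not unique there.

The study constants (sphere radius 12.5 virtual units, walking speed
20°/s) are exposed for unit conversions: half the circumference is
π·12.5 ≈ 39.27 virtual units, and a full great circle takes
360/20 = 18 s.

## Ideal triangle-completion responses

An outbound path is two legs joined by a signed mid-path turn.  The
ideal inbound response under a geometry is constructed, not solved in
closed form: the endpoint pose comes from composed rotations, the
return bearing from the exact geodesic, and the response turn from the
signed angle between heading and bearing.  The construction is
self-verifying through the *closure oracle*: turning by the solution
and advancing by its distance must return to the start within 1e-9.
Spherical trigonometric identities (law of cosines, sine rule) serve as
an independent cross-check in the tests.

Two framings are reported: `inner_angle` (the triangle's interior angle
at the response corner) and `pooled_turn` = 180 − inner angle (the
response-turn variable after left/right mirror trials are folded onto
0–180°, which makes the turn a linear variable for regression).  Trial
tables store pooled turns.

The seven default outbound shapes (legs 30–90°, mid turns 60–120°) live
in `data/default_design.yaml`, not in code, so a different design can be
dropped in.  They span ideal planar turns of 94–156° and
planar-vs-spherical gaps of 4–45°, so responses cannot follow a
shape-insensitive stereotype and the two geometry models are
discriminable.

Degenerate shapes whose outbound endpoint lands within 1e-6 of the
start (or antipodal to it) are rejected.

## The multi-planar-map planner

The sphere is tessellated by the 20 faces of the regular icosahedron
whose 12 vertices carry the landmarks (vertex 0 at the north pole; all
edges arccos(1/√5) ≈ 63.435°).  Point-in-face tests use signs of
determinants against the three edge planes; edge/vertex ties resolve to
the lowest face id.

A route's *face chain* is the ordered sequence of faces crossed by the
great-circle arc, traced by dense sampling (0.02° steps) with three
deterministic repairs: endpoint faces on an edge/vertex keep the traced
face when it contains the endpoint; arcs passing numerically through a
vertex are bridged by the lowest-id common neighbor face; and as a last
resort the arc is nudged sideways by 1e-9 rad.

*Unfolding* develops a chain into the plane: the first face is
flattened about its centroid, and each subsequent face is attached as
the equilateral triangle across the already-placed shared edge.  The
per-face flattening map is the azimuthal-equidistant projection about
the face centroid composed with the exact similarity that puts the
three projected vertices onto the placed planar triangle (side 63.435
degree units; the similarity's scale is ≈ 0.980, so within-face
distances are distorted by at most a few percent).  Shared-edge
vertices glue exactly; a face revisited later in a chain receives a
fresh placement, as a development must.

*Planning* draws the straight segment from the start's image to the
target's image, lifts its direction back to a spherical heading through
the first face's flattening map (numerical differential, 1e-3-unit
step), and advances that heading by the planar length.  Direction error
is the angle between the lifted heading and the true bearing; position
error is the geodesic distance from the arrival point to the target.

The *suboptimal* arrangement models a wrongly recalled first landmark:
the detour vertex is the lowest-id landmark that is off the optimal
landmark set, in the start's neighborhood, and adjacent to the first
optimal waypoint (with tiered fallbacks when no such vertex exists),
and the map strip is developed along the polyline
start → detour → optimal waypoints → target, stitched through the
shorter side of each waypoint's face fan.  Waypoints are the crossed
edges' vertices nearer the arc's plane.  Detours that would make a leg
degenerate (antipodal or coincident) are filtered.

Simulated starts are uniform on the sphere, rejection-filtered to the
requested distance window from a fixed vertex target (rotational
symmetry makes one target sufficient); the suboptimal arm requires
distances above 120°.

### What the simulation can and cannot reproduce

The qualitative structure is robust: optimal arrangements are far more
accurate than suboptimal ones, all position errors stay well below the
90° chance level, and within-face plans are nearly exact.  The *maxima*
over 500 uniform distant starts are, however, larger than the bounds a
reader might expect from a smaller or differently sampled set of
starts: the development of a long geodesic across icosahedral patches
carries net turning set by the 60° vertex defects, so the straight-line
plan's initial direction can deviate up to ≈ 25° (optimal) even with a
distortion-minimizing flattening — at face-centroid starts, where the
projection is locally exact, the chord-versus-geodesic holonomy alone
contributes ≈ 14° on a 143° route, and conformal or gnomonic per-face
projections do no better.  The 95th percentiles (≈ 20° optimal; ≈ 57°
direction / 42° position suboptimal) sit close to the extremes visible
in a scatter of a few hundred draws.

## Synthetic cohorts

**Triangle completion.**  Responses follow the same family the analysis
fits: turn = α_i + β_i·(ideal turn of the responder's geometry) + ε,
with α_i ~ N(0, 10°), β_i ~ N(1, 0.15), independent draws for the
distance response, and trial noise ε ~ N(0, 14°) for turns and
N(0, 31°) for distances.  The noise values are calibrated so the
per-participant R² against the true turn predictor lands near 0.67 and
the distance R² near 0.36 under the default design — the fit-quality
band the analysis is meant to operate in — and live in
`data/default_cohort.yaml`.  On the plane environment every responder
produces the planar ideal (it is the correct solution there); the
responder geometry only matters on the sphere.  Responses are generated
directly on the pooled 0–180° scale; with the default design's ideal
turns (94–156°) noise excursions past the fold are negligible.  A
mixture responder blends the two ideal predictors with weight w.

**Object location.**  20 participants × 2 environments × 2 distance
conditions × 12 trials.  Targets are six designated landmarks; starts
are placed at a uniform distance within the condition's window (40–110°
short, 120–175° long, labels re-derived by the 110° threshold at
analysis time).  The planning strategy is either `global_3d` (true
great-circle bearing) or `planar_atlas` (the planner above; long sphere
trials use a suboptimal arrangement with probability 0.5).  Execution
adds wrapped-Normal heading jitter (sd 10°), multiplicative distance
misestimation (sd 20%), and an isotropic placement/memory error at the
stop (sd 10° per axis).  The placement component matters structurally,
not just for realism: without an error source independent of the
heading jitter, position error is a near-deterministic function of
direction error, and the within-participant position-outlier filter
then trims long plane trials asymmetrically, inducing a spurious
interaction even for global-3D navigators.  On the plane the planner is
exact (planar maps carry no distortion there), which is what makes the
long-versus-short gap sphere-specific under the planar-atlas strategy.

These generators emulate the *statistical structure* the analyses
assume — they do not model learning across runs, feedback-driven
strategy change, visual cue quality, or response-time dynamics, so
green tests certify the inference machinery and the planner, not any
claim about real participants.

## Inference

Outliers: Tukey fences at 1.5×IQR with type-7 (linear-interpolation)
quartiles — across participants within each triangle shape for the
triangle task (a trial is removed if *either* its turn or its distance
is outside), within participant on position error for the
object-location task.  Groups with fewer than 4 trials are kept whole
with a warning.

Mixed models: `dv ~ ideal predictor` with by-participant random
intercept and slope, unstructured 2×2 covariance, fitted by *full*
maximum likelihood (REML log-likelihoods are not comparable across
different fixed effects, so ML is required for the BIC comparison).
statsmodels' MixedLM is fitted under L-BFGS, Powell and Nelder-Mead and
the highest likelihood kept, since single optimizers stall on some
cohorts; the result matches an lme4 reference fit to 1e-4 on a frozen
fixture.  A singular covariance (smallest eigenvalue below 1e-8 of the
largest) triggers a refit with diagonal covariance, flagged on the
returned fit.  BIC = k·ln(n) − 2·logLik with k counting fixed effects,
unique random (co)variances and the residual variance; the Bayes factor
for model A over B is exp((BIC_B − BIC_A)/2).  The combined model adds
both predictors' fixed and random slopes.  Per-participant fit quality
is ordinary least-squares R², summarized as mean ± sd.  The radius
sweep fits spherical predictors at scales 1–3; by scale 3 the spherical
and planar predictors are nearly collinear and the comparison is
expected to saturate near BF = 1.

The interaction test computes, per participant, (long − short) mean
direction error on the sphere minus the same contrast on the plane,
then a one-sample JZS Bayes factor with Cauchy prior scale √2/2,
evaluated by adaptive quadrature (relative tolerance 1e-8) of the
inverse-gamma scale-mixture integral, plus the classical paired t and
Cohen's d.  Degenerate all-equal differences give t = 0 (or ±∞ with a
nonzero mean, where the evidence saturates).  The test is two-sided.

Bayes-factor design analysis simulates n paired differences from
Normal(d, 1) per replicate and reports the percentage of replicates
with BF₁₀ ≥ threshold, under the stated d and under the null.  A note
on the null arm: the fixed-n rate of BF₁₀ ≥ 3 at n = 20 under this
prior is analytic — BF₁₀(t) = 3 at t ≈ 2.561, so the rate is
2·P(T₁₉ > 2.561) ≈ 1.9% — which is the value the simulation converges
to; rates below 1% at this n require a different threshold or a
sequential design.

## Problem sizes

Defaults were chosen as the sizes the analyses are designed around: 20
participants, 7 shapes × 4 repetitions × 2 environments (1,120 trials)
for the triangle arm; 960 object-location trials; 500 starts per
arrangement for the planner simulation; 1,000 replicates per
design-analysis arm.  Model-recovery checks use 20 seeded replications.
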