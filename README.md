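# spherenav

Path integration and spatial memory on spherical versus planar surfaces:
geometry-model predictions for the triangle-completion task, a
multi-planar-map route-planning simulation over an icosahedral landmark
layout, synthetic behavioral cohorts, and the Bayesian inference used to
compare them.

## The scientific problem

Human path integration — keeping track of where you started while
walking — is well studied on flat ground, where the neural machinery
(head-direction cells, grid cells) appears optimized for 2-D Euclidean
geometry.  On a sphere that machinery makes *systematic* errors: after
walking two 90° legs joined by a 90° turn on a sphere, the correct
return is another 90° turn and a 90° arc, but a planar path-integration
system prescribes an inner angle of 45° and a √2-long leg — an overturn
and an overshoot.  Comparing a walker's inbound turn angle and distance
against the planar and the spherical prediction therefore reveals which
internal geometry they use.

The package implements the full computational chain for a study of this
question on a virtual sphere (radius 12.5 units, 12 landmarks at the
vertices of a regular icosahedron, 63° apart, walking speed 20°/s):

- **`geometry`** — exact geodesic navigation on the unit sphere and the
  plane (unit-vector representation, no pole singularities).  Lengths
  are in *degree units*: 1 unit = the arc of 1° on the reference sphere.
- **`triangle`** — ideal inbound solutions for any outbound design
  (leg, turn, leg) under planar or spherical geometry at any radius
  scale, with left/right response pooling onto the 0–180° scale.  The
  solver is a geometric construction whose ground truth is a closure
  test: executing the solution returns to the start to 1e-9.
- **`atlas`** — the icosahedral tessellation, face chains crossed by a
  great-circle route, isometric unfolding (development) of a face chain
  into the plane, and a planner that draws a straight line on the
  unfolded map and executes it on the sphere, with optimal or
  suboptimal (detour-landmark) patch arrangements.
- **`synthetic`** — seeded generators for triangle-completion cohorts
  (random intercept + slope per participant, Gaussian trial noise) and
  object-location cohorts (planar-atlas or global-3D planning strategy
  plus execution noise).
- **`stats`** — 1.5×IQR outlier rules, linear mixed models (random
  intercept and slope per participant, full ML) compared through
  BIC-approximated Bayes factors BF ≈ exp(ΔBIC/2), per-participant R²,
  a sweep over spherical-model radii, the JZS Bayesian paired t-test
  (Cauchy prior, scale √2/2), and Bayes-factor design analysis.
- **`pipeline` / CLI** — one seeded configuration runs the whole study
  end to end and writes CSVs plus a JSON report.

## Worked example

```python
from spherenav import PLANE, SPHERE, TriangleShape, ideal_inbound

shape = TriangleShape(leg1=90, mid_turn=90, leg2=90, shape_id="octant")
print(ideal_inbound(shape, PLANE))
print(ideal_inbound(shape, SPHERE))
```

prints (fields: inner angle, pooled turn, return distance):

```
InboundSolution(inner_angle=45.0, pooled_turn=135.0, distance=127.27922061357856, geometry=Geometry(kind='planar', radius_scale=1.0))
InboundSolution(inner_angle=89.99999999999999, pooled_turn=90.00000000000001, distance=90.00000000000001, geometry=Geometry(kind='spherical', radius_scale=1.0))
```

i.e. the planar rule overturns (135° vs. 90°) and overshoots (127° vs.
90°) on the sphere — the signature the mixed-model comparison looks for.

Running the full synthetic study (a cohort of 20 planar-responding
participants, 7 triangle shapes × 4 repetitions per environment):

```
spherenav run-all --seed 1 --out run1 --n-starts 60
```

```
sphere turn: winner planar (BF 3.02e+44); interaction BF10 1.86e+06; power 100%
```

The Bayes factor of ~3e44 says the planar-geometry mixed model explains
the synthetic sphere-condition turn angles overwhelmingly better than
the spherical one (as it should — the cohort was generated by planar
responders); the interaction BF10 shows the long-versus-short direction
error gap specific to the sphere that multi-planar-map navigation
produces; the power figure is the share of simulated experiments at
effect size d = 1.9, n = 20 that reach the BF ≥ 3 evidence threshold.

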