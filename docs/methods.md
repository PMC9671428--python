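# Methods

## Model

`tidalcrm` is a deterministic kinematic collision model. A rigid animal body
travels in a straight line along the flow axis (+X, speed over ground `v`)
through a device whose rotating components turn at constant angular speed
`omega = RPM * 2*pi / 60` about the flow-aligned rotor axis. There is no
hydrodynamics: no flow-field advection, no blade-induced deflection, no
behavioural response (avoidance and evasion are applied downstream of a CRM,
not inside it). A transit either ends at its first contact — producing one
collision record — or the animal clears the device; post-contact dynamics are
undefined and not modelled.

Per collision the model records the contact time, the contact point in world
coordinates and relative to the animal centre, the distance of the contact
behind the nose, the struck component, and the collision speed
`|v_seal + v_device|` where `v_device = omega x (p - hub)` on rotating
components and zero on static ones. The velocity-sum form is the published
definition; for an axially moving animal meeting a tangentially moving blade
the two velocities are orthogonal, so the magnitude equals that of the
velocity difference, and every blade-contact speed is bounded by
`sqrt(v^2 + (omega * R_tip)^2)`.

## Geometry

All bodies are *inflated primitives*: a core point, segment or triangle plus
an inflation radius. Distance between the animal capsule and any component is
then an exact closed form (segment-segment, segment-triangle, point-segment),
and the signed clearance `core_distance - r_seal - inflation` is exact through
contact, with penetration depth as its negative part.

- **Animal**: a capsule — cylinder of length `L - W` and radius `W/2` with
  hemispherical caps — matching the two published dimensions of an adult
  harbour seal (`L = 1.41` m nose-to-tail, `W = 0.34` m maximum diameter).
  The capsule admits exact distance queries and is the only shape those two
  numbers determine up to modelling taste.
- **Blades**: flat tapered plates (defaults: root radius 1.0 m, root chord
  1.6 m, tip chord 0.8 m, thickness 0.12 m), realised as core triangles in
  the rotor plane (span radial, chord tangential) inflated by half the
  thickness — i.e. a plate of the stated thickness with rounded edges. The
  planform is clipped so the *surface* maximum radius equals the 9 m tip
  radius; without the clip, corner contacts at radius > R would break the
  tip-speed bound above. Each blade is tessellated into 8 spanwise panels
  (16 triangles) so that radial and angular culling stay tight.
- **Hub**: a rotating sphere (radius 1.0 m) at the hub centre; the surface
  velocity of a contact point is `omega x r` of that point.
- **Foundation** (static): a vertical monopile capsule (radius 1.5 m, from
  the bottom of the release lattice to hub height) and a downstream nacelle
  capsule (radius 1.5 m, length 5 m). Foundation contacts are recorded with
  zero device velocity and count toward collision probability, since the
  release lattice explicitly covers the foundation.
- Hub, nacelle and foundation dimensions are not published anywhere the model
  could draw on; they are configurable stand-ins, and any result that depends
  on them cannot be compared numerically against the original device.
- **Mesh devices**: an STL/OBJ triangle mesh can replace the parametric
  assembly (zero-inflation triangle cores, per-component motion tags).

Coordinates are right-handed, +X flow/approach direction = rotor axis, +Z up,
angles counterclockwise viewed from upstream; `sense` flips handedness.

## Scenario and time-lags

A scenario crosses a release lattice (default 0.5 m spacing over 22 m x 23 m,
`floor(extent/spacing) + 1` points per axis: 45 x 47 = 2,115) with
`n_time_lags` initial rotor phases, 100 by default — 211,500 transits.
Phases are uniformly spaced over one revolution rather than randomly drawn:
the lattice is deterministic, converges like a quadrature rather than a
Monte-Carlo sample, and reproduces exactly; a `random_phases` option (seeded)
exists for sensitivity checks. The seal is released with its nose 5 m
upstream of the most-upstream device surface. The release distance is
result-invariant by construction — changing it only rotates which phase
lands where, and the uniform phase lattice is closed under rotation up to
quantisation (verified: per-cell CP shifts <= 1/n_time_lags) — so the default
is arbitrary and harmless.

## Contact detection

Time stepping bounds the relative surface displacement per step:
`dt = 0.05 m / (v + omega * R_tip)`. The thinnest feature the step can meet
is the inflated blade slab (thickness/2 + capsule radius ≈ 0.23 m), several
times the 5 cm step bound, so sign changes of the clearance cannot be stepped
over. On a sign change, bisection refines the contact to
`|clearance| <= 1e-3 m` (time bracket `<= 1e-4 s`; the clearance is Lipschitz
in time with constant `v + omega R`, so both tolerances are reachable
together). The contact point is the midpoint of the realizing closest pair at
the bracketed time. Two conservative culling layers keep desk-scale runs
fast without changing results: per-component axial time windows (a component
is only evaluated while the capsule's x-extent can reach it, padded by
0.1 m), and radial-band plus angular-sector culling for rotating triangles
(padded by a chord bound plus 0.05 rad). Both are sufficient conditions for
positive clearance, so skipping a culled component never alters a detected
sign. Distance kernels and the stepping loop are numba-compiled.

Degenerate inputs: a release point already in contact reports a collision at
t = 0; an empty device or empty grid raises before any simulation starts;
rotors are validated flow-aligned (+X) — other orientations are out of scope.

## Risk layer

- **Head/torso**: head iff the contact lies `< 0.4 m` behind the nose.
  Exactly 0.4 m classifies as torso (the published definition assigns
  `< 0.4` to head and `> 0.4` to torso; the boundary is measure-zero and
  goes to the larger region). Contacts marginally beyond the nose (negative
  distance, a contact-extraction artifact bounded by the 1 mm bracketing
  tolerance) are retained, counted as head, and surfaced as the
  `nose_overrun_rate` QC metric; the analytic engine keeps the rate at ~0%.
- **Mortality**: fatal iff `speed > threshold` (strict, matching "over that
  speed"), optionally OR the contact is a head strike (precautionary rule).
  The default sweep is thresholds 0–7 m/s; 5.1 m/s (CI 3.2–6.6) from the
  strike-pathology literature is an example value, not a built-in constant.
- **Maps**: per-cell probability = qualifying records / n_time_lags.
  **Overall** probabilities (sweep rows) = qualifying records / total
  transits over the whole lattice by default; whether published overall
  numbers average over the full lattice or only the swept area is not
  stated, so a per-instance mask parameter supports either domain and the
  package asserts neither.
- **Convergence**: CP recomputed from evenly thinned phase subsets against
  the full set, reported as max per-cell absolute deviation.

## Validation oracles

Two independent cross-checks certify the engine (test-support only):

1. **Closed form.** For a point-sized animal and a blade of constant angular
   width `phi(r)`, the fraction of uniform phases that end in contact is
   `min(1, n * (phi + omega * a / v) / 2*pi)` with `a` the animal's axial
   length plus blade thickness. The test device uses annular-sector blades
   (so `phi` is exact at every radius) of 0.02 m thickness: the closed form
   models a sharp-edged sector, and the rounded-edge mismatch of an inflated
   plate scales with its inflation radius, so a thin test plate keeps the
   geometric mismatch an order below the comparison band. The comparison
   uses 500 phases because with 3 blade arcs a 100-phase lattice quantises
   CP at up to ~0.03 — coarser than the 0.02 band being verified. Agreement
   across 4 radii x 3 speeds is within 0.01 in practice.
2. **Brute force.** A fixed-step (1 ms) detector sampling every component's
   *core* geometry (triangle areas and boundary edges, segment axes, sphere
   centres) with the component's exact inflation as a per-point radius,
   against the exact capsule. Its only error is tangential sample spacing.
   Engine agreement on randomized transits: 200/200 collided flags, all
   contact times within 0.02 s.

A static variant (`sampled_clearance`) estimates minimum distance by dense
sampling of both true surfaces (capsule surface; plate faces, rounded edges
and vertex spheres) and a KD-tree pairwise minimum; it brackets the analytic
clearance to < 0.01 m on randomized non-penetrating poses.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script: the
trend and QC checks run the scenario matrix on a 1 m lattice with 50
time-lags (27,600 transits per scenario, a few seconds each); the oracle
comparisons use single-cell scenarios. The full published scale (0.5 m
lattice, 100 time-lags, 211,500 transits) runs in well under a minute per
scenario on one core thanks to the culling layers; the tests stay at desk
scale because the property checks do not sharpen with lattice density.

## Known limitations

- The original device mesh is proprietary; with the parametric stand-in the
  published per-scenario totals, head/torso percentages and overall
  probabilities are reproducible only as qualitative trends (totals falling
  with approach speed, CP ≈ 1 across the swept area at slow approach, speed
  range hub→tip), not as numbers. Published collision speeds reaching
  17 m/s exceed `sqrt(v^2 + (omega R)^2)` for the stated parameters and are
  unreachable with any geometry here.
- First contact only; no post-strike trajectory, no multiple strikes.
- Straight-line transits; no dive profiles, no evasion/avoidance.
- The capsule has no appendages; strikes on flippers of a real seal would
  classify differently than on a capsule of equal length.
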