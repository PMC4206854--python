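# Methods

`trichosim` simulates the collective gliding of filamentous cyanobacteria
(*Pseudanabaena*-like trichomes) in a thin fluid layer, and quantifies the
stream/band patterns that emerge.  This note documents the model, its
numerical treatment, the parameters that matter, and the limits of what the
test suite demonstrates.

## Model

**Geometry.** Each trichome is a discrete inextensible rod: `N + 1` vertices
joined by `N` edges of equal length `l = Λ/N` (defaults `Λ = 750 µm`,
`l ≈ 6 µm`, diameter `Θ = 1.5 µm`).  For contact purposes each edge carries a
capsule of diameter `Θ`, cut at interior vertices perpendicular to the local
tangent and capped with hemispheres at chain ends.

**Dynamics.** Motion is inertialess.  Each vertex moves according to an
anisotropic overdamped mobility

    dx/dt = (1/ζ) (F∥ + F⊥ / b),        b = 2,

where `ζ` is the per-vertex drag: the slender-body drag of the whole
trichome, `4πµΛ / (ln(2Λ/Θ) + c)` with `µ = 1 Pa·s` and `c = 1/2`, divided by
the `N + 1` vertices.  Forces are the sum of four terms:

1. *Bending.*  Discrete-elastic-rod bending for a naturally straight,
   torsion-free rod: energy `E = (α/l) Σ_i |(κb)_i|²` with the curvature
   binormal `(κb)_i = 2 (e_{i−1} × e_i) / (|e_{i−1}||e_i| + e_{i−1}·e_i)`.
   The force is the exact analytic `−∇E`, with the gradient taken with
   respect to free vertex positions (edge-norm variation included); a
   finite-difference oracle in the test suite pins this down to relative
   1e−4.  The default `α = 2×10⁻²¹ N·m²` corresponds to a persistence length
   of 0.49 m — trichomes are effectively athermal, bent only by collisions.
2. *Gliding.*  A tangential thrust `ζ v₀ P t̂_i` at every vertex (`v₀ =
   1.3 µm/s`), which composed with the mobility propels an isolated straight
   trichome at exactly `v₀`.  The polarity `P ∈ {−1, +1}` flips as a
   Bernoulli event with probability `ω·Δt` per trichome per accepted step
   (`ω = 1/300 s⁻¹`), giving geometric inter-reversal times with mean `1/ω`.
3. *Contact.*  Admissible capsule-capsule interactions (projected-crossing
   point, otherwise up to four vertex-against-edge candidates filtered by the
   capsule domain conditions; chain-end caps claim the region whose
   projection clamps onto the end vertex) feel a truncated 13-7
   Lennard-Jones force `f(h) = ε/2 [(Θ/h)¹³ − (Θ/h)⁷]`: zero at surface
   contact `h = Θ`, repulsive below, weakly attractive out to the `2Θ`
   truncation.  Forces are interpolated to the four edge vertices so that
   each interaction is momentum- and torque-free.  The repulsive branch is
   capped at `R = 100 ζv₀` per contact (the model only needs repulsion to
   dominate propulsion; the cap bounds numerical stiffness).  The single
   emergent control parameter is the cohesion number `β = ε/(ζv₀)`.  `β = 0`
   runs keep a hard core (`f = 0` for `h ≥ Θ`) at the strength corresponding
   to `β = 0.125`.
4. *Walls.*  The domain is periodic in x and y and bounded in z by stiff
   linear walls acting when a vertex is within `Θ/2` of a face; the default
   stiffness `100 ζv₀/Θ` keeps the equilibrium wall penetration near `0.01Θ`
   under gliding-scale loads.

**Inextensibility.** After every accepted Euler step each chain is projected
back onto its fixed edge lengths by Newton iterations on the linearized
constraints; the chain topology makes each iteration an exact tridiagonal
Lagrange solve (Thomas algorithm), i.e. the converged limit of a
LINCS-style constraint solver.  Bond lengths hold to relative 1e−6 at every
step; an independent dense-matrix solve validates the projection in the
tests.

**Nondimensional structure.**  Choosing `V = v₀` and `L = sqrt(α/(ζv₀))`
reduces the equations to `dX/dτ = F_bend + F_glide + β F_contact`: the full
behavior is governed by `β`, `ωT`, the geometric ratios `Θ/L`, `Λ/L`,
domain`/L`, the density `ρ` and `N`.  The test suite verifies this scaling
operationally: two dimensional parameter sets related by the transformation
(lengths ×2, `α` ×8, `ω` /2) produce the same nondimensional trajectory to
1e−9.

## Numerics

* **Integration.**  First-order Euler with step-doubling error control: one
  full step is compared against two half steps; the step is accepted when
  the largest vertex discrepancy is below the absolute accuracy (default
  0.1 µm), and the next `dt` follows the standard first-order controller
  (safety 0.9, growth capped at 1.3×, `dt` capped so `ω·dt ≤ 0.05`).  The
  accepted state is the two-half-step solution.  A fixed-step convergence
  study in the tests confirms first-order behavior.
* **Neighbor lists.**  Candidate edge pairs come from a 2-D spatial hash of
  minimum-image edge midpoints, refined by the exact segment-segment
  distance to a cutoff of `2Θ` plus a one-diameter skin; same-trichome pairs
  within two edges are excluded (adjacent capsules overlap by construction).
  Lists are reused until some vertex has moved `Θ` since the last build.  As
  in the reference GPU implementations of such models, a pair pushed into
  range between rebuilds feels no force until the next rebuild; the skin
  makes this rare.
* **Initialization and relaxation.**  Trichomes start straight, horizontal,
  uniformly placed with random in-plane orientation; the count follows from
  the volume fraction `ρ` and the cylinder volume `π(Θ/2)²Λ`.  Overlaps are
  then relaxed with propulsion, cohesion and reversals disabled.  Dilute
  systems reach penetrations below `0.01Θ`; at working densities the
  trichomes form a jammed mat of mutual crossings whose mechanical
  equilibrium retains a small residual penetration (bending stiffness
  balances the soft contact core), so relaxation stops at the penetration
  plateau — the equilibrium itself.  A plateau deeper than `0.5Θ` is treated
  as "density too high" and raises.
* **Determinism.**  All randomness derives from one seed; each trichome owns
  a dedicated reversal substream, so trajectories are bit-reproducible on
  the same platform and independent of update order.
* **Units.**  All internal physics is SI; configuration files and trajectory
  output use micrometres and seconds (material constants `α`, `µ`, `ε` stay
  SI).  Temperature (used only in persistence-length conversions) defaults
  to 293.15 K; the source measurements never state it, and 20 °C reproduces
  the published conversions to their printed precision.
* **Kernels.**  The inner loops (bending, contact, constraint projection,
  pair search) are numba-compiled, single-threaded; every kernel is
  cross-checked against a plain numpy reference implementation in the test
  suite.

## Pattern observables

All orientational order parameters are nematic (built on doubled angles),
since reversals make trichomes head-tail symmetric:

* **Global alignment** — resultant length of doubled xy-projected edge
  angles; `O(M^{−1/2})` for `M` random edges.
* **Local alignment** — per edge, the resultant of relative 3-D angles to
  edges of *other* trichomes passing within `Θ` (true segment-segment
  separation, the contact model's own distance notion; the edge counts
  itself, so isolated edges score 1).  Midpoint-based neighborhoods are
  degenerate at `l ≈ 4Θ` — midpoints of touching edges are never within
  `Θ` — which is why the contact distance is used.
* **Local cluster size** — distinct trichomes passing within `2Θ`.
* **Tangent correlation length** `ξ` — exponential decay length of the mean
  intra-trichome tangent autocorrelation `acf(k) = ⟨e_i·e_{i+k}⟩`, fitted as
  `exp(−k l/ξ)` over lags up to the first zero crossing; straight trichomes
  report an infinite sentinel.  The estimator recovers the persistence
  length of synthetic worm-like chains to 10 %.
* **Sector alignment autocorrelation time** `T` — trichome edges are binned
  into 100 µm grid sectors; each occupied sector's nematic director (unit
  doubled-angle vector) is tracked over uniformly spaced frames (default
  spacing 288 s, window the last 2 h), and the sector-averaged director
  autocorrelation is fitted to `exp(−kΔt/T)`.  Frozen patterns report the
  infinite sentinel; i.i.d. directors report 0.
* **Sector density distribution** — per-sector edge counts; for a uniform
  configuration these are Gaussian, and aggregation into streams or bands
  shows up as positive skewness relative to the `t = 0` reference.

## Scaled-down demonstration runs

Full-culture simulations (3.5 mm – 1 cm domains, ~1700+ trichomes, 8–12
simulated hours) need cluster/GPU-scale compute.  The packaged
demonstrations reproduce the qualitative regime behavior at desk scale:

* *Stream formation (β = 0):* 500×500×7.5 µm, `ρ = 2.5 %`, `Λ = 250 µm`
  (`N = 42`, `l ≈ 6 µm`), `ω = 1/300 s⁻¹`, 2 simulated hours, three seeds.
  Mean local alignment rises well clear of its initial value (typically
  0.91 to 1.00, against a seed-to-seed spread below 0.005), and the final
  sector density distribution (50 µm sectors at this domain size) is
  positively skewed — the desk-scale analogue of cohesionless stream
  self-organization.  One caveat of the small domain: a single trichome
  spans half the box, so even the freshly relaxed state has clumpy sector
  counts whose sample skew fluctuates strongly between seeds; the
  aggregation signal is therefore assessed against the symmetric
  homogeneous reference, not against the per-seed initial sample.
* *Regime ordering:* 300×300×7.5 µm, `Λ = 150 µm`, 1 simulated hour,
  sector-director autocorrelation over the trailing 30 min at 144 s frames:
  the `β = 0` pattern persists longer than the `β = 5` dynamic mesh,
  reproducing the ordering of pattern-stability with cohesion.

These demonstration runs use an absolute integration accuracy of 0.25 µm
(one sixth of the trichome diameter) rather than the 0.1 µm default: the
qualitative ensemble observables they check are insensitive to per-step
error far below `Θ`, and the low-order integrator exists precisely because
only ensemble properties are of interest.  All force-level contracts are
tested at full precision elsewhere in the suite.

## Design choices where the ground truth is ambiguous

* The printed gradient of the curvature binormal is typeset ambiguously in
  the source literature; the implementation uses the full position gradient,
  with the finite-difference oracle as the arbiter of correctness.
* The printed tail-vertex tangent points backward; all tangents here are
  oriented head-to-tail and polarity is applied explicitly by the gliding
  force.
* The capsule domain conditions are implemented with the spherical-cap
  reading at chain ends (an end cap claims exactly the region whose
  projection clamps onto the end vertex); without it, collinear end-to-end
  approaches would feel no force until deep interpenetration.
* The contact sign convention is fixed so that the sub-`Θ` branch repels and
  the `Θ–2Θ` branch attracts (the printed compact form has the two branches
  reversed relative to its own description).
* "At most two force-bearing interactions per edge pair" holds in practice
  (≥ 99.5 % of random pairs; always in transverse encounters) but is not a
  theorem: nearly parallel overlapping capsules can touch at three or four
  admissible points, all retained.
* The truncated contact force at `h = 2Θ` is ≈ 3.4 % of the peak attraction
  (not < 1 %); the truncation is inherited as-is from the neighbor-list
  cutoff.

## Known limitations

* No torsion, natural curvature, growth, fragmentation, photomovement,
  hydrodynamic coupling or wall-proximity drag corrections: trichomes
  interact only through steric/cohesive contact and glide at fixed speed.
* The fixed per-vertex drag treats the medium as an unbounded viscous fluid;
  near-wall lubrication is ignored.
* The shallow default domain (`H = 7.5 µm ≈ 5Θ`) squashes vertical
  structure; ridge growth in z cannot be reproduced.
* Single-precision GPU behavior of the original large-scale runs is not
  emulated; this is a float64 CPU reference implementation.
* The scaled-down demonstrations show regime-level agreement (direction of
  effects, ordering), not quantitative pattern geometry at culture scale.
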