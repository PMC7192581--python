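# Methods

`spherotfm` reconstructs the collective contractile force of a tumor
spheroid embedded in a nonlinear biopolymer gel from brightfield time-lapse
images of fiducial marker beads. The method has four parts: a constitutive
model for the gel, a spherically symmetric contraction simulator, a
scale-invariant pressure–deformation lookup table, and an image pipeline
(PIV → projection → inversion). This note documents the model, the
numerical choices, and the known limitations.

## Constitutive model

Collagen-like fiber networks respond to strain in three regimes. The
per-fiber stiffness is

    kappa(eps) = k0 exp(eps / d0)              eps < 0          (buckling)
    kappa(eps) = k0                            0 <= eps <= eps_s
    kappa(eps) = k0 exp((eps - eps_s) / ds)    eps > eps_s      (stiffening)

with parameters (defaults for 1.2 mg/ml collagen, a 1:1 rat tail / bovine
skin mixture): `k0 = 1645 Pa` (linear fiber stiffness), `d0 = 0.0008`
(buckling decay strain), `ds = 0.033` (stiffening strain scale),
`eps_s = 0.0075` (stiffening onset). Presets for 0.6 and 2.4 mg/ml change
only `k0` (447 and 5208 Pa). The fiber energy `w(eps)` is the closed-form
double antiderivative with `w(0) = w'(0) = 0` — exact and fast inside the
solver loop; an adaptive-quadrature integration of the stiffness law serves
as an independent oracle in the tests.

Bulk behavior comes from the semi-affine assumption: each material element
deforms affinely and contains an isotropic fiber ensemble. The orientation
average reduces, by axial symmetry, to a 1-D integral over `c = cos(theta)`
evaluated with Gauss–Legendre quadrature (200 nodes for material queries,
120 inside the solver; doubling the node count changes the stress by less
than 0.1%).

**Uniaxial stress and tangent stiffness.** The radial stiffness map and the
zero-strain gel stiffness use the uniaxial stress of an ensemble stretched
by `diag(1+eps, 1, 1)` with *no lateral relaxation* (the configuration a
purely radial strain measurement probes; whether the original analysis
allowed Poisson relaxation is not documented, so we state our convention).
The tangent stiffness is a central finite difference with step `1e-4` —
below the curvature scales of all three branches. At `eps = 0` the buckling
kink makes the central difference average the softened left branch with the
linear right branch: we obtain 321.9 Pa for collagen-1.2, between the
one-sided continuum value `k0/5 = 329 Pa` and the reported 316 Pa (whose
exact orientation/differencing convention is not published). We do not
force agreement; the ±5% tolerance absorbs the convention gap.

A model honesty note: under deep uniaxial *compression* (`eps < -0.04`)
the affine tangent `d sigma / d eps` crosses zero, because the buckled
fiber tension saturates at `-k0 d0` while its axial projection keeps
shrinking. `uniaxial_stress` reports the model as-is; the stiffness map
floors reported values at the buckled-plateau scale `k0 d0 / 5` so maps
stay positive. Around a contracting spheroid the radial strain is tensile
and the floor is never active.

## Contraction simulator

A spheroid is modeled as a spherical inclusion (default radius
`r0 = 100 µm`) contracting inside a large gel sphere (outer radius 2 cm,
displacement fixed to zero there). The solution is spherically symmetric,
so the 3-D problem reduces to one dimension: the inward radial displacement
`u(r)` on 200 logarithmically spaced nodes. Element stretches are
`lam_r = 1 - du/dr` (radial) and `lam_t = 1 - u/r` (tangential, twice),
evaluated element-wise at interval midpoints — the 1-D analogue of
per-element affine deformation. The total energy (orientation-averaged
fiber energy times reference shell volume, minus boundary work) has a
tridiagonal Hessian; a damped Newton iteration with analytic gradient and
Hessian converges in a handful of steps. Interior residuals converge to
~1e-9 of the boundary reaction force (a double-precision cancellation floor
of the volume-weighted assembly; iterations stop when progress stalls below
1e-6 relative, which in practice means 1e-8–1e-12).

**Pressure convention (follower load).** The contractile pressure acts on
the *deformed* inclusion surface: the boundary work is
`P * 4 pi / 3 * (r0^3 - (r0 - delta)^3)` with `delta = u(r0)`. With a dead
load on the reference surface the semi-affine material admits no
equilibrium above ~600 Pa for collagen-1.2 — tangential buckling lets the
inclusion collapse outright — which would make the 0.1–10,000 Pa lookup
range meaningless. Under the follower convention equilibria exist at all
pressures, and the scale-invariance argument is unchanged (the deformed
area also scales with the square of the geometric scale factor).
Pressure-controlled solves are implemented as bracketed root-finds on the
surface displacement (each step a warm-started displacement-controlled
Newton solve), which is robust at severe strain stiffening.

**Scale invariance.** Rescaling a solution by `a` — `U*(r) = a U(r/a)`,
`r0* = a r0` — yields the equilibrium of the rescaled problem at the same
pressure; the strain energy scales as `a^3` and the pressure depends only
on the relative contraction `delta / r0`. These are asserted as properties
(collapse within 1% pointwise, energy within 2%) rather than assumed.

## Lookup table

150 simulations with pressures logarithmically spaced from 0.1 to
10,000 Pa (warm-started continuation, about a minute on one CPU) are
resampled onto a common logarithmic distance grid `x in [1.05, 50]`
(120 points). All interpolation is in log-log space, where the curves are
near power laws. Two curve families are stored:

- **static** `y(x; P)`: the equilibrium deformation `u/r0` observed at the
  normalized *lab-frame* (deformed) distance `x = (r - u)/r0`. Lab
  coordinates are the ones a tile-based measurement of the deformed gel
  reports; they are used for inverting simulated profiles, forward
  prediction, and synthetic ground truth.
- **accumulated** `m(x; P)`: the deformation a fixed lab-position observer
  accumulates when the pressure ramps monotonically from zero — the ramp
  integral of Lagrangian increments evaluated at the particle currently at
  `x` (trapezoidal accumulation along the sweep). Summing incremental PIV
  fields at fixed tiles converges to exactly this quantity, which exceeds
  the static curve at large strain because the tile successively tracks
  material arriving from farther away (+3% in deformation, ~+10% in
  pressure at 1000 Pa). Measured fields are therefore inverted against the
  accumulated family; this removes a systematic overestimate without
  touching the measurement itself.

Inversion interpolates `log P` against `log y` at the query distance;
curves are strictly increasing in pressure at every distance (checked at
build time), so the inverse is unique. Measurements outside the tabulated
band return NaN — flagged and excluded from the median, never clamped,
because clamping would bias the median toward the table edges. Tables are
persisted as versioned JSON (portable and diff-able); loading a different
format version is refused.

## Image pipeline

**PIV.** Each frame pair is compared on quadratic tiles (default 40 px
window — 50 px is the documented alternative for the 4x/1.02 µm setting —
with 50% overlap). The central half-window of the earlier frame is located
inside the full window of the later frame by normalized cross-correlation
(template matching); this avoids the loss-of-pairs bias of plain
same-window correlation and resolves displacements up to a quarter window
per step. The correlation peak is refined by a 3-point Gaussian fit per
axis (parabolic fallback where side lobes are non-positive; no refinement
when the peak is an exact match). Tiles with no texture, a peak below 0.5,
or a first-to-second peak ratio below 1.3 are flagged invalid, not errored.
Verified accuracy on rendered bead scenes: integer shifts exact to
0.05 px, half-pixel shifts within 0.2 px per tile.

**Drift and accumulation.** Rigid stage drift is removed by subtracting
the mean offset of the valid tiles of each step (the mean of a radially
symmetric contraction field over a symmetric tile grid is zero, so this
removes drift without removing signal). Increments are summed at fixed
tile positions (Eulerian accumulation, no advection of tile positions) —
matching the measurement convention the accumulated lookup family is built
for. Invalid increments contribute zero and are counted per tile.

**Segmentation and projection.** The spheroid is segmented in the first
frame: light Gaussian smoothing, global Otsu threshold (spheroid darker
than background), hole filling, largest connected component. The effective
radius is `r0 = sqrt(A_proj / pi)`. Accumulated vectors are projected onto
the inward radial direction (`u_proj = -(u . d_hat)`, inward positive);
tiles pass only if the vector points within ±20° of the (positive or
negative) radial direction — outward vectors are kept with negative sign,
so relaxation phases remain visible. Tiles inside the spheroid mask are
excluded.

**Force reconstruction.** Tiles farther than `min_distance_factor * r0`
(default 2.0; 3–4 recommended for irregular tumoroids) are inverted
through the lookup; the per-timestep summary is the *median* pressure, and
the contractility is `F = P * 4 pi r0^2` with `r0` from the initial
segmentation. Negative projected deformations map outside the
positive-pressure lookup domain and are excluded — a documented limitation:
strong whole-field relaxations reduce the tile count rather than producing
negative pressures. Angular profiles median the tile pressures in 72 bins
of 5°; the coefficient of variation over bins (std/mean) quantifies
directional anisotropy. Deviation maps report `|P_tile - P_best| / P_best`
per tile.

**Stiffness maps.** The scattered projected deformations are linearly
interpolated and differenced along the outward radial direction with step
`delta` equal to the PIV window size, giving the radial strain
(Eq. form `(u(r) - u(r + delta e_r)) / delta`; positive = tension with our
sign conventions); the local stiffness is the tangent stiffness of the
fiber model at that strain.

## Synthetic data

The generator emulates the experimental imaging setting: ~1 µm beads at
2e8 beads/ml seen by a low-NA (0.1) objective — with a ~30 µm optical
section this is ~6e-3 beads/µm², the default areal density — rendered as
Gaussian spots (sigma 1 µm) on a light background, a dark smooth-edged
disc for the spheroid (default r0 = 150 µm in a 1000×1000 px frame at
1.29 µm/px), additive Gaussian noise, and optional stage drift as a random
walk. Bead motion is imposed bead-wise from the simulator-derived field
(each bead's displacement satisfies the static lab-frame curve at its
final position, solved by fixed-point iteration), so the ground truth is
exact and no image resampling is involved. With the default density the
PIV quality flags pass on well over 95% of far-field tiles.

What the synthetic scenes do *not* emulate: fiber texture (confocal
reflection imagery), invading cells near the spheroid rim, illumination
gradients, bead polydispersity, and out-of-plane motion. Passing the
end-to-end tests therefore demonstrates the correctness of the
reconstruction chain under the stated imaging model, not robustness to
every artifact of real microscopy.

## Problem sizes and determinism

The test suite and the acceptance script use reduced problem sizes chosen
as desk-scale defaults: 40-pressure lookup tables over the range the tests
exercise, 10–18 frame time-lapses, 512–1000 px frames. All randomness
(bead positions, noise, drift) flows from explicit integer seeds;
re-running an analysis with the same config is byte-identical.

## Known limitations

- The high-pressure near-surface decay exponent of the continuum 1-D
  model is shallower than -2 but does not reach -0.2 when fitted over
  `x in [1, 2]` at 2000 Pa (we obtain about -0.32; the local slope at the
  surface is -0.24 at 2000 Pa and approaches -0.2 only above ~4000 Pa).
  Discrete per-element fiber sets and 3-D mesh effects in the original
  finite-element implementation plausibly account for the difference; we
  keep the deterministic continuum quadrature and report our value.
- The uniaxial tangent stiffness is not meaningful under deep compression
  (see above).
- The lookup covers contraction only; sustained outward (pushing) fields
  are excluded tile-wise rather than reconstructed.
- The accumulated curve family assumes monotone loading from the
  undeformed state; brief relaxations (twitches) are fine, but a strongly
  non-monotone history would blur the correspondence.
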