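# Methods

This note documents the models implemented in `chiralswim`, the
parameter defaults and why they were chosen, the numerical decisions,
what the synthetic data do and do not emulate, and known limitations.

## Helical path geometry

A cell swimming at constant speed with constant path curvature κ and
torsion τ traces a helix, parametrised as
(r·cos p, r·sin p, c·p) with r = κ/(κ² + τ²) and
c = h/2π = τ/(κ² + τ²).  Over a phase interval P the arc length is
l = P·√(r² + c²) and the chord displacement is
s = √((r cos P − r)² + (r sin P)² + c²P²); their ratio s/l is the
**directionality** of the path.  For hP ≫ r this tends to
τ/√(κ² + τ²), strictly decreasing in κ and increasing in τ.  At whole
turns (P = 2πm) the lateral chord terms vanish and the finite-P ratio
equals the limit exactly.

Kinematics map onto geometry through the Darboux relation at constant
speed s: κ = ω_κ/s and τ = ω_τ/s, where ω_κ is the angular velocity of
(t, n) about the binormal b and ω_τ the longitudinal rotation of
(b, n) about the travel direction t.  Conventions: τ > 0 is a
right-handed helix, the sign of ω_τ carries through to τ;
directionality is handedness-invariant.  The straight line
κ = τ = 0 is carried as an explicitly flagged degenerate descriptor
(infinite radius) rather than as silent zeros, so no downstream code
can divide by zero; its directionality is 1 by convention.

## Brownian diffusion coefficients

The cell body is modelled as a prolate spheroid with effective Stokes
radii r_d = 1.5 μm along t and r_np = 8.0 μm along n and b
(an elongated cell: translation along the long axis sees the smaller
effective radius).  Translational coefficients follow Stokes–Einstein,
D_i = kT/(6π r_i μ).  Rotational diffusion starts from the
Stokes–Einstein–Debye coefficient of the equal-volume sphere,
E = kT/(8πμa³) with a = (r_d²·r_np)^(1/3) ≈ 2.62 μm, and is adjusted
per axis by the Perrin friction factors of a spheroid of axial ratio
e = r_np/r_d ≈ 5.33:

    ξ² = (e² − 1)/e²,  S = 2·artanh(ξ)/ξ
    f_d  = (4/3)·ξ² / (2 − S/e²)           (about the long axis)
    f_np = (4/3)·(1/e² − e²) / (2 − S·(2 − 1/e²))   (about the short axes)

For e ≈ 5.33 these give f_d ≈ 0.703 and f_np ≈ 5.10; spinning about
the long axis is much easier than tumbling.  The factors are friction
*ratios* relative to the equal-volume sphere, so effective rotational
diffusion divides by them: E_i = E/f_i.  The opposite reading
(multiplication) is preserved behind a `perrin_mode` switch because
the per-step expression could be read either way, but division is the
physically standard convention and the default.  The oblate branch
(e < 1) is implemented through the analytic continuation
artanh(iξ)/(iξ) = arctan(ξ)/ξ with ξ² carrying its sign.

**Parameters.** Temperature defaults to 299.15 K (26 °C ambient imaging
temperature; a Celsius constructor converts by +273.15).  Viscosity is
not a measured quantity here; the default is water at 26 °C,
μ = 8.7 × 10⁻⁴ Pa·s, and is configurable.  The Boltzmann constant is
the exact SI value.  All coefficients scale as T/μ exactly.

## Swimmer integrator

One Euler step of length δt (default 0.2 s, matching the 5 Hz imaging
frame interval):

1. translate by s·δt along t;
2. rotate the frame deterministically (below);
3. if Brownian motion is on, translate along t, n, b by independent
   normal draws with standard deviations √(2D_dδt), √(2D_npδt),
   √(2D_npδt), then rotate about t, n, b by independent normal angles
   with standard deviations √(2E_dδt), √(2E_npδt), √(2E_npδt),
   applied sequentially in that order about the instantaneous body
   axes (non-commutation error O(δt²), negligible for these
   sub-milliradian kicks);
4. re-orthonormalise the frame (Gram–Schmidt; equivalent to unit-
   quaternion renormalisation) and, with cyclic boundaries, wrap the
   position into the volume.

**Deterministic rotation.** Curvature rotates (t, n) about b at ω_κ
and torsion rotates (b, n) about t at ω_τ.  Applying these as two
sequential finite rotations is only accurate for small per-step
angles; at the extremes of the simulation grids used here
(ω = 5 rad/s at δt = 0.2 s, i.e. 1 rad per step) the split biases the
realised path noticeably (directionality error up to ~0.05).  For a
constant body-frame angular velocity the exact one-step motion is a
single rotation about the combined Darboux axis ω_τ·t + ω_κ·b by
|ω|·δt, so the integrator composes the deterministic rotation that
way.  The two forms agree to O(δt²); with the combined rotation the
noise-free discrete path matches the closed-form helix directionality
to ~2 × 10⁻⁴ over the whole grid, and halving δt still at least halves
the remaining (chord-stepping) error.

**Populations.** Each cell draws its speed and angular velocities once
from normal distributions (defaults 5 ± 2 μm/s; draws of s ≤ 0 are
redrawn; a (0, 0) speed specification is allowed and means passive,
diffusion-only particles).  Curvature noise has three modes: `fixed`
(ω_κ held at the mean — parameter-sweep grids), `per_cell` (one signed
draw per cell — morphogenetic noise), and `rerandomized` (redrawn
every 200 ms — flagellar propulsion noise).  Draws keep their sign: a
negative ω_κ curves the path the other way about b, which is what
keeps re-randomised noise unbiased.  Each cell owns an RNG stream
seeded from (seed, cell index), so populations are reproducible,
order-independent and trivially parallelisable; identical seed and
cell count give byte-identical outputs.  Initial conditions are the
origin with t = +x (directionality experiments) or uniformly random
positions and orientations when a volume is configured (video
rendering).

## Synthetic videomicrographs

Rendering emulates 5 Hz, 512-frame (102.4 s) low-magnification
dark-field movies at 0.65 μm/pixel: each cell is a point-like Gaussian
spot whose amplitude is constant within ±10 μm of the focal plane and
decays exponentially beyond (default e-folding length 5 μm, chosen so
detectability falls to a few percent ~25 μm from focus, consistent
with reliable detection only within ~10 μm of the focal plane), and
whose width broadens linearly with defocus beyond the plateau.  This
is a synthetic stand-in for an empirically measured point spread of
defocused adhered cells, which is not available; the plateau-then-
exponential detectability is the feature that matters for tracking.
Optional Gaussian or Poisson noise can be added.  Output is multi-page
16-bit grayscale TIFF with pixel size and frame rate recorded in the
image description tag; the reader accepts any multi-page grayscale
TIFF.  A trajectory sampled every 0.2 s maps one-to-one onto frames; a
finer sampling must divide the frame interval and is subsampled.

What this does *not* emulate: physically accurate dark-field
scattering, elongated cell bodies (cells are point-like at 10×
magnification), beat-frequency intensity flicker, and imaging-depth
truncation of real chambers.  Passing the end-to-end tests therefore
shows the pipeline recovers motion statistics from movies with the
stated detectability structure, not that it is robust to every real
imaging artefact.

## Tracking and statistics

Background is removed by subtracting the per-pixel minimum projection
over time.  Cells are detected per frame as local maxima of the 2 px
Gaussian-blurred frame above a threshold (default 5× the blurred
frame's standard deviation; maxima closer than the blur scale are
suppressed so spots merged by the blur yield one detection, and
detections are emitted in coordinate order so downstream processing is
independent of detector ordering).  Linking: each live track predicts
its next position by linear extrapolation from its last two points
(its last point alone if it has one) and claims the nearest detection
within 15 px; conflicts are resolved greedily in ascending
predicted-distance order with coordinate tie-breaks, unclaimed
detections seed new tracks, and unmatched tracks terminate permanently
(no gap closing).  The outcome is deterministic and invariant to
detection order within a frame.

Per-track statistics use velocities over an evaluation window
δt = 2 s at one-frame stride: v_t = (r_{t+δt} − r_t)/δt.  Mean speed
is ⟨|v_t|⟩; directional persistence is ⟨v_t·v_{t+δt}/(|v_t||v_{t+δt}|)⟩
(zero-length velocities are skipped).  Tracks shorter than 5 s are
excluded.  The 2 s window is the interval at which the directional
autocorrelation (computed with a 0.5 s base window, rounded to a whole
number of frames with the actual window used in the denominator) has
shed the fast beat/rotation oscillation but not the path direction.
Population summaries weight every track by its duration in seconds —
including the fractions of track time above persistence thresholds
(0.80/0.90/0.95) and the conditional persistence of fast tracks
(> 5/8/10 μm/s) — so behaviours that fragment tracks are not
undercounted.

## Analytical movement model and fitting

Lateral displacement at position z along the cell and time t:

    x_r = A_r(z)·sin(p_r(z) + ω_r t)        y_r = A_r(z)·cos(p_r(z) + ω_r t)
    b   = A_b(z)·sin(p_b(z) + ω_b t),       ω_b = 2π f_b
    x_c = x_r + b·sin(p_r + p_o + ω_r t)    y_c = y_r + b·cos(p_r + p_o + ω_r t)

with all five per-point functions defined at 8 control points and
linearly interpolated, plus the two global frequencies.  This is a
numerical description of movement, not physically consistent
kinematics (cell length is not preserved over a beat cycle), and the
effective hydrodynamic shape is obtained by setting A_b ≡ 0: the
centreline (A_r sin(p_r + ω_r t), A_r cos(p_r + ω_r t), z), whose time
argument only rotates it rigidly about z.

**Fitting.** The manual workflow (adjust parameters, watch R²) is
preserved as evaluate + `goodness_of_fit`; automated fitting uses
variable projection.  With the two frequencies fixed, the model is
linear in sinusoid coefficients — the beat term expands into sidebands
at ω_b ± ω_r — so each trace is solved by linear least squares, and
only (ω_r, ω_b) are searched.  Because the residual is oscillatory in
frequency (side lobes a cycle-per-record apart), the search starts
with a grid scan within ±30% of the initial guess at quarter-cycle
resolution, then refines locally, then polishes all parameters
jointly.  Per-point parameters are recovered from the sinusoid
coefficients in closed form.  Phases are defined modulo 2π per trace;
after fitting, the per-point (p_b, p_o) → (p_b + π, p_o + π) sign
equivalence is resolved point-by-point from the first control point
outward and all phases are unwrapped onto continuous branches
(adjacent control points differ by < π).  A cell whose rotation phase
advances by less than ~0.5 rad over the record cannot constrain
A_r/p_r — the beat can masquerade as rotation at ω_r = ±ω_b with a
perfect fit — so ω_r is pinned in that case and the result is flagged
non-identifiable.  Non-convergence is reported on the results object
with best-so-far parameters, not raised.

The coordinate convention places z along the cell's long axis with z₁
at the flagellum-tip end; only internal consistency matters for
torque signs.  The default width profile (0.5–1.5 μm, tapering to the
ends) is a synthetic stand-in used when no measured widths are given.

## Slender-body torque

The effective shape is treated as 7 straight segments between the 8
control points, each a slender cylinder of radius equal to the mean of
its endpoint half-widths.  Drag per unit length per unit speed uses the
Gray–Hancock resistive-force coefficients with segment length q as the
slenderness scale:

    C_par  = 2πμ/(ln(2q/r) − 1/2)      C_perp = 4πμ/(ln(2q/r) + 1/2)

(a Lighthill-style variant with the 0.18-prefactor argument is
switchable; the choice rescales absolute torque but not signs or rank
order, which is why the package's validation is antisymmetry- and
rank-based).  q ≤ 2r is rejected as violating slenderness.  For a
uniform flow U·ẑ, the drag on a segment tilted at θ has a component
perpendicular to the flow of magnitude (C_perp − C_par)·U·sinθ·cosθ
per unit length; crossed with the segment midpoint's radial offset
from the z axis (the rotation axis of the shape model) this gives the
segment's torque about z, reported per segment and in total in pN·μm
(1 pN·μm = 10⁻¹⁸ N·m; inputs are μm, μm/s, Pa·s).  Exact properties:
linearity in U and μ, zero total for planar shapes (the lever-arm
cross product vanishes in-plane), and sign reversal under mirror
reflection.  For refinement studies the per-segment coefficients can
be overridden, since segment length is not a meaningful slenderness
scale for very fine subdivisions; an 8-point single-turn helix is
within ~11% of its 1000-point refinement at fixed coefficients.

## Experiment orchestration and problem sizes

Named experiments bundle the standard conditions: the directionality
grids over ω_κ, ω_τ ∈ [0, 5] rad/s with Brownian motion (`fixed`,
`per_cell` at 0 ± 0–5 rad/s, and `rerandomized` at 0 ± 0–2 rad/s every
200 ms), and the three morphotype-like populations
(ω_τ = 11.0 ± 3.0, 2.5 ± 0.7 and 0.15 rad/s; ω_κ = 0.6 ± 0.2 rad/s
per cell; speed 5 ± 2 μm/s) rendered into a 332.8 × 332.8 × 100 μm
cyclic volume (the 512 × 512 px field of view at 0.65 μm/px, focal
plane at mid-depth) and re-analysed by the tracker.  Default
population sizes are 100 cells per condition and 25 cells per grid
point — enough for the rank-order and monotonicity conclusions the
package asserts, with paired per-cell RNG streams across conditions
acting as common random numbers for variance reduction — with a
`--full` flag for 10,000-cell runs.  Configurations serialise to YAML
(round-trip identity), a run's config is copied into its output
directory, and identical config + seed reproduce outputs byte for
byte.

## Known limitations

- No hydrodynamic propulsion from cell geometry: swimming is
  kinematic (speed + angular velocities); torque from shape and the
  rotation it would drive are compared by correlation, not closed into
  a self-consistent force balance against rotational drag.
- No translation–rotation mobility coupling, wall effects, or
  cell–cell interactions.
- Tracking is 2-D; no depth reconstruction from defocus, and no
  run/tumble segmentation (the speed–persistence scatter is the
  product).
- The movement model is descriptive, not mechanical, and its
  rotation component is unidentifiable for non-rotating cells.
- Rendered cells are points; morphology is invisible to the tracker.
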