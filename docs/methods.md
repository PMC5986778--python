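# Methods

## Model

A marker on a pole-like tree performing small free vibrations in the
horizontal plane is modelled as a particle restrained by two orthogonal
spring/damper pairs.  In the principal (stiffness) frame the equations of
motion decouple:

    X'' + 2 δ₁ X' + ω₁² X = 0
    Y'' + 2 δ₂ Y' + ω₂² Y = 0

with natural angular frequencies ω₁ ≤ ω₂ (rad s⁻¹) and envelope decay
rates δ₁, δ₂ (s⁻¹), both axes underdamped (δᵢ < ωᵢ).  The principal frame
sits at an angle α to the measurement x-axis.  A pull-and-release test
starts the motion from rest at (X₀, Y₀), giving the closed-form solutions

    X(t) = X₀ e^(−δ₁t) [cos(ω̄₁t) + (δ₁/ω̄₁) sin(ω̄₁t)],   ω̄ᵢ = √(ωᵢ² − δᵢ²)

and likewise for Y.  Measured coordinates are the rotation of (X, Y) by α.

Terminology: δ (s⁻¹) is called the viscous damping ratio in parts of the
tree-sway literature; the dimensionless ζ = δ/ω is the conventional
damping ratio.  This package calls δ the decay constant and ζ the damping
factor, and reports both.

## Identification procedure

1. **Extrema.** Local extrema of the recorded x(t) and y(t) are detected
   (`scipy.signal.find_peaks`) with a prominence floor of
   `prominence_fraction × max|signal|`, and each extremum time is refined
   by a parabola through the three surrounding samples.  Runs of
   same-kind extrema are collapsed to the most extreme member so maxima
   and minima alternate.
2. **Coincidence time t₁.** Each y-extremum is paired with its nearest
   unused x-extremum; the signed gaps Δt = t_x − t_y versus the pair
   midpoints form a sawtooth whose genuine zero marks the instant when
   both velocities vanish simultaneously, satisfying ω̄₂ − ω̄₁ = π/t₁.
   Because the nearest-neighbour pairing re-wraps every time the faster
   axis gains half a period, sign changes are accepted only when both
   bracketing gaps are below a quarter of the median extremum spacing;
   the first accepted crossing (least distorted by decay) is linearly
   interpolated to give t₁.  Two guards handle the edge cases: a floor on
   max|Δt| (1% of the spacing) turns the equal-frequency degenerate case
   into an explicit error rather than a fit to floating-point noise, and
   when heavy unequal damping pushes one coordinate through a beat node
   at t₁ (which displaces the zero), the cleanest available sign change
   is used and flagged `quality="fallback"`.
3. **Rectangle construction.** With A = (x(0), y(0)) and
   B = (x(t₁), y(t₁)) (linear interpolation between samples), the equal-
   diagonal rescaling λ = |OA|/|OB| maps B onto the corner C = λB of the
   envelope rectangle.  The chord CA is parallel to the principal X axis
   when the count n of y-extrema before t₁ is even, and to the Y axis
   when odd; its two-argument arctangent gives the geometric angle
   estimate, reduced to [0°, 180°).
4. **Angle refinement.** The single-λ rescaling is exact only when both
   axes decay equally; for δ₁ ≠ δ₂ the decayed position shrinks
   anisotropically (e^(−δ₁t₁) vs e^(−δ₂t₁)) and the geometric angle can
   be biased by tens of degrees at realistic parameters.  The reported α
   therefore minimises the summed squared residual of the two independent
   per-axis fits over a 90° window around the geometric seed (grid at 5°
   then bounded Brent to 10⁻⁷ rad).  Principal directions are defined
   modulo 90°, so one window covers every candidate frame and subsumes
   the even/odd parity ambiguity.  The geometric α and λ are reported
   unchanged as diagnostics.
5. **Per-axis fits.** The trajectory rotated by α gives two principal
   coordinates, each fitted independently by nonlinear least squares
   (`scipy.optimize.least_squares`, bounds δ ≥ 0, ω̄ > 0, relative
   parameter tolerance 10⁻¹⁰, ≤ 500 evaluations) to the free-decay
   waveform over (A₀, δ, ω̄).  Starting values: ω̄ from the magnitude
   spectrum peak with parabolic interpolation; δ from the slope of
   log|extremum| versus time; A₀ from the first sample.  A₀ is fitted
   rather than pinned to the first sample so marker noise at t = 0 is not
   forced into the other parameters; the pinned variant's residual is
   reported alongside for transparency.  Derived outputs: ω = √(ω̄² + δ²),
   f = ω/2π, ζ = δ/ω.
6. **Canonical labelling and consistency.** Axes are relabelled so
   fit_X.ω ≤ fit_Y.ω, with α the measurement-frame angle of the
   lower-frequency axis in [0°, 180°).  The check π/t₁ ≈ ω̄₂ − ω̄₁ is
   always reported, never enforced: 2% is achievable on clean synthetic
   records, while 25% is the real-data default because the diagonal
   construction is only approximate under unequal decay and measurement
   noise.

## Synthetic data

`generate_trajectory` emulates a pull-and-release recording: exact
closed-form principal solutions on a uniform grid, rotated by α, with
optional i.i.d. Gaussian noise per coordinate per sample applied in the
measurement frame (emulating marker-tracking error; real marker noise may
be correlated across time and axes, and real stems add small
nonlinearities and multi-mode content that the simulator deliberately
omits — passing tests demonstrate correctness of the estimator on the
model, not robustness to un-modelled physics).  Sample rates at or below
twice the fastest oscillation frequency are refused.

Default study conditions used by the tests and the acceptance script:
30 s records at 100 Hz (motion-capture-like rate, ~100 cycles at
~3.4 Hz), frequency gaps of 1–10%, damping factors ζ of 0.5–5%, release
amplitudes X₀ = 10 mm, Y₀ = 5 mm.  The unequal amplitudes represent a
generic pull direction: the perfectly symmetric X₀ = Y₀ release onto a
45° diagonal is a measure-zero configuration in which one measured
coordinate degenerates to a pure beat.  With gap g and damping factor ζ
the signal at t₁ is e^(−πζ/g) of its initial amplitude (down to ~10⁻⁷ in
the hardest corner of the study range), so noiseless synthetic analyses
use a prominence floor of 10⁻⁹ (`SYNTHETIC_CONFIG`); the default 0.05
floor is meant for real records where noise sets the detection limit.

The shape atlas fixes ω₁ = 20 rad s⁻¹, gaps p ∈ {1, 3, 5}% with
ω₂ = ω₁(1 + p/100), equal decay δ ∈ {0.1, 0.3, 0.5} s⁻¹, a corner start
X₀ = Y₀ = 1 mm (shapes are scale-free), 20 s at 200 Hz.  The narrowness
statistic — the ratio of the smaller to the larger singular value of the
mean-centred point cloud — is rotation- and scale-invariant and orders
the grid exactly as the qualitative rule states: wider with growing p,
narrower with growing damping.

## Numerical choices and limitations

- Angles are radians internally, degrees at interfaces; lengths mm,
  time s; no unit inference (a `m` flag rescales on read).
- Sub-sample extremum timing by 3-point parabola (shift clipped to ±½
  sample); x(t₁), y(t₁) by linear interpolation (adequate at ≥ 100 Hz).
- Track CSV written with 12 significant digits; round-trips are exact
  beyond the 9 digits the format guarantees.
- Dominant-plane projection discards the least-variance SVD direction;
  the in-plane basis is anchored to the measurement axes so planar input
  passes through unchanged (up to mean-centring), and the discarded
  variance fraction is reported.
- Overdamped or critically damped axes, forced/wind excitation, 3-DOF
  motion and multi-marker joint inference are out of scope.  No
  uncertainty quantification is attached to the fitted parameters.
- Under heavy unequal damping (|δ₂ − δ₁|·t₁ ≳ 1) the t₁ diagnostic can
  lock onto a later coincidence (2t₁); the fitted frequencies, decay
  rates and α are unaffected (they come from the residual scan), but the
  π/t₁ consistency check will flag the record.
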