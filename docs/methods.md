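# Methods

## Model and assumptions

The measured DHM phase is φ = φₒ + φₐ, with φₐ a smooth polynomial surface
Σ P[k,l]·xᵏyˡ over raw pixel indices (x = column, y = row, 0-based, unit
spacing, origin top-left; coefficients in rad·px⁻⁽ᵏ⁺ˡ⁾).  No coordinate
centering or physical pixel-pitch scaling is applied; the printed
magnitudes of typical coefficients (e.g. a 1e-2 rad/px tilt giving ~5 rad
across 512 px) are only meaningful on this raw-index convention.

Three assumptions carry the method:

1. **Rank-1 separability.** exp(i(f(y)+g(x))) is an exact rank-1 matrix,
   so PC1 of exp(iφ) recovers a separable background completely.  No
   mean-centering is applied before the SVD — centering would destroy this
   factorisation, which is the entire point of working on the complex
   exponential rather than the raw phase.
2. **Cross-term elimination by differencing.** On an integer grid the
   j-fold forward difference of xʲ is exactly j! (no asymptotics), so the
   min(k,l)-order difference along the matching axis turns any xᵏyˡ into a
   separable surface while preserving the coefficient.  Differences use
   `diff`/`cumsum` semantics: unit spacing, no division, extent shrinking
   by one per difference.
3. **Itoh condition.** Unwrapping (2D before the first derivative, 1D on
   singular-vector phases) is exact when true adjacent-pixel increments
   stay below π; all synthetic surfaces in the test battery satisfy this.

## Parameters

- `fit_degree` (default 5): degree of the 1D least-squares fits replacing
  the two dominant singular-vector phases, and of the boundary-row fits.
  Must cover the highest polynomial degree expected along one axis after
  differentiation; 5 covers fourth-order optics with margin.  Higher
  degrees track more of any sample structure that leaks into PC1 (see
  limitations).
- `IterationPlan` (default ladder (1,x),(1,y),(2,x),(2,y), `include_pca0`
  on): a conventional PCA pass is tried first — it is cheaper and less
  noise-sensitive than derivative steps — then derivative order rises
  until the background is flat.  Fourth-order aberrations need only the
  j=1 rung twice plus the j=2 rung for terms with min(k,l)=2.
- `std_threshold` (default 0.1 rad) and `improvement_floor` (default 5%):
  background-STD stopping rules.  The threshold declares the field flat;
  the floor stops on diminishing returns.  A step that *worsens* the
  background STD is reverted before stopping: its derivative was not
  PC1-dominated, so the subtraction would only inject estimation error.
  Passing `None` for both gives the fixed-schedule ("manual evaluation")
  mode used by the reproduction scripts.
- `boundary_mode`: `"measured"` (default) seeds the integration with the
  boundary vectors captured from the measured phase, exactly inverting the
  difference; `"extrapolated"` replaces each captured vector with its own
  polynomial fit, trading exact inversion for robustness when sample
  structure touches the image border.
- Background region: explicit rectangles, or a 10%-margin border frame by
  default (specimens are assumed roughly centered).  The STD is the
  population standard deviation about the region mean.

## The synthetic generator

`synthgen` emulates: polynomial aberration surfaces (any sparse coefficient
set), a sample phase of a smooth Gaussian spot (default peak 1 rad,
σ = 50 px, centered) plus a sharp binary letter pattern (default
"d-PCA" at 1.5 rad, ~1.6% pixel coverage, rendered from a built-in 5×7
raster so no font engine is involved), wrapping into (−π, π], additive
Gaussian phase noise (seeded), and four-step phase-shifting holograms
(shifts 0, π/2, π, 3π/2; the reference is retarded so the extracted term
is O·R*).  It does **not** model speckle, shot noise, detector
quantisation, pupil effects or physically scaled (µm) coordinates, so
passing tests demonstrate algorithmic correctness on smooth polynomial
backgrounds, not robustness to every artefact of real holograms.

Default grid 512×512 (the size the timing and demo discussions refer to);
unit tests run mostly at 128–256 to stay fast, with the number-matched
demonstration checks at 512.

## Numerical choices

- **Wrapping interval** is fixed to (−π, π] for bit-exact tests; values of
  exactly +π are mapped to −π before calling the scikit-image unwrapper
  (which expects [−π, π)) and the result is re-congruence-corrected.
- **Piston.** The rank-1 product's constant phase is assigned wholly to
  the x-profile (`v_phase`); every residual metric removes the mean first,
  since absolute phase offsets carry no information here.
- **2π-branch alignment.** The separable estimate of a derivative surface
  comes from exp(i·phase) and is therefore only defined modulo 2π.  A
  stray 2π constant would integrate to a ~π·x² surface, so before
  integration the estimate is snapped to the branch of the measured
  derivative (median-rounded 2π multiple).
- **Conditioning.** All polynomial fits (1D singular-vector/boundary fits,
  2D coefficient-recovery fits) are performed on domains scaled to order
  one and the coefficients rescaled to raw pixel units.
- **Degenerate spectra.** If the two leading singular values tie within
  1e-12 the decomposition's first component is used as returned, with a
  warning — PC1 is then not unique.
- **Exactness of the inverse.** `integrate` is the exact inverse of
  `partial_derivative` (boundary vectors re-seed each cumulative sum), so
  noise-free polynomial aberrations with min(k,l) within the plan and
  degrees within `fit_degree` compensate to ≤1e-6 rad at realistic
  (few-radian) surface magnitudes.

## Known limitations

- **Sample leakage.** Because exp(i(φₐ+φₒ)) = D_f · exp(iφₒ-part) · D_g
  for separable φₐ-parts, the PC1 singular-vector phases equal the
  aberration profiles *plus the PC1 phase of the sample-only matrix*: a
  smooth, centered sample (e.g. a Gaussian spot of ~1 rad, σ ≈ 10% of the
  field) contributes a separable component that the polynomial fits partly
  absorb.  The residual against truth therefore scales with the sample's
  separable energy — about 0.09 rad for the default stand-in sample, and
  proportionally less for weaker or narrower specimens.  This is a
  property of PCA-based compensation itself, not of this implementation;
  background segmentation or robust fitting would be needed to go below
  it.
- **Noise sensitivity.** Derivative steps amplify per-pixel noise (the
  difference doubles noise variance, and the cumulative sum re-integrates
  fit errors across the field).  The j=0 pass is preferred when it
  suffices; boundary smoothing and the revert-on-worsening rule contain
  the worst of it.
- **Strong cross terms.** When a derivative surface is itself still
  non-separable (e.g. the j=1 step on a hundreds-of-radians x²y² term),
  its PC1 estimate subtracts a partly arbitrary separable surface; the
  evaluation loop recovers at realistic magnitudes, but the schedule is
  not guaranteed to converge for arbitrarily large cross aberrations.
- **Border samples.** In `"measured"` boundary mode, sample phase lying on
  the first rows/columns leaks into the recovered background there; use
  `"extrapolated"` mode in that case.
- A true phase jump above π between neighbours (violating the Itoh
  condition) cannot be unwrapped correctly by construction.
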