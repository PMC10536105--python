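# Methods

## The measurement model

An ellipsoidal-reflector photometer places the sample at the first focus
of a truncated mirror ellipsoid and a CCD conjugate to the second, so the
spatial distribution of scattered light arrives at the sensor as a zoned
"photometric image". The analysis reduces each frame to three numbers: the
mean digital number (DN) of the central circle A1 (radius R1, nominally the
collimated-beam radius), the middle ring A2 (R1–R2) and the external ring
A3 (R2–R3), all centred on the image's radial symmetry point. "Illuminance"
throughout means this zone-mean DN statistic, not a radiometric lux value.

Ring illuminance as a function of sample thickness d (mm) and laser power
P (mW) follows a two-stage parametric model:

* transmitted (forward-scattered) light: `E_T(d) = m(P) · exp(n(P) · d)`,
  an exponential decay valid for d > 0.7 mm — below that, single-scattering
  transients make the decay law a poor description, so thinner samples are
  excluded from transmitted fits (configurable `d_min`);
* reflected (backscattered) light: `E_R(d) = a(P) · ln(d) + b(P)`
  (natural log), a slow logarithmic growth;
* the per-power coefficients are polynomials of P: m, a, b quadratic and
  n sextic, coefficients ordered constant-first.

The package ships the published coefficients for stacked 0.1 mm
polyethylene film at 650 nm over ten powers 1.8–23.4 mW (2.4 mW steps) as
`erphot.reference`, used both as the generator's default forward model and
as the target of the validation comparisons.

## Region of interest and symmetry point

`detect_roi` marks pixels at or above `tau · max(frame)` as bright, takes
the bounding box of the rows and columns containing any bright pixel, and
accepts it once the form objective — the box's side ratio rows/cols — lies
within `form_limits`; otherwise the sensitivity threshold `tau` is lowered
by `tau_step` and the scan repeats, failing (with the last form value
reported) when `tau_min` is passed. Defaults: `tau0 = 0.5`,
`tau_step = 0.05`, `tau_min = 0.05`, `form_limits = (0.8, 1.25)`. The
iteration scheme is fixed by the method; the constants are package
defaults, since real bright areas are near-square and a centred disk
passes at the first threshold.

An accepted box is expanded to a square about its own centre (clipped at
frame edges): the method requires a square ROI but thresholding of a real
spot rarely yields one exactly. The symmetry point is the ROI's central
pixel for an odd side and the common corner of the four central pixels for
an even side; under the pixel-centre convention used throughout — pixel
(r, c) occupies the continuous point (r + 0.5, c + 0.5) — both cases are
simply the midpoint of the half-open ROI bounds, which is how it is
computed.

## Zone membership and illuminance

Zone masks classify each pixel by the distance from its centre to the
symmetry point with half-open intervals: A1 iff dist < R1, A2 iff
R1 ≤ dist < R2, A3 iff R2 ≤ dist < R3. This makes the three zones an exact
partition of the R3 disk — no boundary pixel is counted twice or dropped —
and "area" is the pixel count, so illuminance is summed DN over the zone
divided by its pixel count. Sub-pixel area weighting was deliberately not
used: the reference statistic is a plain pixel-count ratio, and fractional
weights would shift zone means in a way the published coefficients do not
reflect.

R2 and R3 are batch-global configuration constants (the same for every
frame of a study, so ring illuminances are proportionate across the
batch); R1 defaults to the beam radius in pixels (2 mm beam diameter at
≈14.4 px/mm, the scale at which a 480-row sensor spans a field of radius
equal to the reflector's 16.7 mm focal parameter).

Reflected-light frames carry a systematic central shadow (the beam-delivery
prism and tube in the camera's view). Because it is systematic — identical
across the frames being compared — it is *not* excluded by default;
`zone_illuminance` accepts an exclusion spec that removes occluded pixels
from both the DN sum and the area for sensitivity analysis. The default
occlusion rectangle is inscribed in the A1 circle, so ring statistics are
unaffected either way.

Replicates follow the reference protocol: three measurement points along
the sample perimeter, three captures each, and the nine zone-illuminance
values averaged arithmetically per (thickness, power, mode).

## Synthetic generator

`render_frame` draws a piecewise-constant spot — each zone at its target
level, a flat background outside R3 — adds Gaussian read noise, applies
occlusion rectangles multiplicatively, clips to the sensor range and
rounds to integer DN. `generate_study` sets the ring levels from the
forward model (`gain · E_model`, clipped at zero DN) for every
(thickness, power, mode, site, capture) combination, with per-frame seeds
derived deterministically from the study seed.

What the generator emulates: the zoned mean-brightness structure, sensor
noise and quantization, the reflected-mode shadow, and the replicate
layout. What it does not: optical blur and aberrations of the ellipsoidal
mirror, speckle, radial structure within a zone, flat-field or dark-frame
non-uniformity, and saturation behaviour. Passing recovery tests therefore
demonstrate that the *analysis chain* is faithful to the model it assumes,
not that the model captures every property of real captures.

Choices the data model forces:

* **Units and gain.** The published model-unit illuminances reach ≈25,000,
  beyond 8-bit range, and no DN-per-unit conversion is published. The
  generator renders 16-bit frames by default and exposes a `gain` factor
  (DN per model unit, default 1); the pipeline divides gain back out of
  measured illuminances, so regression results are always in model units.
* **Noise.** No sensor-noise model is published; additive Gaussian read
  noise (default 2 DN for image studies) is an assumption, and the noise
  standard deviation is a direct knob.
* **Negative model values.** The logarithmic reflected model predicts
  negative illuminance below ≈1 mm at some powers, and the sextic n(P) —
  whose printed high-order coefficients are heavily rounded and amplified
  by P⁶ — drives transmitted levels below 1 DN at high power beyond a few
  mm thickness. A physical sensor clips the former at 0 DN and quantizes
  the latter away, which is exactly what `render_frame` does; image-based
  recovery is therefore quantization-limited, and exact-recovery checks
  run on the model-level path (`synthesize_illuminance_table`), which
  bypasses rendering and evaluates the forward model directly.

## Fitting numerics

* **Exponential fits** use the exact log-linear solution (ln E regressed
  on d) as starting values, refined by Levenberg–Marquardt on the original
  scale; the refinement is accepted only if it does not increase the
  residual sum of squares. Pure log-linear fitting would minimise relative
  rather than additive error and distort coefficients under noise; pure
  nonlinear fitting without the log-linear start risks poor convergence.
  On noiseless data the log-linear start is already exact.
* **Logarithmic fits** are ordinary least squares of E on ln d, solved by
  `lstsq`; a test verifies agreement with the textbook closed-form slope
  and intercept to machine precision.
* **Power polynomials** are fitted in numpy's shifted/scaled polynomial
  basis and converted back to raw monomial coefficients: a raw degree-6
  Vandermonde over 1.8–23.4 mW is ill-conditioned, while the scaled route
  recovers exact sextic coefficients to ~1e-15 absolute.
* **r²** is 1 − SSres/SStot with centred SStot, computed on the original
  scale, reported per polynomial. A perfect fit of constant data is
  defined as r² = 1.
* Degenerate inputs fail loudly: fewer than 3 usable points, non-positive
  illuminance in a transmitted fit, non-positive thickness in a reflected
  fit, or fewer distinct powers than the polynomial degree requires (the
  sextic needs 7; stage 2 skips a family with a warning rather than
  failing the run when the power grid is too small).

## Problem sizes and what the tests compute

The validation study is the reference grid: transmitted thickness
0.8–10 mm in 0.2 mm steps, reflected 0.1–10 mm in 0.1 mm steps, ten
powers — 1,470 conditions, run noiselessly at model level in well under a
second, recovering every quadratic-family coefficient to better than
1e-10 relative and every sextic coefficient to better than 1e-12 absolute.
The image-path integration test renders a reduced grid (transmitted
0.8–3 mm where levels stay well above 1 DN at every power, reflected
1–10 mm, one replicate, gain 3) at 640×480 / 16 bit and recovers the same
coefficients to the quantization limit (quadratic families within 2%
relative, sextic terms within 1e-3 absolute). Geometry primitives are
checked against brute-force per-pixel classifiers over randomized centres
and radii, and ROI centre recovery over 100 random spot placements is
within 1 px noiseless and 2 px at 2 DN read noise.

## Known limitations

* The link between ROI size and the reflector's focal parameter requires
  an object-to-sensor magnification that is instrument-specific; ROI size
  is data-driven here, and the focal-parameter relation is left as a
  configuration cross-check.
* Published reliability values sit beside specific coefficients in the
  reference table and their exact assignment (m-fit vs n-fit vs combined)
  is ambiguous; the package reports r² per polynomial and makes no claim
  about reproducing that assignment.
* Whether the original stage-1 fits were log-linearised or nonlinear is
  not recorded; both agree exactly on noiseless data, which is what the
  recovery validation uses.
* Occlusion rectangles are taken from configuration, not detected; no
  flat-field/dark-frame correction or saturation repair is attempted.
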