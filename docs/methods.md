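# Methods

`hybridpgi` implements a hybrid ion-range verification pipeline that images
the secondary radiation excited by a therapeutic ion beam in a phantom with
the *same* detector array in two modalities at once:

* **Compton prompt-gamma imaging (PGI)** of the quasi-instantaneous
  nuclear de-excitation gammas (0.6–6 MeV), whose emission tracks the
  slowing-down ions and peaks near the Bragg peak;
* **in-beam PET** of back-to-back 511 keV photons from beta-plus emitters
  (⁹C, ¹²N, ¹³O, ¹⁰C, ¹¹C, ¹⁵O) activated along the track, split into
  *in-spill* (during beam delivery) and *off-spill* (between spills)
  images.

Because the experimental list-mode data are not deposited, the package
includes a first-class synthetic event generator that reproduces the
statistical structure the analysis relies on; everything downstream of the
hit stream is the analysis under test.

## Geometry and conventions

Four Compton imagers (one 50×50 mm² monolithic scatter crystal, 15 mm
thick — 10 mm for imager C — plus four 50×50×25 mm³ absorber crystals in a
co-planar 2×2 plane) sit in twofold front-to-front configuration: A/D
face each other across the beam at x = 0, B/C at x = −60 mm
(50 mm crystal + 10 mm lateral gap), scatter front faces 198 mm apart
(|z| = 99 mm).  The beam runs along −x at y = z = 0; images live on the
z = 0 plane.  Imager C carries a 0.93 efficiency scale (thinner scatter).
Each absorber crystal is mounted with its 25 mm dimension along x
(50×100 mm² footprint per imager): with 60 mm imager spacing a 100 mm-wide
absorber plane would physically collide with its neighbour, and this
orientation preserves all stated distances, volumes, and non-overlap.
Crystal membership uses closed boxes (points on a face are inside) so
boundary behaviour is deterministic.

A consequence worth knowing: with 50 mm crystal columns the deepest
reconstructable LOR midpoint is ≈ −85 mm, so the 155 MeV-like scenario
places its Bragg peak centered in the downstream (B/C) field of view
(prompt peak −55 mm, β⁺ fall-off midpoint −62 mm) rather than at the
experimental absolute depths — shift-recovery results are
placement-independent.

## Synthetic event generator

The generator replaces transport physics with parametric depth profiles
(plateau — optionally with a Gaussian-smeared erfc fall-off at its deep
boundary — + Bragg-peak Gaussian + optional entrance-flash Gaussian for
He/C + optional exponential distal tail), sampled by inverse CDF.  The
55 MeV graphite scenario uses narrow coincident peaks; the 155 MeV PE
scenario uses a broad β⁺ plateau with an erfc edge (midpoint −62 mm,
σ = 4 mm), the shape the off-spill distributions show at that energy:

* **Prompt gammas**: depths from the prompt profile; transverse Gaussian
  beam spot (4 mm FWHM default); discrete line energies
  {718, 2000, 4440, 6130} keV with weights {0.25, 0.30, 0.35, 0.10}
  (a 4.44 MeV carbon line plus representative lines spanning the 0.6–6 MeV
  acceptance; the 6.13 MeV line deliberately falls outside the sum window,
  emulating out-of-window flux); emission times uniform within the 45 ms
  spills of the 300 ms synchrotron cycle.
* **Activation**: per-isotope inventories follow the closed-form spill
  recursion N⁺(k) = N⁻(k−1)e^(−λτ_s) + (R/λ)(1−e^(−λτ_s)),
  N⁻(k) = N⁺(k)e^(−λτ_b); decay times are drawn from the tabulated
  activity curve λN(t) (piecewise-exact at period boundaries).  Default
  isotope set ⁹C (126.5 ms), ¹²N (10 ms), ¹³O (8 ms), ¹⁰C (19.3 s),
  ¹⁵O (122 s), ¹¹C (20.4 min) with yields {1.0, 0.3, 0.2, 0.5, 0.3, 0.3}
  favouring ⁹C, the dominant short-lived contributor under this duty
  cycle.  Annihilation pairs are exactly back-to-back; origins are blurred
  by a 2 mm positron-range sigma.
* **In-spill broad component**: a prompt-epoch pair channel (flat in
  depth, 15 mm transverse sigma, in-spill times; 15% of the annihilation
  budget) models pair production and in-setup positron annihilation during
  delivery.  Its share was set so the in-spill PET profile comes out
  ≈ 1.5× wider than the off-spill one, the contrast the experimental
  width table shows.
* **Transport** is single-scatter and attenuations-free: a photon entering
  a scatter crystal Compton-scatters once at a depth uniform along its
  chord, with the angle drawn from the Klein–Nishina law; the scattered
  photon is fully absorbed if it enters an absorber of the same imager.
  Annihilation photons make photoelectric-like full-energy hits in the
  first crystal they enter, thinned by a configurable efficiency (0.7).
  Energy splitting is exact before smearing.  Detector response defaults:
  5% FWHM at 511 keV with 1/√E scaling of the fractional resolution, and
  1.5 mm per-axis position sigma (representative of large monolithic
  halide crystals; both configurable, and no test depends on the exact
  default).  Directions are importance-aimed at crystal volumes by
  default; this biases only the absolute efficiency — which the generator
  does not claim to model — never the cone or LOR geometry.
* **Seeding**: one master seed; sub-streams are spawned with
  `SeedSequence.spawn` in a fixed order (prompt sampling, prompt
  transport, annihilation sampling, annihilation transport, background),
  so identical configs give byte-identical hit files.

What a green test therefore establishes: that the selection,
reconstruction and statistical machinery behave correctly on data with the
assumed structure.  It does not validate nuclear cross-sections, absolute
count rates, neutron backgrounds, pile-up or dead time — none of which the
generator emulates.

## Event selection

PGI coincidences pair a scatter-layer hit with an absorber-layer hit of
the same imager inside a closed ±10 ns window; accepted when the energy
sum lies in 600 keV–6 MeV *and* the absorber deposit alone is ≥ 600 keV
(suppressing positron-decay and random coincidences), and the Compton
kinematics are valid.  (With the 600 keV absorber floor the kinematic cut
is provably redundant — cos θ ≥ 1 − 511/600 — but it is kept and counted
for non-default windows.)  PET coincidences pair hits on opposite sides of
the beam plane (any layer) inside ±10 ns with a 0.9–1.1 MeV sum.
Multi-hit ambiguity resolves earliest-first with a stable (energy, crystal
index) tie-break; every run emits a selection report with
accepted + per-cause rejected = candidates.

## Compton reconstruction

Each accepted pair defines a cone: apex at the scatter hit, axis from the
absorber hit toward the scatter hit (pointing back into the source
half-space), half-angle θ from
cos θ = 1 − m_ec²(1/E_abs − 1/(E_sc+E_abs)).

*Backprojection oracle*: every cone accumulates a Gaussian band (width in
mm: angular deviation × apex distance, default σ = 3 mm) around its conic
intersection with z = 0.  Strictly non-negative, linear, permutation
invariant — the geometric ground truth the analytic route is tested
against.

*Analytic spherical-expansion inversion*: a cone ring at angle θ on the
direction sphere has Legendre spectrum P_l(cos θ).  Averaging over the
ring azimuth (addition theorem), a backprojected event contributes
P_l²(cos θ) per degree, so the unbiased per-degree inverse filter divides
by the ensemble mean of P_l².  The filter collapses to a two-argument
kernel K(cos θ_e, μ) = Σ_l (2l+1)/(4π) · w_l P_l(cos θ_e)/H_l · P_l(μ),
precomputed on a (cos θ bin × μ) table and evaluated at
μ = direction(event apex → pixel) · axis.  Evaluating at each event's own
apex (rather than a common imager reference) removes a parallax of up to
~20 mm and makes the argmax agree with the backprojection oracle to the
pixel.  Regularization: truncation at l_max = 40, Gaussian apodization
w_l = exp(−l(l+1)σ_r²/2) for a 2° ring width, and suppression of degrees
with |H_l| below 10⁻³ of the maximum.  Output retains negative side-lobes;
oscillations shrink with statistics.  Per-imager images are combined as
Σ_i (I_i/ε_i)w_i / Σ_i w_i with Monte-Carlo field-of-view sensitivity maps
(isotropic point emitters on a lattice, direction set closed under the
z-flip so mirror imagers get exactly mirror maps) and the per-imager
efficiency scales.

## PET reconstruction

Accepted LORs are intersected with z = 0 (lines parallel to the plane or
crossing outside the extent are discarded, not clamped) and histogrammed
on the PET grid (300×300 mm², 700×700 px default), per spill phase (tagged
by the earlier hit).  Images are efficiency-corrected by pixelwise
division with a normalized MC pair-detection sensitivity map
(floor-thresholded at 8% of maximum — below that the correction amplifies
edge noise); the correction matters: without it the acceptance roll-off
compresses recovered range shifts by ~3×.

## Range metrics

* `weighted95`: intensity-weighted mean x of the pixels ≥ 95% of the
  masked maximum, restricted to the connected component containing the
  anchoring maximum (ties resolved toward the deepest pixel along the
  beam) — a secondary locus elsewhere cannot pull the average.  Error:
  weighted std of those pixels' x.
* `contour50`: mean x of pixels crossing half-maximum beyond the peak in
  the beam direction; membership is a 2% value band or a strict sign
  change between x-neighbours (a step between two columns contributes its
  midpoint).  Error: their x spread.
* `gaussfit`: Gaussian + baseline least squares on a 1D profile,
  covariance errors.
* `edgefit`: Gaussian-convolved step A/2·erfc((d−x)/(√2σ)) + b fitted to
  the distal region (windowed from just upstream of the profile maximum),
  d being the 50% fall-off.  The pipeline's PET fall-off estimate windows
  the fit around the half-maximum crossing and weights bins by their
  statistical errors — after efficiency division the bin variances differ
  by an order of magnitude, and an unweighted fit is dominated by the
  noisiest deep bins.  The erfc model is matched to the smeared-plateau
  profile; fitting it to a Gaussian-tailed profile is window-sensitive and
  magnifies shifts (measured 10–30% even noise-free), which is why the
  155 MeV scenario's β⁺ profile is a smeared plateau.

All estimators are shift-covariant and scale-invariant; negative pixels
from the analytic inversion are clipped to zero at the metrics boundary
(switchable).

## Sensitivity machinery

`variance_scaling_study` repeats an estimator over m disjoint (or
bootstrap, flagged) subsets per statistics level and reports box-plot
summaries with a bootstrap error on the std; pure counting statistics
predicts the spread ratio √10 ≈ 3.16 per tenfold statistics — the
"factor of approximately 3" law this package's acceptance target checks
(measured ≈ 3.2–3.5 at desk scale; the weighted-95% threshold selection
adds a little super-Poisson variance at low N).  `permutation_sensitivity`
forms all unordered pairwise |Δx_max|; its ECDF is the probability of
beating a target precision and q90 the inverse-ECDF (no interpolation,
smallest attained value with cumulative fraction ≥ 0.9) 90%-confidence
precision.  Defaults: m = 50 realizations per level (desk scale).

## Numerical and design choices

* Coincidence windows are closed; energy windows apply to detected
  (smeared) energies; scatter-before-absorber ordering is not enforced
  (symmetric window).
* Backprojection/inversion kernels are numba-accelerated with an exact
  numpy fallback; reduced band grids around the phantom (1 mm pixels) are
  used for the repeated-reconstruction studies, the full 1200² /700² FoVs
  for imaging.
* Scatter-to-absorber gap (not stated anywhere authoritative): default
  15 mm face-to-face, configurable.
* Transverse imager offsets default to 0 (centered on the beam height).
* Degenerate inputs: zero-width profiles produce point sources; empty
  phase selections give an empty image with a warning, not an error; an
  all-suppressed inversion filter raises a regularization error.

## Known limitations

* No attenuation, inter-imager scatter, randoms/pile-up, neutron or
  biological wash-out modelling; absolute efficiencies and count rates are
  out of scope.
* The four-imager stand-in geometry cannot see activity deeper than
  ≈ −85 mm, so the deepest graphite position (−120 mm) has PGI coverage
  but essentially no PET statistics (the analysis drivers report and skip
  it).
* The published experimental table values (absolute positions,
  14 mm @ 90% CL at 155 MeV) depend on the real data and full transport
  physics and are covered only by arithmetic consistency checks and
  qualitative orderings.
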