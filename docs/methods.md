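# Methods

## The staining model

Osmium tetroxide staining of aldehyde-fixed cortical punches is modeled as
four coupled processes on a 1-D depth axis `x` (mm, 0 at the cortical
surface, positive into the tissue): passive diffusion of free OsO4 into the
tissue, irreversible first-order binding to available sites, slow
free-osmium-dependent unmasking of additional sites, and isotropic tissue
expansion.  All tissue state variables are *projected* (areal) densities —
volumetric density times the local beam path length `d(x)` — because a
single-angle X-ray projection integrates along the beam.  A fifth variable
`o(x,t)` carries the solution osmium along the same beam outside the
sample, so the modeled projection intensity `F_I2C·(o + f + b)` can be
compared directly with measured, standardized absorbance.

Assumptions inherited by the implementation: the bath is an infinite
source at constant concentration; the punch is laterally homogeneous
(semi-infinite slab with the curved-cap thickness profile); binding and
unmasking are irreversible first-order reactions; expansion is isotropic
and monomolecular; secondary osmium sources (ventricles, axon tracts) and
washout chemistry are outside the model.

Initial and boundary conditions: `f(x>0,0)=0`, `b(·,0)=0`, `s(x,0)=S0·d(x)`,
`m(x,0)=M0·d(x)`, `o(x,0)=C0·(D−d(x))`; at the surface the fields are held
at `f=C0·R`, `b=s=m=0`, `o=C0·(D−R)` (Dirichlet), and at the maximum depth
`L` all gradients vanish.  The surface value `f(0,t)=C0·R` is adopted as
stated for the source data even though `d(0)=0` makes a thickness-weighted
reading of the same quantity vanish; the two readings differ only at the
single surface node and the fit domain starts at 100 µm.  The deep boundary
coefficient `B0` defaults to 0, the only value consistent with `b(·,0)=0`.

### Reaction coupling on volumetric concentrations

The bilinear rate terms are evaluated on volumetric concentrations:
`kon·s·f/d(x)` (projected) rather than `kon·s·f`.  This keeps the rate
constants geometry-independent and consistent with fitting volumetric
`S0`, `M0`.  Near the cap apex `d(x) → 0`, so `d` is floored at `d(Δx/2)`
(half a grid cell below the apex) to keep the division benign; the literal
projected-density product is available behind
`simulate(..., volumetric_reactions=False)` for comparison.

### Numerics

Method of lines on a uniform grid (default 301 nodes on [0, 3] mm):
second-order central differences for diffusion with a mirror ghost at `x=L`
(the trapezoid sum is then the discretely conserved quantity), first-order
conservative upwinding for the flux-form advection term, and LSODA with a
banded Jacobian (bandwidth 5 after per-node interleaving of the five
species), `rtol=1e−6`/`atol=1e−9` by default.  The conservation test suite
tightens to `rtol=1e−9`/`atol=1e−13`, at which the closed-system osmium
content is conserved to machine precision and the pointwise stoichiometric
invariant `s+m+b` drifts below 1e−14.  A full 22-hour simulation costs
~0.1 s, which is what makes the trust-region inverse fit (a few hundred
forward runs) interactive.

A resolution warning fires when `Δx > √(De·Δt_report)/4`; it is advisory
(the erfc oracle shows max error ≈ 3e−4 at the default grid).

## Intensity standardization

Raw transmission `w` becomes absorbance `u = full_scale − w`
(`full_scale = 10000`), is baseline-corrected with the solution window
−150…−50 µm (`u_b = u − b(t) − median_t(b)`), and standardized by the
affine map built from `b̄` (mean `u_b` over −200…0 µm), `m = 6420` and
`a = 0.61749`:

    u_min  = b̄ − ((1−0.9)/0.9)·(m − b̄)
    u_ref  = u_min − a·(m − u_min)
    u_norm = (1 + a)·(m − u_min)
    û      = (u_b − u_ref) / u_norm

This map pins the solution level at `û = (1+10a)/(10(1+a)) ≈ 0.4436`
independent of `b̄`, anchors saturated 2% staining near 0.9, and sends the
concentration–absorbance relation through the origin.  Dividing the pinned
solution level by `D·F_I2C` (25 mm, 214.6308) gives 82.7 nmol/mm³ — the
measured 2% OsO4 solution density — which is why the synthetic ground
truth uses exactly `C0 = 0.4436/(D·F_I2C)`: forward model, preprocessing
chain and `estimate_C0` are then mutually consistent by construction.

Two empirical constants (`a`, `m`) are calibration factors of the original
instrument and are configuration-overridable; no physical meaning is
claimed for `m = 6420` beyond its role in the affine map.

## Preprocessing chain choices

* **Registration** — translational jitter is estimated between
  *consecutive* frames by phase correlation on gradient-magnitude images
  and accumulated relative to the reference frame.  Consecutive frames are
  nearly identical, so the genuinely moving staining front does not bias
  the estimate, and the sharp static edges (punch sides, vial floor)
  dominate the gradient images.  Subpixel refinement by Fourier upsampling
  (1/20 px quantization).
* **Flat-field** — the quadratic log-intensity surface is fitted to the
  median of frames 2–5 by least *trimmed* squares (keep fraction 0.55,
  multi-start concentration steps).  The solution background is exactly
  log-quadratic under the cone-beam bias, so the trimmed fit locks onto it
  and extrapolates the bias across the sample footprint; an ordinary
  least-squares fit would absorb several percent of tissue structure into
  the correction.  The correction itself divides by `exp(Z)` and
  multiplies by `max(exp(Z))` (normalizing to the brightest illumination).
* **Surface tracking** — the sample surface is anchored in the frame with
  the strongest vertical edge and then tracked frame-to-frame within ±3
  rows, locating per frame the sub-pixel *onset* of deviation from the
  local solution level.  A plain max-gradient detector fails at the time
  when early staining exactly compensates the thickness contrast of the
  unstained cap (the edge contrast crosses zero); the onset estimator with
  temporal continuity rides through that crossover.  Frames where no onset
  is found within the window yield missing values, not failures.

## Synthetic recordings

The generator renders the scene the analysis assumes: a laterally uniform
punch (200 px wide at 20 µm pixels) with curved-cap thickness profile,
solution above, and a vial-floor/Sylgard band at the bottom that serves as
the stationary height reference; heavy-metal accumulation follows the
forward model; the sample height follows `H0·(1+g(t)/100)` rounded to
pixels; frames carry uniform integer stage jitter in [−5, 5] px, a
quadratic log-intensity bias normalized to unit maximum (a global gain is
`detector_full_scale`, not shading), sinusoidal baseline drift, and
additive Gaussian detector noise (shot noise optional, off by default —
the detector's noise statistics are not published, and Gaussian noise
suffices for recovery studies).  Acquisition is scaled down from the real
~1300 frames/22 h to a 5-frame dense burst at 0.5 min (the flat-field
step needs near-onset frames 2–5) followed by 30-min frames to 1234 min.

What the generator does *not* emulate — and what passing recovery tests
therefore do not demonstrate on real data: tissue heterogeneity (white
matter, vessels, secondary osmium sources), detector nonlinearity and
spectral hardening, rotation or focus drift, and lateral thickness
variation within the ±25 px averaging band.

## Inverse fit

Six parameters `(De, kon, kunmask, S0, M0, H)` are fitted by bounded
trust-region least squares on the domain x ∈ [100, 700] µm,
t ∈ [0, 1200] min; `De`, `kon`, `kunmask` are optimized in log10, the
linear parameters as-is; bounds default to `De ∈ [1e−5, 1e−1] mm²/min`,
rates ∈ [1e−2, 1e6] mm³/(mmol·min), `S0, M0 ∈ [0, 2e−3] mmol/mm³`,
`H ∈ [0.05, 1.5] mm`.  `C0` is estimated first from the solution window
(−150…−50 µm, t ≤ 1200 min) as `mean(û)/(D·F_I2C)`.  Forward runs are
memoized on the rounded parameter vector; simulator failures during a
candidate evaluation return a large residual instead of aborting the fit.
The fit targets the standardized `û`; fitting baseline-corrected `u_b`
instead is an affine rescaling absorbed by `F_I2C`.

Synthetic study conditions for recovery experiments (chosen once):
`De = 1e−3 mm²/min`, `kon = 500`, `kunmask = 15 mm³/(mmol·min)`,
`S0 = 3.53774e−4` (the fitted binding-site density 353.774 nmol/mm³),
`M0 = 1.2e−4 mmol/mm³`, `H = 0.5 mm`, `C0 = 8.267e−5 mmol/mm³`, growth
`a1 = 5.8697%`, `a2 = 5.6924%`, `τ = 588.23 min`.  These reproduce the
characteristic phenomenology: solution level 0.44, saturation plateau
approaching 0.85–0.9 with slow late rise from unmasking, binding fast
relative to diffusion.  Recovery fits run on a 151-node grid with profile
data every 20 µm / 30 min, sizes at which a self-fit costs a few seconds.

On real recordings the residual standard error is dominated by model error
(tissue heterogeneity), not detector noise; per-sample fits of the source
recordings report `SE_res = 0.026 ± 0.005`.  On synthetic data `SE_res`
estimates the injected noise scale, which is the property the tests assert.

## Front analysis and stoichiometry

The staining front at each time is the first depth, scanning inward from
the per-time intensity maximum (the stained plateau — this skips the
thin-cap dip at the surface), where `û` falls below a threshold (default
0.45, half the saturation anchor; the extraction criterion of the original
front measurements is not published, so the threshold is exposed in the
API), linearly interpolated between grid samples.  The penetration law is
fitted as `x = c·√t` or `x = c·t^p`; in the fast-binding limit the
simulated front yields `p ≈ 0.48` and `c ∝ √De` (log-log slope 0.499 over
a 10× sweep), the emergent form of the `t ∝ x²` protocol-scaling rule.

The stoichiometry accounting is rational arithmetic on literature inputs:
56,241 nmol/g phospholipid × 0.427 g / 508.91 mm³ = 47.19 nmol/mm³
(reported at 4 significant figures, and carried at that precision into)
× 2.5 double bonds/lipid = 117.975 nmol/mm³.  Against the fitted site
density 353.774 nmol/mm³ the ratio is 2.999 — three times more binding
sites than lipid double bonds, before any unmasking.

## Known limitations

* The û round trip through the full preprocessing chain is exact only for
  a static surface.  When the sample grows, tissue physically enters the
  fixed baseline window (−150…−50 µm above the *initial* surface) late in
  the experiment and biases `b(t)`; the same contamination affects real
  recordings with ~200 µm of expansion.  Height tracking, not the
  baseline, is the reliable readout of surface motion.
* The model is 1-D and homogeneous; agreement with real profiles degrades
  beyond ~700–800 µm depth where secondary sources contribute.
* `kunmask` and `M0` are the least identifiable parameters (their effect
  is a slow late plateau rise); noisy-data recovery errors of 10–25% are
  expected and observed.
* Washout (ferrocyanide), ferricyanide and formamide conditions are
  deliberately out of scope: no quantitative model exists for them.
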