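# Methods

## The summation template

Sensitivity is modelled as a smooth two-limb function of total retinal input.
Input and sensitivity are both handled in dB (10·log₁₀ units), so that a
change in RGC density is an additive shift on the input axis:

    u  = 10·log₁₀(area_deg² · duration_ms · density_poff · convergence)
    x  = u − 10·log₁₀ τ
    S(u) = 10·α + x − 10·(1 − 1/κ)·log₁₀(1 + 10^(x/10))

The local log-log slope decreases monotonically from 1 (complete summation,
`u ≪ τ`) to `1/κ` (partial summation, `u ≫ τ`); the transition is gradual,
so no single "Ricco's area" value is defined or reported. The template is a
function of `x = u − 10·log₁₀τ` only, which gives the exact identity
`S(u + Δ; α, τ) = S(u; α, τ·10^(−Δ/10))`: a horizontal shift of the curve and
a change of the transition input are the same thing. This shift-invariant
parameterization was chosen over the variant that adds `u` directly (they
differ by the reparameterization α → α + log₁₀τ) precisely because it makes
the horizontal-shift semantics of the H1 model exact by construction. The
absolute meaning of a printed α therefore belongs to the parameterization
it was estimated under.

Default parameters: α = 1.42, log₁₀τ = 3.58, κ = 2.59 (partial-summation
slope 0.39). Under the packaged physiological scales (parasol-OFF density
≈ 20–100 cells/deg², convergence ≈ 4–17 cones/RGC) these place the G-I
stimulus in complete summation and G-III–G-V in partial summation in the
healthy macula, with τ crossed between G-I and G-III — the configuration the
analysis depends on. A consequence of this form is that healthy sensitivities
sit at roughly 7 dB (G-I) to 24 dB (G-V) rather than at clinical Humphrey
values near 26–33 dB; the synthetic world is internally consistent (the
generator and every fit share the same template), but analysis parameters
defined on the clinical scale must be translated (see the structural-floor
threshold below).

### Calibration

`(α, log₁₀τ, κ)` are estimated by least squares on dB residuals with a
multistart Nelder–Mead simplex (objective tolerance 1e-8, ≥ 5 perturbed
starts, best objective kept). Censored rows are excluded (healthy data
contain few). Confidence intervals are percentile bootstrap over *eyes*
(not observations), preserving within-eye correlation; a parameter whose
95% interval is wider than 2 units is flagged weakly identified (κ when no
data lie on the partial limb). With heteroscedastic noise and the limited
input span of a small cohort, noisy calibration shows some downward bias in
κ and log₁₀τ; the noise-free recovery experiment isolates the optimizer,
which recovers the generating vector to well under 0.01.

## Structural RGC estimates

GCL thickness maps (µm, 0.2-deg raster, fovea-centred visual-field
coordinates) are converted pointwise to densities:

    total(x) = thickness_mm(x) · volumetric_density(ecc) · mm_per_deg(ecc)²
    poff(x)  = total(x) · poff_fraction(ecc)

All eccentricity profiles ship as editable CSV interpolation tables under
`maculasum/profiles/`. The packaged defaults are *synthetic plausible
curves* shaped to the documented qualitative contracts (volumetric density
peaks parafoveally; convergence non-decreasing within 10 deg; parasol-OFF
fraction in (0,1) rising with eccentricity; displacement positive,
continuous, zero beyond 4 deg, with slope > −1 so the radial map is
injective). For real analyses they should be replaced with histology-derived
tables; nothing downstream changes.

Stimulus footprints are displaced by moving every boundary vertex (≥ 64)
radially outward by d(ecc) — not just the stimulus centre — so footprints
near the fovea are distorted as well as moved. Counts are the integral of
the bilinearly interpolated density over the footprint polygon, computed by
a signed triangle-fan decomposition with a degree-5 Gauss rule per triangle.
The signed fan is valid for any simple polygon and the rule is exact for
constant and linear fields; this replaces raster-mask counting, which cannot
reach the 0.1% tolerance for the G-I footprint (radius 0.05 deg) at any
reasonable pitch. Everything is computed in visual degrees, so axial length
never enters.

## The synthetic cohort

The generator reproduces the study design: 29 young healthy eyes, 20
age-similar controls (GCL 6% thinner on average), and 10 glaucoma eyes per
severity stage; five stimulus sizes (0.10–1.72 deg, 200 ms) on the 68-point
10-2 grid (odd-integer coordinates with x² + y² ≤ 82); the young cohort
repeats G-I, patients and controls repeat G-III — six tests per eye. All
synthetic eyes use right-eye field coordinates; the importer mirrors real
left eyes once at load.

**Ground truth.** Each eye gets a healthy GCL profile (per-eye scalar scale
SD 5%) and, for glaucoma eyes, a multiplicative damage field in log₁₀ space:
a diffuse component (sum of broad Gaussian depressions) times one or two
sharp-edged arcuate scotomas (sigmoid of distance to a circular arc,
transition width 0.25 deg). Functional loss clamps at −30 dB of density (an
absolute scotoma); GCL thickness clamps at the residual fraction (default
0.15, ≈ −8 dB), reflecting non-functional residual tissue. The structural
round trip (thickness → density) therefore reproduces the functional truth
exactly wherever loss has not reached the floor.

**Severity calibration.** Each glaucoma eye draws a target MD uniformly
inside its stage's stratum (early −5.5..−1, moderate −11.5..−6.5, advanced
−22..−13 dB) and the damage field's overall severity multiplier is bisected
until the G-III MD summary (mean deviation from the eye's healthy baseline)
hits the target — stage membership holds by construction, which is the only
sense in which severity is "tuned".

**Per-stimulus effective densities.** The per-location density the
hierarchical model estimates is defined as the area-averaged P-OFF density
under the displaced G-III footprint. The generator, however, computes the
*true* threshold for each size from that size's own footprint average. Near
a sharp scotoma edge the G-V footprint summates intact retina that the G-III
footprint does not see, so large-stimulus sensitivities exceed what any
one-density-per-location model predicts — the edge-of-scotoma phenomenon the
evaluation stage flags.

**Noise and censoring.** Observed thresholds are the template prediction
plus Gaussian noise with SD(s) = min(8, 1.5 + 0.2·(30 − s)) dB, drawn
directly (no staircase simulation — the analysis consumes thresholds).
Draws ≤ 0 dB are recorded as 0 with the censored flag; values cap at a
40 dB ceiling, which is never binding in this world and is not modelled in
the likelihood. Because baseline sensitivities are low on this template's
scale, this noise model is relatively harsh: SD is already ≈ 4 dB at the
healthy G-III operating point. Two consequences are documented rather than
hidden: the G-V edge excess (≤ ~8 dB at a handful of border locations) is
largely masked under full noise, so the edge-clustering test isolates the
mechanism with noise-free perimetry; and calibration on noisy small cohorts
is visibly biased (above).

## The hierarchical censored model

Let s_{e,l,a,r} be the recorded sensitivity for eye e, location l, stimulus
a, repeat r, and let o_{l,a} = 10·log₁₀(area·duration·convergence) be the
fixed part of the input.

* **H1 (horizontal, hierarchical density).** d_{e,l} = μ_pop + b_e + b_{e,l}
  with b_e ~ N(0, σ_eye²), b_{e,l} ~ N(0, σ_loc²); expected sensitivity
  T(o + d_{e,l}) + v_pop with a single population-level vertical offset.
* **H2 (vertical, hierarchical offset).** v_{e,l} = ν_pop + c_e + c_{e,l};
  expected sensitivity T(o + δ_pop) + v_{e,l} with a single population-level
  horizontal (density) shift.

Fitting both shifts hierarchically is rejected as unidentifiable: at a
location whose tested sizes all lie on one limb, vertical and horizontal
shifts trade off freely. Uncensored rows contribute the Gaussian density at
the observation; censored rows contribute log Φ((0 − μ)/σ) — the Tobit
lower-tail mass — which removes the upward bias of treating floored values
as exact. Censoring is *one-sided* information: at a fully censored
location the posterior is bounded above (below the density at which the
largest stimulus reaches 0 dB) but relies on the hierarchy below, so its
mean generally sits above a truth lying at the −30 dB functional floor.
The honest guarantee, and the one tested, is that the censored likelihood
estimates strictly less than a naive fit treating recorded zeros as exact.

Priors (weakly informative, all in dB): μ_pop ~ N(healthy structural mean,
10); v_pop, ν_pop ~ N(0, 5); σ_eye, σ_loc, σ_noise ~ Half-Normal(5).
Residual noise is a single homoscedastic σ_noise by default; a
heteroscedastic variant (SD scaled by a capped linear function of the
predicted sensitivity, mirroring the generator's shape) is available via
`HierarchicalModelSpec(heteroscedastic=True)` and reduces the small
population-level offset distortion that heteroscedastic data induce in the
homoscedastic fit.

**Sampler.** Adaptive Metropolis-within-Gibbs, exploiting that location
effects are conditionally independent given eye effects and hyperparameters
(and eye effects given hyperparameters): each sweep makes one vectorized
element-wise proposal/acceptance pass over all location effects, one over
all eye effects, random-walk updates of the scalars and log-SDs, plus three
mixing moves that are essential in the centered parameterization: a
likelihood-invariant translation between the hierarchical scalar and the
eye effects, a per-eye translation between eye and location effects, and a
slope-compensated joint move along the horizontal/vertical trade-off
direction (compensation slope fixed from the data at the prior mean, so the
proposal stays symmetric). Proposal scales adapt toward 44% acceptance
during warmup only. Defaults: 4 chains × 1000 warmup + 1000 kept; split
R-hat and ESS from ArviZ with a convergence gate at 1.05 — an unconverged
fit is returned with a warning, never silently. All draws are deterministic
given the seed. A gradient-based sampler would mix faster per sweep, but
the block structure keeps this scheme well within desk-scale budgets
(a 8-eye study fits in a few seconds).

Reported density summaries are posterior means/SDs per location in dB
(horizontal shifts are additive there) with a log₁₀ convenience column.
Posterior predictions are per-row posterior means of T(o + H) + V and are
*not* censored — they may be negative.

## Evaluation

* **R²/RMSE** on recorded sensitivities, excluding the young calibration
  cohort. Censored handling is explicit: the default "recorded" mode clamps
  predictions at the censoring limit (comparing on the device's recorded
  scale); "exclude" and "raw" modes are available. The raw mode penalizes
  exactly the model that correctly infers deeply negative sensitivities at
  censored locations, which is why it is not the default.
* **Model comparison**: paired bootstrap resampling subjects (B = 1000),
  percentile CIs for each RMSE, percent RMSE reduction, and a two-sided
  bootstrap p-value for the difference.
* **Dynamic range**: 1st–99th percentile width of the dB density estimates,
  computed per eye and averaged (a pooled variant is a one-liner on the same
  table). Under the residual-tissue floor the structural/functional ratio
  falls far below 1 and shrinks from early to advanced disease; it is not
  monotone across *healthy* groups because healthy functional estimates are
  noise-broadened while healthy structure is not.
* **Edge flags**: threshold at the 97.5th percentile of the G-V prediction
  error; locations above it are flagged (underpowered below 40 rows, still
  computed). Censored G-V rows should be excluded by the caller — a 0 dB
  recording minus a deeply negative prediction is a censoring artifact, not
  a prediction error.
* **Structure-function**: RMSE of sensitivities predicted from structural
  densities through the template; the same restricted to locations with
  preserved G-I sensitivity; and structural-vs-functional density RMSE in
  dB. The preserved-G-I threshold defaults to the clinical 10 dB; for the
  synthetic world `gi_floor_threshold()` computes the equivalent cut as the
  midpoint between the median healthy and median floored G-I sensitivity
  (≈ 4 dB under defaults).

## Problem sizes used by the test suite

The suite runs the full pipeline at reduced scale as a design choice that
keeps every check exact in kind: 8-eye studies (1 young / 1 control / 2 per
stage), 2 chains × 250–400 warmup and kept draws, 20 replicate studies per
generating hypothesis for the model-selection property, B = 30–500 bootstrap
replicates, and 10⁶-draw Monte-Carlo oracles for the censored tail.

## Known limitations

* The template parameterization fixes a vertical-offset convention; printed
  α values from other parameterizations are not directly comparable.
* The synthetic world's sensitivity scale is compressed relative to clinical
  perimetry (see above); clinical-scale analysis constants must be
  translated, and two spec-level behaviours (edge-flag clustering under full
  noise; sub-floor unbiasedness at fully censored locations) hold only in
  the qualified forms documented here.
* Histology profile tables are synthetic defaults, not digitized curves.
* The MD summary is a G-III mean-deviation summary statistic on the 10-2
  grid, not a normative-database 24-2 MD.
* Fixation losses, false positives/negatives, staircase dynamics and
  response-time behaviour are not simulated.
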