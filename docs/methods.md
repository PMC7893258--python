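# Methods

`whalebody` implements a two-channel analysis of lipid-store body condition
in free-ranging baleen whales: tissue body density (TBD) estimated from the
hydrodynamics of stroke-free glides recorded by animal-borne tags, a
length-standardized surface area index (LSSAI) from overhead outline
measurements, and a hierarchical Bayesian model that fuses both channels
into a latent per-whale "underlying" tissue body density (uTBD) with
life-history covariates.

## The hydrodynamic glide model

During a glide, the along-path acceleration of the body is

    a = -1/2 (C_D A / m) ρ_sw v²
        + (ρ_sw / ρ_tissue(d) - 1) g sin p
        + (V_air / m) g sin p (ρ_sw - ρ_air (1 + 0.1 d)) / (1 + 0.1 d)

with tissue density compressed hydrostatically,

    ρ_tissue(d) = ρ_tissue(0) / (1 - r (1 + 0.1 d) · 101325).

Hydrostatic pressure is approximated as (1 + 0.1 d) atmospheres and
converted to Pa by the factor 101 325; diving air follows Boyle's law.  The
formula is implemented literally, which means one atmosphere of compression
is already applied at d = 0: ρ_tissue(0) is a zero-pressure reference
density, about 0.04 kg m⁻³ below the at-surface value at the default
compressibility.  Parameters and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| ρ_tissue(0) | non-gas tissue density | kg m⁻³ | estimated; uniform prior on [800, 1200] |
| C_D·A·m⁻¹ | combined drag term (not separable) | m² kg⁻¹ | estimated; Normal(11×10⁻⁶, 5×10⁻⁶) truncated > 0 |
| V_air·m⁻¹ | diving air volume per mass | m³ kg⁻¹ | estimated; uniform prior on [0, 2×10⁻⁴] |
| r | tissue compressibility | Pa⁻¹ | fixed 0.38×10⁻⁹ |
| g | gravity | m s⁻² | 9.8 |
| ρ_air | surface air density | kg m⁻³ | 1.225 (not estimated; scaled by pressure in the air term) |

The drag prior mean corresponds to the lift-induced drag expected for a
large-flippered whale gliding at moderate pitch; its SD (5×10⁻⁶ m² kg⁻¹,
weakly informative) is a package choice.

## Glide extraction from tag records

The dominant stroke frequency of a deployment is taken from the spectral
peak of the dorsoventral acceleration channel.  The channel is high-pass
filtered (4th-order Butterworth, zero phase) at 0.4× that frequency; an
amplitude envelope is a centred moving maximum over half a stroke period
(|signal| peaks every half cycle, and a wider window dilates stroke bouts
into adjacent glides).  A sample is "stroking" when the envelope exceeds

    threshold = min( 5 × MAD(filtered),  0.5 × 95th-percentile envelope ).

The MAD term is the classical sparse-signal noise floor; the cap handles
records where stroking dominates, in which case the MAD reflects stroke
amplitude itself and an uncapped threshold would sit above the signal.
Stroke-free runs of at least 5 s are glides; each is tiled into
non-overlapping 5 s segments from its start (remainder discarded).  Per
segment, acceleration is the OLS slope of speed on time (with its standard
error), and depth/pitch/speed are segment means; seawater density is
interpolated linearly from the CTD profile at the segment's mean depth
(constant extrapolation beyond the cast).  When no propeller speed channel
exists, speed is |depth rate / sin pitch|, and segments with |mean pitch|
below a configurable floor (default 30°, bounding the 1/sin error
inflation) are dropped and logged.  Both descent and ascent glides are
used.  Whales with fewer than 10 glide segments are excluded.

Boundary precision of detected windows is limited by the filter transient
and the envelope window to roughly one stroke half-period (≈ 1 s at the
synthetic defaults), not by the detector logic.

## Bayesian estimation and model comparison

Glide observations enter a Gaussian likelihood: observed acceleration ~
Normal(model prediction, sd), where sd is either the per-segment regression
SE (default; floored at 10⁻⁴ m s⁻² so the noise-free limit stays proper) or
a single estimated σ_a added in quadrature (half-normal(0.1 m s⁻²) prior).
Tissue density and drag can each be per-whale ("individual") or shared
("global"); the air volume can be global or per-dive with a hierarchical
normal mean.  Structures are compared by DIC with the classical effective
parameter count p_D = mean deviance − deviance at the posterior mean; ties
break toward fewer parameters and non-converged candidates are excluded.

Sampling uses an adaptive Metropolis-within-Gibbs scheme written for this
package (`whalebody.mcmc`): componentwise Gaussian random-walk updates with
per-coordinate step adaptation toward 44% acceptance during burn-in (frozen
afterwards), a vectorized elementwise sweep for blocks of conditionally
independent latents, and an optional Haario-style joint update with
adapted covariance for correlated coefficient blocks.  Defaults are 3
chains × 20 000 iterations, 50% burn-in, convergence declared at split-R̂
< 1.05; non-convergence is warned, never silent.  All draws derive from a
single seed.  A brute-force least-squares grid search over
(ρ_tissue, drag) with the air volume held fixed serves as an independent
check of the sampler, and the sampler itself is validated against closed
form Gaussian targets and an independent ensemble sampler in the tests.

## LSSAI from outline widths

An outline is the total length L (rostrum tip to fluke notch, pixels) and
the body width at 21 equally spaced section boundaries.  Section i
(spanning ((i−1)·5%, i·5%] of length) is a trapezoid with parallel sides
w_{i−1}, w_i and height L/20; its length-standardized projected area is
PA = (B/L + b/L)(h/L)/2.  LSSAI sums PA over sections 7–17 inclusive
(30–85% of body length), the mid-body region where whale-to-whale variance
concentrates.  Dividing every dimension by L makes the index invariant to
image scale, altitude and camera geometry, so no ground-sampling-distance
correction is applied.  When several frames of a whale exist, the frame
with the best mean quality score (posture, brightness, submergence, each
1–3) is used; ties go to the earliest frame.  Widths missing inside
sections 7–17 are an error — no imputation.  A rasterized filled-polygon
oracle (pixel counting at ≥ 2000 px body length) reproduces the trapezoid
sum within 1% and converges to it with resolution.

## The fusion model

Each whale j has a latent uTBD_j observed through two channels:

    uTBD_j ~ Gamma(mean μ_j, shape k),  log μ_j = x_jᵀ β
    TBD_jg ~ Normal(uTBD_j, sd_jg)          (sd supplied per observation)
    LSSAI_j ~ Normal(α + γ uTBD_j, σ_L)     (α, γ, σ_L estimated)

The default linear predictor is intercept + location + day/100 +
location×day/100 + sex (male, unknown; female reference) + pregnant +
lactating + immature.  The location×day interaction is included because an
early-season location contrast that vanishes late in the season requires
one.  The season-day axis is Julian day with days < 100 shifted +365, so a
November–January field season is monotone.  Factor levels supported by
fewer than two whales are dropped (coefficient fixed at 0) with a warning;
with no LSSAI observations anywhere the link parameters are dropped and the
model reduces to a Gamma regression on the TBD channel (checked against a
statsmodels Gamma GLM in the tests).

Priors: β₀ ~ Normal(log 1037, 0.05); other β ~ Normal(0, 1);
k ~ half-normal(5×10⁵); α, γ weakly informative normals; σ_L ~
half-normal(0.05).  The shape scale admits the k ≈ (μ/σ)² ~ 10⁵ implied by
residual whale-to-whale spreads of ~2 kg m⁻³ at μ ≈ 1037.  Two internal
reparameterizations aid mixing without changing the model: covariate
columns are mean-centred (undone at reporting), and the LSSAI link is
written α_c + γ(u − 1037) with α = α_c − 1037γ reported.

Effects are reported on the response scale as exact contrasts at the
reference covariates (Canada, adult resting female, day = first sampling
day): effect = exp(β₀ + β) − exp(β₀) per draw, summarized by posterior
mean ± sd.  Missing channels are predicted from the posterior: the latent
uTBD_j for the TBD channel, α + γ·uTBD_j plus σ_L noise for LSSAI; whales
not in the fit are predicted through the Gamma regression from their
covariates.

## Density to lipid fraction

An affine map through two published (density, lipid fraction) anchor pairs,
(1037.0 kg m⁻³, 0.363) and (1031.2 kg m⁻³, 0.390), converts tissue density
to an approximate lipid-store proportion (slope ≈ −0.00466 per kg m⁻³).
This is a declared, species-extrapolated stand-in for an isotope-dilution
calibration whose functional form is not published; it reproduces the two
independently published check pairs (33.4% at 1043.2, 36.5% at 1036.5) to
printed precision, and warns outside 1000–1070 kg m⁻³.

## Synthetic data: what it emulates, and what it does not

The generators produce data with exactly the statistical structure the
models assume, under study-calibrated conditions:

* **Glides** — depths uniform on 10–120 m (shallow humpback feeding
  dives), |pitch| truncated-normal with mean 49.1° and SD 13.7° (the
  observed glide pitch statistics), speed lognormal around 1.5 m s⁻¹,
  acceleration = forward model + Normal(0, 0.01 m s⁻²) by default.
* **Tag records** — V-shaped dive legs at ±49.1° pitch, a 0.4 Hz stroking
  sinusoid on the dorsoventral channel, stroke-free windows planted at
  known times with linear speed ramps whose slope is the forward-model
  acceleration at window-centre conditions (quasi-static), and depth
  integrated as dz/dt = −v sin p, so the kinematics are self-consistent.
* **Outlines** — a humpback-like width template (peaking mid-body) scaled
  exactly to a target LSSAI, with optional multiplicative shape noise that
  concentrates variance mid-body.
* **Populations** — 93 whales by default, of which 59 carry the TBD
  channel, 55 LSSAI and 21 both (study-like missingness); covariate
  effects calibrated to −3.5 (pregnant), +6.0 (lactating), +5.3
  (Norway early) kg m⁻³ and −2.7 kg m⁻³ per 100 days; Gamma shape 2.7×10⁵
  (residual spread ≈ 2 kg m⁻³, matching the published within-group
  late-season SDs of 1.8–2.2 kg m⁻³); per-whale TBD observation SD
  uniform on 1–5 kg m⁻³, the reported range of tag-posterior spreads.

Every generator is seed-deterministic and emits a machine-readable truth
record; recovery tests read truth only from it.  What the generators do
*not* emulate: real stroke-and-glide gait transitions and propulsive
hydrodynamics, depth-varying stroke frequency, outline annotation error
from posture or refraction, non-Gaussian acceleration noise, and covariate
confounding beyond what the design encodes.  Passing recovery tests
therefore show the estimators are correct and well calibrated *under the
assumed model*, not that the model captures every feature of field data.

## Numerical choices and problem sizes

Acceleration SEs are floored at 10⁻⁴ m s⁻²; the grid oracle is conditioned
on the fitted air volume when compared with the MCMC optimum (the two
parameters are correlated with V_air, so both routes must optimize the
same pair); DIC deviances are computed on a ≤ 500-draw posterior
subsample.  The verification runs use 3 chains of 2 500–3 000 iterations
for the 3-parameter glide fits (split-R̂ typically < 1.03; 50 replicate
fits of 200 glides complete in ~2 minutes) and 12 000 iterations for the
106-dimensional fusion posterior (split-R̂ < 1.05 in ~30 s); the
package default of 20 000 iterations is conservative for production use.

## Known limitations

* ρ_tissue(0) is a zero-pressure reference by construction of the printed
  compression formula; at-surface density differs by ~0.04 kg m⁻³.
* The drag term, air volume and tissue density are mutually correlated in
  the likelihood; with depth spans much narrower than 10–120 m the air
  volume (and with it, density) becomes weakly identified, as does density
  when all glides are near-horizontal (both conditions are warned).
* The lipid conversion is an affine extrapolation across species; it is an
  index, not a measurement.
* Detected glide-window boundaries carry ~1 s uncertainty from filtering;
  segment statistics are insensitive to this at 5 s tiling.
* The fusion model treats each whale's TBD channel as a single summary
  observation by default; a per-glide-segment observation list is
  supported through `WhaleRecord.tbd_obs` but per-segment error
  correlations are not modelled.
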