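# whalebody

Lipid-store body condition of free-ranging whales, estimated two
independent ways and fused into one latent state.

Baleen whales finance migration and breeding from lipid reserves built up
on their feeding grounds, and because lipid (~920 kg m⁻³) is far less
dense than lean tissue (~1060 kg m⁻³), a whale's **tissue body density
(TBD)** is a direct index of its energy stores.  This package implements,
for biologging and photogrammetry practitioners:

* **Glide hydrodynamics** — extract stroke-free 5 s glide segments from
  tag records (depth, pitch, dorsoventral acceleration, speed) and fit the
  glide force balance by MCMC to estimate TBD, the combined drag term
  C_D·A·m⁻¹ and the diving air volume V_air·m⁻¹, with individual-vs-global
  parameter structures compared by DIC:

      a = −½ (C_D A/m) ρ_sw v² + (ρ_sw/ρ_tissue(d) − 1) g sin p
          + (V_air/m) g sin p (ρ_sw − ρ_air(1+0.1d)) / (1+0.1d)

* **Photogrammetry** — compute the length-standardized surface area index
  (LSSAI) from overhead outline widths: trapezoid areas of 20 body
  sections, summed over mid-body sections 7–17 and standardized by body
  length (fatter whales project a larger area for their length).

* **Fusion** — a hierarchical Bayesian model in which each whale's latent
  "underlying TBD" follows a log-linear Gamma regression on location,
  feeding-season day, sex and reproductive status, observed through the
  TBD channel (known per-observation error) and the LSSAI channel (linear
  link with estimated intercept, slope and error).  Whales with either
  channel inform the covariate effects; missing channels are predicted.

* **Composition** — an approximate, species-extrapolated affine conversion
  from tissue density to lipid-store fraction.

* **Synthetic data** — seeded generators for every input (glides, tag
  time series, outlines, CTD profiles, whale populations) calibrated to
  the study conditions, each with a machine-readable truth record.

The two Bayesian models are scikit-learn-style estimators
(`TissueDensityModel`, `UtbdModel`: `fit`, `predict`, `get_params`,
fitted attributes with trailing underscores).

## Worked example

Simulate glides for one whale from the forward model and re-estimate its
tissue density:

```python
import numpy as np
from whalebody import HydroParams, TissueDensityModel, ModelStructure
from whalebody.synthetic import GlideSimConfig, simulate_glides

cfg = GlideSimConfig(
    params={"w0": HydroParams(tissue_density=1036.0, drag_term=12e-6,
                              air_per_mass=3.73e-5)},
    n_glides=200, noise_sd=0.01,
)
glides, truth = simulate_glides(cfg, seed=11)
model = TissueDensityModel(structure=ModelStructure(), n_iter=3000, seed=5)
model.fit(glides)
print(model.tissue_density_[["whale_id", "rho_tissue_mean", "ci_lo", "ci_hi"]])
```

prints

```
  whale_id  rho_tissue_mean        ci_lo        ci_hi
0       w0      1036.265599  1035.849739  1036.675580
```

i.e. the posterior mean recovers the generating density (1036.0 kg m⁻³)
within 0.3 kg m⁻³ and the 95% credible interval covers it.  The bundled
21-whale comparison table cross-validates the two channels:

```python
from whalebody import correlate_channels
from whalebody.datasets import tagged_whale_records

r, p = correlate_channels(tagged_whale_records())
print(f"r = {r:.2f}, p = {p:.4f}")   # r = -0.48, p = 0.0267
```

— whales that look fatter from the air (larger LSSAI) have lower
tag-estimated tissue density, i.e. larger lipid stores.  Converting the
densities of a whale sampled twice in one season:

```python
from whalebody import lipid_fraction
print(f"{lipid_fraction(1037.0):.3f} -> {lipid_fraction(1031.2):.3f}")
# 0.363 -> 0.390  (lipid fraction rising as the whale fattens)
```

A command-line interface mirrors the library
(`whalebody simulate|extract-glides|fit-density|lssai|fit-utbd|lipid|run-all`);
`whalebody run-all --seed 1 --out results/` runs the full synthetic
pipeline end to end.

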