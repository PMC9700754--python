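# rseikit

Ecological-quality monitoring from gridded remote-sensing products:
construction of the **remote sensing ecological index (RSEI)**, five-grade
classification and multi-epoch change detection, and attribution of the
index's spatial differentiation to natural and social covariates with the
four **geodetector** statistics.

The package is aimed at spatial ecologists and remote-sensing analysts who
want a tested, scriptable version of this widely used workflow — plus a
synthetic-landscape generator with analytically known ground truth, so every
stage can be validated without downloading satellite products.

## The model

Four per-pixel indicators summarize ecological condition:

- **greenness** — NDVI;
- **wetness** — tasseled-cap wetness,
  `Wet = 0.1147·Red + 0.2489·NIR1 + 0.2408·Blue + 0.3132·Green − 0.3122·NIR2 − 0.6416·SWIR1 − 0.5087·SWIR2`
  (MOD09A1-style band order);
- **heat** — daytime land surface temperature;
- **dryness** — `NDBSI = (SI + IBI)/2`, the mean of the bare-soil index SI
  and the index-based built-up index IBI.

Open water is removed with an MNDWI mask (`(Green − SWIR1)/(Green + SWIR1) >
0`), each indicator is standardized to zero mean and unit variance
(`y = (x − x̄)/s`), and PCA is run on the 4×4 correlation matrix (KMO and
Bartlett sphericity diagnostics included).  The first principal component is
sign-oriented so greenness loads positively, then min–max rescaled to [0, 1]:
that is the RSEI.  It is graded at 0.2 intervals into poor / fair / moderate
/ good / excellent, and epochs are compared by the sign of the grade change.

Attribution uses point samples on a regular lattice (default spacing 1200 map
units).  Continuous covariates are discretized with exact Fisher–Jenks
natural breaks (default 11 classes); land cover passes through as IGBP
codes.  For a stratification *h = 1…L* of *N* samples, the factor detector is

    q = 1 − Σ_h N_h σ_h² / (N σ²),

the share of response variance explained by the strata (population
variances, so q = SSB/SST exactly).  The interaction detector types the
overlay q₁₂ of two stratifications against q₁, q₂ (non-linear reduction →
non-linear enhancement); the risk detector compares stratum means with
Welch t-tests; the ecological detector compares two covariates' within-strata
sums of squares with an F-ratio.  Significance of q uses a seeded permutation
test by default (a noncentral-F approximation is available).

## Worked example

```python
import numpy as np
from rseikit import SimConfig, simulate
from rseikit.pipeline import epoch_products, detect_factors
from rseikit.geodetector import grid_sample
from rseikit.raster_core import RasterStack

sim = simulate(SimConfig(seed=7))          # 150x150 landscape, 500 m cells
prod = epoch_products(sim)                 # indices -> mask -> PCA -> RSEI
pca = prod["pca"]
print(round(pca.kmo, 3), f"{100*pca.contribution_rates[0]:.1f}%")
print(np.round(pca.eigenvectors[:, 0], 3))

stack = RasterStack(list(sim.covariate_grids.values()), list(sim.covariate_grids))
samples = grid_sample(prod["rsei"], stack, 1200.0)
kinds = {s.name: s.kind for s in sim.config.covariates}
print(detect_factors(samples, kinds, reps=199, seed=7)["factor"]
      [["factor", "q", "p_value"]].round(4).to_string(index=False))
```

prints

```
0.771 98.8%
[ 0.5  0.5 -0.5 -0.5]
     factor      q  p_value
        fvc 0.3780    0.005
 nightlight 0.2289    0.005
   rainfall 0.2063    0.005
    landuse 0.0961    0.005
 popdensity 0.0347    0.005
temperature 0.0323    0.005
```

KMO = 0.771 (> 0.5, adequate for PCA); PC1 carries 98.8% of indicator
variance with the expected sign pattern (greenness and wetness positive,
heat and dryness negative).  The factor-detector table ranks fractional
vegetation cover first (q̂ = 0.378 against an analytic q_true of 0.366 for
this seed's landscape), with every permutation p-value at its 199-replicate
floor of 1/200.

The same analysis runs from the shell:

```sh
rseikit run-all --seed 7 --out run/    # simulate -> RSEI -> grades -> detectors
rseikit simulate --seed 7 --out sim/   # or stage by stage: indices, rsei,
rseikit indices --red sim/band_red.tif ... --out-dir idx/
```

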