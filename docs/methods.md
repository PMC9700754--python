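# Methods

## Data model and conventions

All rasters are single-band, north-up grids with square cells on one shared
projected CRS; pixel (0, 0) is the north-west corner, a cell value refers to
the whole cell, and point-in-cell tests use half-open intervals
`[x, x+cell) × (y−cell, y]`.  Missing data are NaN in memory and a finite
sentinel (−9999 by default) on disk; nodata cells never enter any statistic.
GeoTIFF georeferencing travels in the ModelPixelScale/ModelTiepoint tags plus
the GDAL nodata tag, with the CRS label in the image description.
Reprojection between CRSs is out of scope — inputs must arrive in one CRS.
Resampling offers nearest (source cell containing the target cell centre)
and mean-aggregate (mean of source cells whose centres fall in the target
cell, nodata ignored); mean-aggregate conserves the global mean exactly when
the target tiles the source.  Multi-date stacks reduce to a per-pixel median
after QA rejection (nonzero mask = reject); an even survivor count takes the
midpoint of the two central values, and all-rejected pixels become nodata.
QA bit decoding is deliberately not implemented: any precomputed reject mask
is accepted.

## Indicators

Wetness uses the tasseled-cap coefficients for seven-band MODIS-style
surface reflectance exactly as printed in the package docstrings.  SI, IBI,
NDBSI, and MNDWI are normalized-difference forms; every zero denominator
(including IBI's sub-ratios) yields nodata rather than ±inf, and nodata in
any input band propagates.  Where an index formula says "NIR" without
qualification we use NIR1 (the ~858 nm band, MODIS band 2); this is an
argument (`nir=`) on the SI/IBI functions.  The water mask defaults to
MNDWI > 0, the standard cut-off, applied after compositing and before
standardization; the threshold is configurable.  Fractional vegetation cover
uses the dimidiate pixel model with the bare-soil/full-vegetation endmembers
at the 5th/95th percentiles of valid NDVI (a common convention; the model
itself does not fix the cut-offs), clipped to [0, 1].

## RSEI

Standardization uses the sample standard deviation (n−1).  PCA is an
eigen-decomposition of the correlation matrix of the four standardized
indicators — identical to covariance PCA on such data, which the tests
assert.  Components are ordered by descending eigenvalue; each eigenvector is
canonicalized so its first non-negligible component is positive, which also
breaks eigenvalue ties (within 1e−12) deterministically.  The RSEI is the
min–max rescaled PC1 score with the component oriented so the NDVI loading
is positive (tie-break: NDBSI loading non-positive).  This orientation rule
reproduces the expected sign pattern (+ greenness, + wetness, − heat,
− dryness) whenever the indicators actually share a quality axis.  Rescaling
uses the epoch's own valid-pixel min/max: each epoch's map spans [0, 1]
(per-epoch normalization; a pooled multi-epoch rescale would preserve
between-epoch level differences but is not what per-year mapping does — the
choice is per-epoch, and deliberate).  The contribution-rate-weighted
multi-component composite is provided as an explicit alternative
(`composite_index`); with m = 1 it ranks pixels identically to the RSEI.

KMO uses partial correlations from the inverse correlation matrix; Bartlett's
sphericity statistic is −(n−1−(2p+5)/6)·ln det R with p(p−1)/2 degrees of
freedom.  Both are computed on the pixel sample actually entering PCA.

## Grading and change

Grades cut [0, 1] at 0.2 intervals, left-closed/right-open with the top bin
closed, so 1.0 is "excellent" and every value receives exactly one grade
(printed grade tables usually show overlapping endpoints; this closure is a
documented choice).  Values outside [0, 1] beyond 1e−9 are an error.  Area is
valid-pixel count × cell area; polygon membership is by pixel centre.
Change between epochs is the sign of the grade difference — three classes
(improved/unchanged/declined), matching how multi-year comparisons are
reported — and is antisymmetric under epoch swap by construction.

## Geodetector

Variance conventions: inside q and the ecological F, stratum variances are
population variances (÷N_h), making Σ N_h σ_h² the exact within-stratum sum
of squares and q = SSB/SST an identity; the risk detector's Welch t-tests
use sample variances (÷(n_h−1)), as standard.  The printed risk-detector
formula divides the variance of the stratum mean by n_h a second time; we
read that as a typo and use the conventional Welch statistic with
Welch–Satterthwaite degrees of freedom.  Pairwise risk decisions are
reported both raw (the default, at 95% confidence) and Holm-adjusted.

Significance of q defaults to a seeded permutation test (shuffle stratum
labels, recompute q, upper-tail proportion with add-one smoothing):
transparent and assumption-free.  The noncentral-F approximation used by the
reference geodetector software is available as an explicitly labelled
alternative (`method="noncentral-F"`); neither is asserted to be what any
particular software reports.  The ecological detector's F is compared
two-sidedly against F(N₁−1, N₂−1) so the decision is invariant under
exchanging the covariates (F ↦ 1/F).

Interaction typing checks independence first (|q₁₂ − (q₁+q₂)| ≤ 1e−12), then
the strict inequalities; boundary cases q₁₂ = min or max fall into the
adjacent reduction class.  This makes the assignment total and exclusive,
which the tests sweep over a 50³ lattice.

Natural-breaks discretization is an exact Fisher–Jenks dynamic program
(minimum within-class SS over contiguous classes of the sorted values),
implemented here because no installed package provides it; the test suite
checks it against exhaustive search on 500 small instances.  Breaks are the
class maxima; a value equal to a break belongs to the lower class.  Above
6,000 points the optimization runs on an evenly spaced subsample of the
sorted values and applies the resulting breaks to all data — boundary
assignments can then differ from the exact optimum, but the lattice samples
the detectors consume are below that size, where the program is exact.
Continuous covariates default to 11 classes; categorical covariates pass
their codes through.

Sampling places lattice points at origin + spacing/2 + k·spacing (cell-centre
anchoring, configurable in principle via the grid origin); default spacing is
1200 map units.  "Abnormal" rows — any nodata, or a response outside [0, 1]
— are dropped; no other outlier rule is applied.

## Synthetic landscapes

The generator emulates the structure the pipeline assumes, not radiometric
realism.  Each covariate's strata are contiguous quantile bands of an
independent smooth Gaussian random field (white noise convolved with a
Gaussian kernel, length scale 12 cells by default, re-standardized), so that
coarse lattice sampling still sees every stratum.  Stratum effects are a
linear ramp scaled to the covariate's variance budget (land cover uses a
fixed class-effect pattern with wetlands highest and urban lowest).  The
latent quality field is the standardized sum of all contributions plus iid
pixel noise; the default budget is fvc 0.30, rainfall 0.18, nightlight 0.10,
temperature 0.08, land use 0.07, population density 0.06, residual 0.21.
Because the auxiliary fields are smooth and finite, realized stratum maps
correlate across covariates; the reported q_true values are therefore
computed exactly from the realized maps —
q_true = SSB(m)/(N·Var(m) + N·σ²_ε) with m the noiseless composite — rather
than from the nominal budget, and q̂ estimates them without bias.

Indicators are loading·latent + iid noise (defaults +1.0, +0.7, −0.9, −0.8;
noise sd 0.05) mapped to plausible scales (NDVI around 0.5, LST around
302 K).  The seven bands are linear in the probit-rank of the latent field
with small noise (sd 0.004), chosen so wetness rises and SI/IBI fall with
quality and land MNDWI stays negative with a wide margin; band-derived
indices therefore correlate with the direct layers (|r| > 0.9 is the
contract — exact inversion of IBI is over-determined, so approximation is by
design).  A contiguous water body (default 3% of cells, the top quantile of
another smooth field) carries a water band signature (MNDWI > 0) and
consistent direct-indicator values (wet, cool, vegetation-free).

Continuous covariate rasters place stratum h's values in a cluster occupying
half of its unit slot, leaving gaps equal to the cluster width, so
natural-breaks discretization at k = L recovers the generating strata
exactly (verified in the exact-optimization regime).  All randomness flows
from one root seed through `numpy.random.SeedSequence.spawn`, making output
byte-identical under a fixed seed.

What passing these tests does **not** show about real data: real indicator
noise is spatially structured and non-Gaussian, real covariates are not
cleanly separable clusters (so Jenks classes are a modelling choice, not a
recovery), MODIS QA structure and gridding artifacts are absent, and real
stratifications can interact with the response nonlinearly in ways the
additive construction here cannot produce.

## Problem sizes and numerics

Default landscapes are 150×150 cells at 500 m (22,500 pixels, ~3,700 lattice
samples at 1200 m) — large enough that q̂ sampling error is well under the
0.02 recovery tolerance while the whole pipeline runs in seconds.  The
permutation test defaults to 999 replicates (199 in the quick pipeline
smoke configurations).  Degenerate inputs fail loudly: constant indicators
cannot be standardized, constant responses have no q, singular correlation
matrices have no KMO, and k above the number of distinct values has no
break structure.
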