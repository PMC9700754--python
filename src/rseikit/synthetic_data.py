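"""Synthetic landscapes with known ground truth.

Generates everything the pipeline consumes — seven reflectance bands, NDVI,
LST, covariate rasters, land use — from a latent ecological-quality field
with analytically known structure, so that index computation, PCA, grading,
and the geodetector statistics can all be verified without real imagery.

Construction
------------
Each covariate contributes a stepwise field: its strata are contiguous
quantile bands of an independent smooth Gaussian random field (so strata are
spatially clumped, as real covariates are), and each stratum carries an
effect size.  The latent quality field is the standardized sum of all
covariate contributions plus iid pixel noise.  Because the stratum maps are
fixed once generated, the q-statistic each covariate should attain against
the latent field is computable exactly from the realized stratum means of
the noiseless composite and the residual variance:

    q_true_c = SSB_c(m) / (N Var(m) + N sigma_eps^2),

with m the noiseless composite.  The four RSEI indicators are then linear in
the latent field with independent noise — greenness and wetness positively,
heat and dryness negatively — and a seven-band reflectance set is built by
approximately inverting the index formulas, so that tasseled-cap wetness and
NDBSI computed from the bands correlate strongly (|r| > 0.9) with the direct
indicator layers.  A contiguous water body is injected with a band signature
that MNDWI detects.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so components are independently regenerable and byte-identical
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .raster_core import CategoricalGrid, Grid
from .spectral_indices import ReflectanceBands

__all__ = [
    "IGBP_CODES",
    "IGBP_LEGEND",
    "CovariateSpec",
    "SimConfig",
    "SimOutput",
    "CovariateSim",
    "gen_latent_field",
    "gen_indicators",
    "gen_covariate_with_q",
    "gen_landuse",
    "simulate",
]

#: IGBP land-cover codes handled by the generator (the classes occurring in
#: an east-China agricultural plain: forests through water bodies).
IGBP_LEGEND = {
    5: "mixed forests",
    7: "open shrublands",
    9: "savannas",
    10: "grasslands",
    11: "permanent wetlands",
    12: "croplands",
    13: "urban areas",
    14: "cropland-natural vegetation mosaic",
    17: "water bodies",
}
IGBP_CODES = tuple(IGBP_LEGEND)

# Cropland-dominated class mix typical of an agricultural plain.
_DEFAULT_LANDUSE_PROPS = {
    12: 0.45, 14: 0.12, 10: 0.10, 13: 0.10, 9: 0.06,
    11: 0.05, 5: 0.05, 17: 0.04, 7: 0.03,
}

# Relative ecological effect by land-cover class: wetlands highest, urban
# lowest; standardized and scaled to the class's variance budget at run time.
_LANDUSE_EFFECT_RANK = {
    11: 1.2, 5: 0.8, 17: 0.5, 10: 0.2, 7: 0.1, 9: -0.1,
    14: 0.0, 12: -0.2, 13: -1.3,
}


@dataclasses.dataclass
class CovariateSpec:
    """One covariate of the synthetic landscape.

    ``ssb`` is the covariate's between-stratum variance contribution to the
    (unit-total-variance) latent budget; ``direction`` +1 means higher
    covariate values raise ecological quality, -1 the opposite.
    ``value_range`` maps stratum ranks to physical units for the continuous
    raster.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    L: int
    ssb: float
    direction: int = 1
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.ssb < 0:
            raise ValueError("ssb must be >= 0")


def _default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("fvc", "continuous", 11, 0.30, +1, (0.0, 1.0)),
        CovariateSpec("rainfall", "continuous", 11, 0.18, +1, (820.0, 950.0)),
        CovariateSpec("nightlight", "continuous", 11, 0.10, -1, (0.0, 63.0)),
        CovariateSpec("temperature", "continuous", 11, 0.08, +1, (14.0, 17.0)),
        CovariateSpec("landuse", "categorical", 9, 0.07),
        CovariateSpec("popdensity", "continuous", 11, 0.06, -1, (0.0, 2000.0)),
    ]


@dataclasses.dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions.

    ``indicator_loadings`` give each indicator's coefficient on the latent
    field (greenness/wetness positive, heat/dryness negative);
    ``indicator_noise_sd`` is the iid noise added to each indicator.  The
    covariate ``ssb`` values sum to < 1; the remainder is iid residual
    variance of the latent field.
    """

    shape: tuple[int, int] = (150, 150)
    cell_size: float = 500.0
    crs_label: str = "EPSG:32650"
    seed: int = 0
    length_scale: float = 12.0
    indicator_loadings: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"ndvi": 1.0, "wet": 0.7, "lst": -0.9, "ndbsi": -0.8})
    indicator_noise_sd: float = 0.05
    band_noise_sd: float = 0.004
    covariates: list[CovariateSpec] = dataclasses.field(default_factory=_default_covariates)
    landuse_proportions: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_LANDUSE_PROPS))
    water_fraction: float = 0.03

    def __post_init__(self) -> None:
        if self.indicator_noise_sd < 0 or self.band_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        total = sum(self.landuse_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("land-use proportions must sum to 1")
        ssb_total = sum(c.ssb for c in self.covariates)
        if ssb_total >= 1.0:
            raise ValueError("covariate variance budget must sum to < 1")
        if not 0 <= self.water_fraction < 1:
            raise ValueError("water_fraction must be in [0, 1)")

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(1.0 - sum(c.ssb for c in self.covariates)))


@dataclasses.dataclass
class CovariateSim:
    """Output of :func:`gen_covariate_with_q`."""

    strata: CategoricalGrid
    response: Grid
    q_true: float


@dataclasses.dataclass
class SimOutput:
    """Full synthetic landscape with ground truth."""

    bands: ReflectanceBands
    ndvi: Grid
    lst: Grid
    wet: Grid
    ndbsi: Grid
    covariate_grids: dict[str, Grid]
    landuse: CategoricalGrid
    strata_maps: dict[str, CategoricalGrid]
    latent: Grid
    water: np.ndarray
    q_true: dict[str, float]
    config: SimConfig


# ---------------------------------------------------------------------------
# Field generators
# ---------------------------------------------------------------------------

def gen_latent_field(shape: tuple[int, int], length_scale: float,
                     seed: int | np.random.SeedSequence = 0) -> Grid:
    """Smooth zero-mean, unit-variance Gaussian random field.

    Seeded white noise is convolved with an isotropic Gaussian kernel of the
    given length scale (in cells) and re-standardized; larger length scales
    give stronger spatial autocorrelation.
    """
    if not length_scale > 0:
        raise ValueError("length_scale must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(noise, sigma=length_scale, mode="reflect")
    field = (field - field.mean()) / field.std()
    return Grid(field, cell_size=1.0)


def _quantile_strata(field: np.ndarray, proportions: Sequence[float]) -> np.ndarray:
    """Contiguous quantile bands of a field: 0-based stratum indices.

    Rank-transforming the field and cutting at cumulative proportions yields
    spatially clumped strata whose class frequencies match the proportions up
    to rounding.
    """
    flat = field.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    cum = np.cumsum(np.asarray(proportions, dtype=np.float64))
    cuts = np.round(cum[:-1] * flat.size).astype(np.int64)
    labels = np.searchsorted(cuts, ranks, side="right")
    return labels.reshape(field.shape)


def gen_covariate_with_q(aux: Grid, L: int, effect_sizes: Sequence[float],
                         within_sd: float,
                         seed: int | np.random.SeedSequence = 0) -> CovariateSim:
    """Stratified response with an analytically known q.

    Strata are L equal quantile bands of the auxiliary field (spatially
    contiguous); the response is the stratum's effect size plus iid noise.
    The analytic q uses the realized stratum sizes:

        q_true = SSB / (SSB + N * within_sd^2),
        SSB = sum_h N_h (e_h - e_bar)^2.

    With zero within-stratum noise q_true = 1 (the stratification explains
    everything); with equal effect sizes q_true = 0.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if within_sd < 0:
        raise ValueError("within_sd must be >= 0")
    effects = np.asarray(effect_sizes, dtype=np.float64)
    if effects.size != L:
        raise ValueError("need one effect size per stratum")
    labels0 = _quantile_strata(aux.values, [1.0 / L] * L)
    rng = np.random.default_rng(seed)
    response = effects[labels0] + rng.normal(0.0, within_sd, size=aux.shape)
    n = labels0.size
    sizes = np.bincount(labels0.ravel(), minlength=L).astype(np.float64)
    ebar = float((sizes * effects).sum() / n)
    ssb = float((sizes * (effects - ebar) ** 2).sum())
    if within_sd == 0:
        q_true = 1.0
    else:
        q_true = ssb / (ssb + n * within_sd ** 2)
    strata = CategoricalGrid((labels0 + 1).astype(np.int64),
                             {i + 1: f"stratum_{i + 1}" for i in range(L)},
                             aux.origin_x, aux.origin_y, aux.cell_size,
                             aux.crs_label, nodata=-1)
    return CovariateSim(strata=strata,
                        response=aux.with_values(response),
                        q_true=q_true)


def gen_landuse(shape: tuple[int, int], proportions: Mapping[int, float],
                seed: int | np.random.SeedSequence = 0,
                length_scale: float = 8.0) -> CategoricalGrid:
    """Spatially clumped IGBP land-cover map with target class frequencies.

    Quantile-partitions a smooth random field by the cumulative proportions,
    which keeps classes contiguous and frequencies within rounding of the
    targets.
    """
    if not proportions:
        raise ValueError("proportions must be non-empty")
    codes = list(proportions)
    unknown = set(codes) - set(IGBP_CODES)
    if unknown:
        raise ValueError(f"codes outside the supported IGBP set: {sorted(unknown)}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    aux = gen_latent_field(shape, length_scale, seed)
    labels0 = _quantile_strata(aux.values, [proportions[c] for c in codes])
    code_arr = np.asarray(codes, dtype=np.int64)[labels0]
    return CategoricalGrid(code_arr, IGBP_LEGEND, cell_size=1.0, nodata=-1)


# ---------------------------------------------------------------------------
# Indicators and bands
# ---------------------------------------------------------------------------

# Linear band models in u = Phi(latent): intercept + slope * u.  Chosen so
# that wetness rises, SI/IBI fall with quality, and MNDWI stays below zero on
# land (green < swir1) with a comfortable noise margin.
_BAND_MODEL = {
    "red":   (0.25, -0.15),
    "nir1":  (0.20, +0.30),
    "blue":  (0.08, 0.0),
    "green": (0.12, +0.05),
    "nir2":  (0.25, +0.15),
    "swir1": (0.32, -0.12),
    "swir2": (0.25, -0.10),
}
# Open-water signature: strong green, low infrared -> MNDWI > 0.
_WATER_BANDS = {
    "red": 0.05, "nir1": 0.05, "blue": 0.06, "green": 0.30,
    "nir2": 0.04, "swir1": 0.05, "swir2": 0.04,
}


def gen_indicators(latent: Grid, config: SimConfig,
                   water: np.ndarray | None = None,
                   seed: int | np.random.SeedSequence | None = None,
                   ) -> tuple[Grid, Grid, Grid, Grid, ReflectanceBands]:
    """Indicator layers and reflectance bands driven by the latent field.

    Returns (ndvi, wet, lst, ndbsi, bands).  Each direct indicator is
    loading * latent + iid noise (positive loadings for ndvi/wet, negative
    for lst/ndbsi), mapped onto a plausible physical scale.  The bands are an
    approximate inversion: linear in the probit-rank of the latent field, so
    indices computed from them track the direct layers without being exactly
    equal.  ``water`` marks cells overwritten with an open-water signature.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    z = latent.values
    load = config.indicator_loadings
    sd = config.indicator_noise_sd

    def noisy(coef: float) -> np.ndarray:
        return coef * z + rng.normal(0.0, sd, size=z.shape)

    ndvi_v = 0.5 + 0.1 * noisy(load["ndvi"])
    wet_v = 0.02 * noisy(load["wet"])
    lst_v = 302.0 + 4.0 * noisy(load["lst"])
    ndbsi_v = 0.1 * noisy(load["ndbsi"])
    if water is not None and water.any():
        # Open water: wet, cool, vegetation-free.  These cells carry a
        # matching band signature below and are MNDWI-masked downstream.
        ndvi_v = np.where(water, 0.05, ndvi_v)
        wet_v = np.where(water, 0.05, wet_v)
        lst_v = np.where(water, 296.0, lst_v)
        ndbsi_v = np.where(water, -0.10, ndbsi_v)
    ndvi = latent.with_values(ndvi_v)
    wet = latent.with_values(wet_v)
    lst = latent.with_values(lst_v)
    ndbsi = latent.with_values(ndbsi_v)

    u = stats.norm.cdf(z)
    band_grids = {}
    for name, (intercept, slope) in _BAND_MODEL.items():
        vals = intercept + slope * u + rng.normal(0.0, config.band_noise_sd, size=z.shape)
        if water is not None and water.any():
            vals = np.where(water, _WATER_BANDS[name], vals)
        band_grids[name] = latent.with_values(vals)
    return ndvi, wet, lst, ndbsi, ReflectanceBands(**band_grids)


def _ramp_effects(L: int, ssb: float, direction: int) -> np.ndarray:
    """Linear per-stratum effects with population variance ``ssb``."""
    h = np.arange(1, L + 1, dtype=np.float64)
    z = (h - h.mean()) / h.std()  # population sd over equal weights
    return direction * np.sqrt(ssb) * z


def _landuse_effects(codes: Sequence[int], proportions: Mapping[int, float],
                     ssb: float) -> np.ndarray:
    """Class effects (wetlands high, urban low) scaled to variance ``ssb``."""
    raw = np.array([_LANDUSE_EFFECT_RANK[c] for c in codes])
    w = np.array([proportions[c] for c in codes])
    mean = float((w * raw).sum())
    var = float((w * (raw - mean) ** 2).sum())
    return np.sqrt(ssb / var) * (raw - mean)


def simulate(config: SimConfig | None = None) -> SimOutput:
    """Generate a full landscape: covariates -> latent quality -> imagery.

    Deterministic given ``config.seed``; every component draws from its own
    spawned seed sequence.
    """
    if config is None:
        config = SimConfig()
    root = np.random.SeedSequence(config.seed)
    n_cov = len(config.covariates)
    seeds = root.spawn(n_cov + 4)
    cov_seeds, (eps_seed, ind_seed, water_seed, jitter_root) = seeds[:n_cov], seeds[n_cov:]
    jitter_seeds = jitter_root.spawn(n_cov)

    shape = config.shape
    geo = dict(origin_x=0.0, origin_y=shape[0] * config.cell_size,
               cell_size=config.cell_size, crs_label=config.crs_label)

    strata_maps: dict[str, CategoricalGrid] = {}
    effects_by_cov: dict[str, np.ndarray] = {}
    contributions = np.zeros(shape)
    landuse: CategoricalGrid | None = None

    for spec, cseed in zip(config.covariates, cov_seeds):
        if spec.kind == "categorical":
            lu = gen_landuse(shape, config.landuse_proportions, cseed,
                             config.length_scale)
            codes_present = sorted(config.landuse_proportions)
            effects = _landuse_effects(codes_present, config.landuse_proportions,
                                       spec.ssb)
            code_to_idx = {c: i for i, c in enumerate(codes_present)}
            idx = np.vectorize(code_to_idx.get)(lu.codes)
            contribution = effects[idx]
            landuse = CategoricalGrid(lu.codes, IGBP_LEGEND, **geo, nodata=-1)
            strata_maps[spec.name] = landuse
        else:
            aux = gen_latent_field(shape, config.length_scale, cseed)
            labels0 = _quantile_strata(aux.values, [1.0 / spec.L] * spec.L)
            effects = _ramp_effects(spec.L, spec.ssb, spec.direction)
            contribution = effects[labels0]
            strata_maps[spec.name] = CategoricalGrid(
                (labels0 + 1).astype(np.int64),
                {i + 1: f"class_{i + 1}" for i in range(spec.L)},
                **geo, nodata=-1)
        effects_by_cov[spec.name] = effects
        contributions = contributions + contribution

    eps_rng = np.random.default_rng(eps_seed)
    eps = eps_rng.normal(0.0, config.residual_sd, size=shape)
    raw = contributions + eps
    latent_vals = (raw - raw.mean()) / raw.std()
    latent = Grid(latent_vals, **geo)

    # Exact q per covariate against the latent construction: between-stratum
    # SS of the noiseless composite over its total variance plus noise.
    m = contributions
    n = m.size
    total = float(((m - m.mean()) ** 2).sum()) + n * config.residual_sd ** 2
    q_true: dict[str, float] = {}
    for spec in config.covariates:
        smap = strata_maps[spec.name]
        labels = smap.codes.ravel()
        uniq, inv = np.unique(labels, return_inverse=True)
        sizes = np.bincount(inv).astype(np.float64)
        sums = np.bincount(inv, weights=m.ravel())
        means = sums / sizes
        grand = m.mean()
        ssb = float((sizes * (means - grand) ** 2).sum())
        q_true[spec.name] = ssb / total

    # Water body: top quantile of an independent smooth field.
    water = np.zeros(shape, dtype=bool)
    if config.water_fraction > 0:
        wfield = gen_latent_field(shape, config.length_scale, water_seed)
        thresh = np.quantile(wfield.values, 1.0 - config.water_fraction)
        water = wfield.values > thresh

    ndvi, wet, lst, ndbsi, bands = gen_indicators(latent, config, water, ind_seed)

    # Continuous covariate rasters: clustered values (within-cluster span
    # half the between-cluster gap) so natural-breaks discretization with
    # k = L recovers the true strata.
    covariate_grids: dict[str, Grid] = {}
    for spec, jseed in zip(config.covariates, jitter_seeds):
        if spec.kind == "categorical":
            covariate_grids[spec.name] = strata_maps[spec.name].as_grid()
            continue
        labels0 = strata_maps[spec.name].codes - 1
        jrng = np.random.default_rng(jseed)
        u = jrng.uniform(size=shape)
        pos = labels0 + 0.25 + 0.5 * u  # cluster h occupies [h+0.25, h+0.75]
        lo, hi = spec.value_range
        covariate_grids[spec.name] = Grid(lo + (hi - lo) * pos / spec.L, **geo)

    return SimOutput(bands=bands, ndvi=ndvi, lst=lst, wet=wet, ndbsi=ndbsi,
                     covariate_grids=covariate_grids, landuse=landuse,
                     strata_maps=strata_maps, latent=latent, water=water,
                     q_true=q_true, config=config)
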