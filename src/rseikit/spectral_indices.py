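"""Band algebra for the RSEI indicator inputs.

Produces tasseled-cap wetness (Wet), the soil index (SI), the index-based
built-up index (IBI), their mean NDBSI (the dryness indicator), the modified
normalized difference water index (MNDWI) used to mask open water, and
fractional vegetation cover (FVC) from NDVI via the dimidiate pixel model.

Band semantics follow the MOD09A1 surface-reflectance layout: bands 1-7 are
Red, NIR1, Blue, Green, NIR2, SWIR1, SWIR2.  Where an index formula says
"NIR" without qualification, NIR1 (the standard ~858 nm near-infrared band)
is used; this is configurable through the ``nir`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster_core import Grid

__all__ = [
    "WET_COEFFICIENTS",
    "ReflectanceBands",
    "compute_wet",
    "compute_si",
    "compute_ibi",
    "compute_ndbsi",
    "compute_mndwi",
    "water_mask",
    "compute_fvc",
]

#: Tasseled-cap wetness coefficients for MOD09A1 bands 1-7
#: (Red, NIR1, Blue, Green, NIR2, SWIR1, SWIR2).
WET_COEFFICIENTS = (0.1147, 0.2489, 0.2408, 0.3132, -0.3122, -0.6416, -0.5087)

_BAND_ORDER = ("red", "nir1", "blue", "green", "nir2", "swir1", "swir2")


@dataclasses.dataclass
class ReflectanceBands:
    """Seven co-registered surface-reflectance grids in MOD09A1 band order."""

    red: Grid
    nir1: Grid
    blue: Grid
    green: Grid
    nir2: Grid
    swir1: Grid
    swir2: Grid

    def __post_init__(self) -> None:
        ref = self.red
        for name in _BAND_ORDER:
            if not ref.co_registered(getattr(self, name)):
                raise ValueError(f"band {name!r} is not co-registered with red")

    def __iter__(self):
        return (getattr(self, name) for name in _BAND_ORDER)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with zero denominators mapped to NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.asarray(out, dtype=np.float64)
    out[den == 0] = np.nan
    return out


def compute_wet(bands: ReflectanceBands) -> Grid:
    """Tasseled-cap wetness: fixed linear combination of the seven bands.

    Any nodata input pixel propagates to nodata output.
    """
    arrays = [g.values for g in bands]
    out = np.zeros_like(arrays[0])
    for coef, arr in zip(WET_COEFFICIENTS, arrays):
        out = out + coef * arr
    return bands.red.with_values(out)


def compute_si(bands: ReflectanceBands, nir: str = "nir1") -> Grid:
    """Soil index SI = ((SWIR1+Red) - (NIR+Blue)) / ((SWIR1+Red) + (NIR+Blue))."""
    n = getattr(bands, nir).values
    a = bands.swir1.values + bands.red.values
    b = n + bands.blue.values
    return bands.red.with_values(_safe_ratio(a - b, a + b))


def compute_ibi(bands: ReflectanceBands, nir: str = "nir1") -> Grid:
    """Index-based built-up index.

    IBI = (A - B) / (A + B) with
    A = 2*SWIR1/(SWIR1+NIR), B = NIR/(NIR+Red) + Green/(Green+SWIR1).
    Any zero sub-denominator yields nodata at that pixel.
    """
    n = getattr(bands, nir).values
    s1 = bands.swir1.values
    a = _safe_ratio(2.0 * s1, s1 + n)
    b = _safe_ratio(n, n + bands.red.values) + _safe_ratio(
        bands.green.values, bands.green.values + s1
    )
    return bands.red.with_values(_safe_ratio(a - b, a + b))


def compute_ndbsi(si: Grid, ibi: Grid) -> Grid:
    """Dryness indicator: per-pixel mean of SI and IBI."""
    if not si.co_registered(ibi):
        raise ValueError("SI and IBI grids are not co-registered")
    return si.with_values(0.5 * (si.values + ibi.values))


def compute_mndwi(bands: ReflectanceBands) -> Grid:
    """MNDWI = (Green - SWIR1) / (Green + SWIR1), for open-water detection."""
    g = bands.green.values
    s = bands.swir1.values
    return bands.green.with_values(_safe_ratio(g - s, g + s))


def water_mask(indicator: Grid, mndwi: Grid, threshold: float = 0.0) -> Grid:
    """Set pixels with MNDWI above ``threshold`` to nodata.

    Open water carries a strong wetness signal unrelated to terrestrial
    ecological quality, so every indicator is masked before standardization.
    """
    if not indicator.co_registered(mndwi):
        raise ValueError("indicator and MNDWI grids are not co-registered")
    out = indicator.values.copy()
    out[mndwi.values > threshold] = np.nan
    return indicator.with_values(out)


def compute_fvc(ndvi: Grid, low_pct: float = 5.0, high_pct: float = 95.0) -> Grid:
    """Fractional vegetation cover via the dimidiate pixel model.

    FVC = (NDVI - NDVI_soil) / (NDVI_veg - NDVI_soil), clipped to [0, 1],
    with the bare-soil and full-vegetation endmembers taken as the
    ``low_pct`` / ``high_pct`` percentiles of the valid NDVI distribution.
    """
    vals = ndvi.valid_values()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("NDVI must contain at least two distinct valid values")
    lo, hi = np.percentile(vals, [low_pct, high_pct])
    if hi == lo:
        raise ValueError("degenerate NDVI distribution: percentiles coincide")
    fvc = np.clip((ndvi.values - lo) / (hi - lo), 0.0, 1.0)
    return ndvi.with_values(fvc)
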