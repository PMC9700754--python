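"""RSEI construction by principal component analysis.

The four water-masked indicators (NDVI greenness, Wet humidity, LST heat,
NDBSI dryness) are standardized to zero mean and unit sample variance over
their common valid-pixel mask, checked for factorability (KMO sampling
adequacy and Bartlett's sphericity test), and decomposed by PCA on the
correlation matrix.  The first principal component is sign-oriented so that
greenness loads positively, then min-max rescaled to [0, 1] to give the
remote sensing ecological index.  A weighted multi-component composite
(contribution-rate weights) is provided as an explicit alternative estimator.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .raster_core import Grid

__all__ = [
    "INDICATOR_NAMES",
    "IndicatorStack",
    "PcaResult",
    "standardize",
    "kmo_statistic",
    "bartlett_sphericity",
    "principal_components",
    "rsei_from_pc1",
    "composite_index",
]

INDICATOR_NAMES = ("ndvi", "wet", "lst", "ndbsi")


@dataclasses.dataclass
class IndicatorStack:
    """The four co-registered RSEI inputs on their common valid mask."""

    ndvi: Grid
    wet: Grid
    lst: Grid
    ndbsi: Grid

    def __post_init__(self) -> None:
        for name in INDICATOR_NAMES[1:]:
            if not self.ndvi.co_registered(getattr(self, name)):
                raise ValueError(f"indicator {name!r} is not co-registered with ndvi")

    def __iter__(self):
        return (getattr(self, name) for name in INDICATOR_NAMES)

    def common_mask(self) -> np.ndarray:
        """Intersection of the four valid-pixel masks."""
        mask = self.ndvi.valid_mask
        for g in list(self)[1:]:
            mask = mask & g.valid_mask
        return mask

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid x 4) data matrix over the common mask, plus the mask."""
        mask = self.common_mask()
        data = np.column_stack([g.values[mask] for g in self])
        return data, mask


@dataclasses.dataclass
class PcaResult:
    """Eigenstructure of the indicator correlation matrix plus diagnostics.

    ``eigenvectors`` holds unit eigenvectors as columns, ordered by
    descending eigenvalue; ``loadings`` are eigenvectors scaled by sqrt of
    their eigenvalue (component-indicator correlations for standardized
    data); ``contribution_rates`` are eigenvalue shares of total variance.
    """

    indicator_names: tuple[str, ...]
    mean_vector: np.ndarray
    sd_vector: np.ndarray
    correlation_matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    contribution_rates: np.ndarray
    loadings: np.ndarray
    n: int
    kmo: float
    bartlett_stat: float
    bartlett_p: float


def standardize(stack: IndicatorStack) -> tuple[IndicatorStack, dict[str, tuple[float, float]]]:
    """Standardize each indicator to mean 0, sample sd 1 over the common mask.

    Returns the standardized stack and a record {name: (mean, sd)}.  The
    spread is the sample standard deviation (n-1 denominator).  A constant
    indicator cannot be standardized and raises ValueError naming it.
    """
    mask = stack.common_mask()
    if mask.sum() < 2:
        raise ValueError("need at least 2 jointly valid pixels")
    out = {}
    record: dict[str, tuple[float, float]] = {}
    for name in INDICATOR_NAMES:
        g: Grid = getattr(stack, name)
        vals = g.values[mask]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"indicator {name!r} has zero spread; cannot standardize")
        z = np.full(g.shape, np.nan)
        z[mask] = (vals - mean) / sd
        out[name] = g.with_values(z)
        record[name] = (mean, sd)
    return IndicatorStack(**out), record


def kmo_statistic(correlation: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum a_ij^2) over i != j, where a_ij are
    partial correlations obtained from the inverse correlation matrix.
    Values above 0.5 are conventionally taken as adequate for PCA.
    """
    r = np.asarray(correlation, dtype=np.float64)
    p = r.shape[0]
    if r.shape != (p, p) or p < 3:
        raise ValueError("correlation must be square with p >= 3")
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular") from exc
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    ssr = float((r[off] ** 2).sum())
    ssp = float((partial[off] ** 2).sum())
    return ssr / (ssr + ssp)


def bartlett_sphericity(correlation: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p+5)/6) * ln det(R), df = p(p-1)/2; returns the
    statistic and the upper-tail p-value.
    """
    r = np.asarray(correlation, dtype=np.float64)
    p = r.shape[0]
    if n <= p:
        raise ValueError("n must exceed the number of indicators")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(stats.chi2.sf(stat, df))
    return float(stat), pval


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Flip so the first component exceeding 1e-12 in magnitude is positive."""
    for v in vec:
        if abs(v) > 1e-12:
            return vec if v > 0 else -vec
    return vec


def principal_components(standardized: IndicatorStack) -> PcaResult:
    """Eigen-decomposition of the correlation matrix of the four indicators.

    On standardized data the correlation and covariance matrices coincide,
    so this is equally the covariance-matrix PCA.  Components are ordered by
    descending eigenvalue; eigenvalue ties (within 1e-12) are broken by the
    eigenvector sign canonicalization, which is applied to every component.
    """
    data, _ = standardized.as_matrix()
    if data.shape[1] != 4:
        raise ValueError("exactly four indicators are required")
    n = data.shape[0]
    mean_vec = data.mean(axis=0)
    sd_vec = data.std(axis=0, ddof=1)
    corr = np.corrcoef(data, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvecs = np.column_stack([_canonical_sign(eigvecs[:, i]) for i in range(4)])
    contrib = eigvals / eigvals.sum()
    loadings = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    kmo = kmo_statistic(corr)
    bstat, bp = bartlett_sphericity(corr, n)
    return PcaResult(
        indicator_names=INDICATOR_NAMES,
        mean_vector=mean_vec,
        sd_vector=sd_vec,
        correlation_matrix=corr,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        contribution_rates=contrib,
        loadings=loadings,
        n=n,
        kmo=kmo,
        bartlett_stat=bstat,
        bartlett_p=bp,
    )


def _oriented_pc1(pca: PcaResult) -> np.ndarray:
    """PC1 eigenvector oriented so greenness (NDVI) loads positively.

    If the NDVI loading is (numerically) zero the tie is broken by requiring
    the NDBSI (dryness) loading to be non-positive.
    """
    vec = pca.eigenvectors[:, 0].copy()
    i_ndvi = pca.indicator_names.index("ndvi")
    i_ndbsi = pca.indicator_names.index("ndbsi")
    if abs(vec[i_ndvi]) > 1e-12:
        if vec[i_ndvi] < 0:
            vec = -vec
    elif vec[i_ndbsi] > 0:
        vec = -vec
    return vec


def rsei_from_pc1(pca: PcaResult, standardized: IndicatorStack) -> Grid:
    """Project onto the oriented PC1 and min-max rescale valid pixels to [0, 1]."""
    data, mask = standardized.as_matrix()
    vec = _oriented_pc1(pca)
    scores = data @ vec
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("PC1 scores are constant; cannot rescale")
    rescaled = (scores - lo) / (hi - lo)
    out = np.full(standardized.ndvi.shape, np.nan)
    out[mask] = rescaled
    return standardized.ndvi.with_values(out)


def composite_index(pca: PcaResult, standardized: IndicatorStack, m: int = 1) -> Grid:
    """Weighted composite of the first ``m`` components.

    Y = sum_{i<=m} w_i * PC_i scores with contribution-rate weights
    w_i = lambda_i / sum_{j<=m} lambda_j (weights sum to 1).  Unlike the
    default RSEI this is not rescaled; with m = 1 it ranks pixels exactly
    as the PC1-based RSEI does.
    """
    p = pca.eigenvalues.size
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}]")
    data, mask = standardized.as_matrix()
    weights = pca.eigenvalues[:m] / pca.eigenvalues[:m].sum()
    vecs = pca.eigenvectors[:, :m].copy()
    vecs[:, 0] = _oriented_pc1(pca)
    scores = (data @ vecs) @ weights
    out = np.full(standardized.ndvi.shape, np.nan)
    out[mask] = scores
    return standardized.ndvi.with_values(out)


def diagnostics_table(pca: PcaResult):
    """Long-form DataFrame of eigenvalues, contribution rates, and loadings."""
    import pandas as pd

    rows = []
    for i in range(pca.eigenvalues.size):
        row = {
            "component": f"PC{i + 1}",
            "eigenvalue": pca.eigenvalues[i],
            "contribution_rate": pca.contribution_rates[i],
        }
        for j, name in enumerate(pca.indicator_names):
            row[f"eigvec_{name}"] = pca.eigenvectors[j, i]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["kmo"] = pca.kmo
    df.attrs["bartlett_stat"] = pca.bartlett_stat
    df.attrs["bartlett_p"] = pca.bartlett_p
    return df
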