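"""Geodetector statistics for spatial stratified heterogeneity.

Given point samples of a response (here the RSEI) and covariates discretized
into strata, four detectors quantify how strongly each covariate structures
the response:

* factor detector — the q-statistic, q = 1 - SSW/SST, the share of response
  variance explained by a stratification;
* interaction detector — q of the overlay of two stratifications, typed
  against the single-factor q values (enhancement/reduction/independence);
* risk detector — per-stratum response means with pairwise Welch t-tests;
* ecological detector — an F-ratio of within-stratum sums of squares telling
  whether two covariates differ significantly in explanatory power.

Variance conventions: inside q and the ecological F, per-stratum variances
are population variances (divide by N_h) so that N_h * sigma_h^2 is exactly
the within-stratum sum of squares and q = SSB/SST holds as an identity.  The
risk detector's t-tests use sample variances, as standard for Welch tests.

Continuous covariates are discretized with exact Fisher-Jenks natural breaks
(minimum within-class sum of squared deviations); categorical covariates
pass through unchanged.  Samples are drawn on a regular lattice over the
co-registered rasters.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raster_core import CategoricalGrid, Grid, RasterStack

__all__ = [
    "Stratification",
    "FactorResult",
    "InteractionResult",
    "RiskResult",
    "EcoResult",
    "grid_sample",
    "jenks_breaks",
    "discretize",
    "factor_q",
    "q_significance",
    "interaction_detect",
    "risk_detect",
    "ecological_detect",
]

INTERACTION_TYPES = (
    "non-linear reduction",
    "single-factor non-linear reduction",
    "two-factor enhancement",
    "independent",
    "non-linear enhancement",
)


@dataclasses.dataclass
class Stratification:
    """Stratum label per sample row.

    Labels may be arbitrary integers (e.g. IGBP codes); ``L`` and the
    per-stratum sizes are derived from the distinct labels present.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("stratum labels must be integers")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def strata(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def L(self) -> int:
        return self.strata.size

    @property
    def sizes(self) -> np.ndarray:
        return np.unique(self.labels, return_counts=True)[1]

    def compact(self) -> np.ndarray:
        """Labels re-coded to 0..L-1 (sorted label order)."""
        return np.searchsorted(self.strata, self.labels)


@dataclasses.dataclass
class FactorResult:
    q: float
    p_value: float
    method: str
    ssw: float
    sst: float


@dataclasses.dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    type: str


@dataclasses.dataclass
class RiskResult:
    strata: np.ndarray          # stratum labels, sorted
    means: np.ndarray           # per-stratum response means
    sizes: np.ndarray
    t: np.ndarray               # pairwise Welch t (NaN on diagonal / skipped)
    df: np.ndarray
    p: np.ndarray
    significant: np.ndarray     # raw decisions at the given alpha
    significant_holm: np.ndarray
    alpha: float

    @property
    def best_stratum(self) -> int:
        """Label of the stratum with the highest mean response."""
        return int(self.strata[int(np.argmax(self.means))])


@dataclasses.dataclass
class EcoResult:
    F: float
    df: tuple[int, int]
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Sampling and discretization
# ---------------------------------------------------------------------------

def grid_sample(response: Grid, covariates: RasterStack, spacing: float,
                response_range: tuple[float, float] | None = (0.0, 1.0),
                ) -> pd.DataFrame:
    """Extract samples on a regular lattice over co-registered rasters.

    Points sit at ``origin + spacing/2 + k*spacing`` in each axis (cell-centre
    style anchoring).  A row is kept only if the response and every covariate
    are valid there; rows with any nodata, or a response outside
    ``response_range``, are dropped as abnormal.  Columns: id, x, y, Y, then
    one column per covariate layer.
    """
    if spacing < response.cell_size:
        raise ValueError("spacing must be at least one cell")
    for name, layer in zip(covariates.names, covariates):
        if not response.co_registered(layer):
            raise ValueError(f"covariate {name!r} is not co-registered with the response")
    nr, nc = response.shape
    width = nc * response.cell_size
    height = nr * response.cell_size
    xs = np.arange(spacing / 2.0, width, spacing) + response.origin_x
    ys = response.origin_y - np.arange(spacing / 2.0, height, spacing)
    xx, yy = np.meshgrid(xs, ys)
    xx, yy = xx.ravel(), yy.ravel()
    col = np.floor((xx - response.origin_x) / response.cell_size).astype(np.int64)
    row = np.floor((response.origin_y - yy) / response.cell_size).astype(np.int64)
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    xx, yy, row, col = xx[inside], yy[inside], row[inside], col[inside]

    data = {"x": xx, "y": yy, "Y": response.values[row, col]}
    for name, layer in zip(covariates.names, covariates):
        data[name] = layer.values[row, col]
    df = pd.DataFrame(data)
    keep = df.notna().all(axis=1)
    if response_range is not None:
        lo, hi = response_range
        keep &= (df["Y"] >= lo) & (df["Y"] <= hi)
    df = df[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError("no valid sample rows survive nodata/abnormal-value removal")
    df.insert(0, "id", np.arange(len(df)))
    return df


def _sse_suffix(x_sorted: np.ndarray, s1: np.ndarray, s2: np.ndarray,
                starts: np.ndarray, end: int) -> np.ndarray:
    """SSE of x[start..end] (inclusive) for each start, from prefix sums."""
    m = end + 1 - starts
    seg1 = s1[end + 1] - s1[starts]
    seg2 = s2[end + 1] - s2[starts]
    return seg2 - seg1 * seg1 / m


def jenks_breaks(values: Sequence[float], k: int, max_n: int = 6000) -> list[float]:
    """Exact Fisher-Jenks natural breaks.

    Partitions the sorted values into ``k`` contiguous classes minimizing the
    total within-class sum of squared deviations (dynamic program, exact).
    Returns the k-1 interior breaks as the maxima of classes 1..k-1; a value
    equal to a break belongs to the lower class.

    For very large inputs (n > ``max_n``) the optimization runs on an
    evenly-spaced subsample of the sorted values (deterministic) and the
    resulting breaks are applied to the full data.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    if np.isnan(x).any():
        raise ValueError("values must not contain NaN")
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x).size
    if k > distinct:
        raise ValueError(f"k={k} exceeds the number of distinct values ({distinct})")
    if k == 1:
        return []
    if n > max_n:
        idx = np.unique(np.linspace(0, n - 1, max_n).round().astype(np.int64))
        x = x[idx]
        n = x.size

    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    # cost[j] after class c: optimal SSW of x[0..j] split into c classes.
    cost = np.array([_sse_suffix(x, s1, s2, np.array([0]), j)[0] for j in range(n)])
    back = np.zeros((k, n), dtype=np.int64)
    for c in range(2, k + 1):
        new_cost = np.full(n, np.inf)
        for j in range(c - 1, n):
            starts = np.arange(c - 1, j + 1)  # first index of the last class
            total = cost[starts - 1] + _sse_suffix(x, s1, s2, starts, j)
            i = int(np.argmin(total))
            new_cost[j] = total[i]
            back[c - 1, j] = starts[i]
        cost = new_cost

    # Backtrack class boundaries; breaks are the class maxima.
    breaks = []
    j = n - 1
    for c in range(k, 1, -1):
        start = int(back[c - 1, j])
        breaks.append(float(x[start - 1]))
        j = start - 1
    return sorted(breaks)


def discretize(column: Sequence[float], k: int = 11,
               categorical: bool = False) -> Stratification:
    """Stratify one covariate column.

    Continuous columns are cut at Fisher-Jenks natural breaks into ``k``
    classes labelled 1..k in value order; categorical columns pass their
    integer codes through unchanged.
    """
    arr = np.asarray(column)
    if np.isnan(arr.astype(np.float64)).any():
        raise ValueError("column must not contain NaN")
    if categorical:
        return Stratification(arr.astype(np.int64))
    arr = arr.astype(np.float64)
    breaks = jenks_breaks(arr, k)
    labels = np.searchsorted(np.asarray(breaks), arr, side="left") + 1
    return Stratification(labels.astype(np.int64))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _ssw_sst(y: np.ndarray, compact: np.ndarray, L: int) -> tuple[float, float]:
    """Within-stratum and total sums of squares (population variances)."""
    counts = np.bincount(compact, minlength=L).astype(np.float64)
    sums = np.bincount(compact, weights=y, minlength=L)
    sums2 = np.bincount(compact, weights=y * y, minlength=L)
    ssw = float(np.sum(sums2 - sums * sums / np.maximum(counts, 1)))
    sst = float(np.sum(y * y) - y.sum() ** 2 / y.size)
    return ssw, sst


def _q_value(y: np.ndarray, compact: np.ndarray, L: int) -> float:
    ssw, sst = _ssw_sst(y, compact, L)
    return 1.0 - ssw / sst


def factor_q(Y: Sequence[float], strata: Stratification,
             method: str = "permutation", reps: int = 999,
             seed: int = 0) -> FactorResult:
    """Factor detector: q = 1 - SSW/SST.

    q is the share of response variance explained by the stratification
    (exactly SSB/SST under population variances): q = 1 when every stratum is
    internally constant, q = 0 when all stratum means equal the grand mean.
    """
    y = np.asarray(Y, dtype=np.float64)
    if y.size != strata.n:
        raise ValueError("Y and strata must have the same length")
    if y.size < 2:
        raise ValueError("need at least two samples")
    compact = strata.compact()
    L = strata.L
    ssw, sst = _ssw_sst(y, compact, L)
    if sst <= 0:
        raise ValueError("total sum of squares is zero; q is undefined")
    q = 1.0 - ssw / sst
    p = q_significance(q, y.size, L, y, strata, method=method, reps=reps, seed=seed)
    return FactorResult(q=q, p_value=p, method=method, ssw=ssw, sst=sst)


def q_significance(q: float, N: int, L: int, Y: Sequence[float],
                   strata: Stratification, method: str = "permutation",
                   reps: int = 999, seed: int = 0) -> float:
    """p-value for an observed q.

    ``permutation`` (default): shuffle the stratum labels, recompute q, and
    report the upper-tail proportion with add-one smoothing — transparent and
    assumption-free.  ``noncentral-F``: the noncentral-F approximation used
    in the geodetector literature, F = (N-L)/(L-1) * q/(1-q) against a
    noncentral F(L-1, N-L) law.
    """
    y = np.asarray(Y, dtype=np.float64)
    compact = strata.compact()
    if method == "permutation":
        if reps < 1:
            raise ValueError("reps must be >= 1")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(reps):
            perm = rng.permutation(compact)
            if _q_value(y, perm, L) >= q - 1e-12:
                exceed += 1
        return (exceed + 1.0) / (reps + 1.0)
    if method == "noncentral-F":
        if q >= 1.0:
            return 0.0
        f_stat = (N - L) / max(L - 1, 1) * q / (1.0 - q)
        sigma2 = y.var()
        counts = np.bincount(compact, minlength=L).astype(np.float64)
        means = np.bincount(compact, weights=y, minlength=L) / np.maximum(counts, 1)
        lam = (np.sum(means ** 2) - (np.sum(np.sqrt(counts) * means)) ** 2 / N) / sigma2
        return float(stats.ncf.sf(f_stat, L - 1, N - L, max(lam, 0.0)))
    raise ValueError(f"unknown method: {method!r}")


def interaction_detect(Y: Sequence[float], strataA: Stratification,
                       strataB: Stratification, tol: float = 1e-12,
                       ) -> InteractionResult:
    """Interaction detector: q of the overlay stratification, typed.

    The overlay strata are the observed (a, b) label pairs.  The type follows
    the standard decision table: below both single q values -> non-linear
    reduction; between them -> single-factor non-linear reduction; above the
    larger -> two-factor enhancement; equal to the sum (within ``tol``) ->
    independent; above the sum -> non-linear enhancement.
    """
    y = np.asarray(Y, dtype=np.float64)
    if strataA.n != y.size or strataB.n != y.size:
        raise ValueError("stratifications must cover the same rows as Y")
    pairs = strataA.compact().astype(np.int64) * strataB.L + strataB.compact()
    overlay = Stratification(np.unique(pairs, return_inverse=True)[1].astype(np.int64))
    if overlay.L < 2:
        raise ValueError("overlay produces a single stratum")
    q1 = factor_q_value(y, strataA)
    q2 = factor_q_value(y, strataB)
    q12 = factor_q_value(y, overlay)
    return InteractionResult(q1=q1, q2=q2, q12=q12,
                             type=classify_interaction(q1, q2, q12, tol))


def factor_q_value(Y: Sequence[float], strata: Stratification) -> float:
    """q without a significance test (no permutation cost)."""
    y = np.asarray(Y, dtype=np.float64)
    ssw, sst = _ssw_sst(y, strata.compact(), strata.L)
    if sst <= 0:
        raise ValueError("total sum of squares is zero; q is undefined")
    return 1.0 - ssw / sst


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-12) -> str:
    """Assign exactly one interaction type to a (q1, q2, q12) triple.

    Equality with q1 + q2 (within ``tol``) is checked first; boundary cases
    q12 == min or q12 == max fall into the adjacent reduction class, keeping
    the assignment total and exclusive.
    """
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "non-linear enhancement"
    if q12 > hi:
        return "two-factor enhancement"
    if q12 < lo:
        return "non-linear reduction"
    return "single-factor non-linear reduction"


def risk_detect(Y: Sequence[float], strata: Stratification,
                alpha: float = 0.05) -> RiskResult:
    """Risk detector: per-stratum means with pairwise Welch t-tests.

    t = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2) with sample variances and
    Welch-Satterthwaite degrees of freedom, two-sided at ``alpha``.  Strata
    with fewer than 2 samples report their mean but skip tests (NaN t).
    Decisions are reported raw and Holm-adjusted.
    """
    y = np.asarray(Y, dtype=np.float64)
    labels = strata.strata
    L = labels.size
    compact = strata.compact()
    means = np.array([y[compact == i].mean() for i in range(L)])
    sizes = np.array([(compact == i).sum() for i in range(L)])
    var = np.array([y[compact == i].var(ddof=1) if sizes[i] >= 2 else np.nan
                    for i in range(L)])
    t = np.full((L, L), np.nan)
    df = np.full((L, L), np.nan)
    p = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            if sizes[i] < 2 or sizes[j] < 2:
                continue
            se2_i = var[i] / sizes[i]
            se2_j = var[j] / sizes[j]
            denom = se2_i + se2_j
            if denom == 0:
                t_ij = 0.0 if means[i] == means[j] else np.inf * np.sign(means[i] - means[j])
                dof = sizes[i] + sizes[j] - 2.0
            else:
                t_ij = (means[i] - means[j]) / np.sqrt(denom)
                dof = denom ** 2 / (
                    se2_i ** 2 / (sizes[i] - 1) + se2_j ** 2 / (sizes[j] - 1)
                )
            t[i, j] = t[j, i] = t_ij
            df[i, j] = df[j, i] = dof
            p[i, j] = p[j, i] = 2.0 * float(stats.t.sf(abs(t_ij), dof)) if np.isfinite(t_ij) else 0.0
    significant = p < alpha
    # Holm step-down over the upper triangle.
    significant_holm = np.zeros_like(significant)
    iu = np.triu_indices(L, 1)
    pvals = p[iu]
    finite = np.isfinite(pvals)
    if finite.any():
        order = np.argsort(pvals[finite])
        m = int(finite.sum())
        adj = np.zeros(m, dtype=bool)
        running = True
        sorted_p = pvals[finite][order]
        for rank, pv in enumerate(sorted_p):
            running = running and pv <= alpha / (m - rank)
            adj[order[rank]] = running
        holm_flat = np.zeros(pvals.size, dtype=bool)
        holm_flat[np.flatnonzero(finite)] = adj
        significant_holm[iu] = holm_flat
        significant_holm = significant_holm | significant_holm.T
    return RiskResult(strata=labels, means=means, sizes=sizes, t=t, df=df, p=p,
                      significant=significant, significant_holm=significant_holm,
                      alpha=alpha)


def ecological_detect(Y: Sequence[float], strataA: Stratification,
                      strataB: Stratification, alpha: float = 0.05) -> EcoResult:
    """Ecological detector: F-ratio of within-stratum sums of squares.

    F = [N1 (N2 - 1) SSW1] / [N2 (N1 - 1) SSW2] compared two-sidedly against
    the F(N1 - 1, N2 - 1) distribution; the decision is invariant under
    exchanging the two covariates (F -> 1/F).
    """
    y = np.asarray(Y, dtype=np.float64)
    n1 = strataA.n
    n2 = strataB.n
    ssw1, _ = _ssw_sst(y, strataA.compact(), strataA.L)
    ssw2, _ = _ssw_sst(y, strataB.compact(), strataB.L)
    if ssw2 <= 0:
        raise ValueError("SSW of the second covariate is zero; F is undefined")
    f_stat = (n1 * (n2 - 1) * ssw1) / (n2 * (n1 - 1) * ssw2)
    d1, d2 = n1 - 1, n2 - 1
    p = 2.0 * min(float(stats.f.sf(f_stat, d1, d2)), float(stats.f.cdf(f_stat, d1, d2)))
    p = min(p, 1.0)
    return EcoResult(F=f_stat, df=(d1, d2), p_value=p, significant=p < alpha)
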