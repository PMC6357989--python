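"""Spatial autocorrelation and hot-spot statistics on planar units.

Implements, from their standard formulas, the machinery needed to turn
per-region indicator prevalences into "hot spots of need":

* fixed distance-band binary weights (optionally including self),
* Global Moran's I with the randomization-assumption variance,
* incremental spatial autocorrelation over a distance grid, with the
  z-peak distance taken as the neighborhood scale,
* a Getis-Ord Gi*-style local hot-spot z-score with a
  99/95/90-confidence class ladder,
* standard-deviation class breaks for choropleth-style region layers,
* cumulative need counts across indicator flags.

All distances are planar Euclidean.  Units with no neighbors inside the
band ("islands") are warned about and excluded from incremental
inference rather than silently zero-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform


class IslandWarning(UserWarning):
    """Some units have no neighbors within the distance band."""


@dataclass
class SpatialWeights:
    """Sparse symmetric spatial weights with cached variance sums.

    Attributes
    ----------
    W : scipy.sparse.csr_matrix
        n x n weight matrix.
    include_self : bool
        True when the diagonal carries w_ii = 1 (Gi* neighborhoods).
    """

    W: sparse.csr_matrix
    include_self: bool

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    @property
    def s1(self) -> float:
        sym = self.W + self.W.T
        return 0.5 * float(sym.multiply(sym).sum())

    @property
    def s2(self) -> float:
        totals = np.asarray(self.W.sum(axis=1)).ravel() + np.asarray(
            self.W.sum(axis=0)
        ).ravel()
        return float((totals**2).sum())

    def islands(self) -> np.ndarray:
        """Indices of units with no neighbors other than themselves."""
        off_diag = self.W - sparse.diags(self.W.diagonal())
        counts = np.asarray((off_diag != 0).sum(axis=1)).ravel()
        return np.flatnonzero(counts == 0)

    def to_edge_frame(self) -> pd.DataFrame:
        coo = self.W.tocoo()
        return pd.DataFrame({"i": coo.row, "j": coo.col, "w": coo.data})


@dataclass(slots=True, frozen=True)
class MoranResult:
    """Global Moran's I with randomization-assumption inference."""

    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int


@dataclass(slots=True)
class IncrementalMoranResult:
    """Moran's I over an ascending distance grid."""

    distances: np.ndarray
    I: np.ndarray
    z: np.ndarray
    p: np.ndarray
    skipped: list[float]
    peak_distance: float


HOTSPOT_CLASSES = ("cold99", "cold95", "cold90", "ns", "hot90", "hot95", "hot99")
_Z_LADDER = (2.575829303549, 1.959963984540, 1.644853626951)


@dataclass(slots=True)
class HotSpotLayer:
    """Per-unit Gi*-style z-scores and confidence classes."""

    z: np.ndarray
    classes: np.ndarray  # strings from HOTSPOT_CLASSES

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "class": self.classes})


def distance_band_weights(
    points: np.ndarray, d: float, include_self: bool = False
) -> SpatialWeights:
    """Binary weights: w_ij = 1 iff Euclidean distance(i, j) <= d, i != j.

    With ``include_self`` the diagonal is set to 1 as required by the
    Gi* hot-spot statistic.  Units without any neighbor trigger an
    :class:`IslandWarning` listing them.
    """
    points = np.asarray(points, dtype=float)
    if d <= 0:
        raise ValueError("distance band must be positive")
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    dist = squareform(pdist(points))
    A = (dist <= d).astype(float)
    np.fill_diagonal(A, 1.0 if include_self else 0.0)
    w = SpatialWeights(W=sparse.csr_matrix(A), include_self=include_self)
    isl = w.islands()
    if isl.size:
        warnings.warn(
            f"{isl.size} island unit(s) with no neighbor within d={d}: "
            f"{isl.tolist()[:20]}",
            IslandWarning,
            stacklevel=2,
        )
    return w


def morans_i(values: np.ndarray, w: SpatialWeights) -> MoranResult:
    """Global Moran's I with z/p under the randomization assumption.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 for deviations
    z_i = x_i - mean(x).  The variance uses the permutation moments
    (S0, S1, S2 and the sample kurtosis b2); the p-value is two-sided
    normal.
    """
    if w.include_self:
        raise ValueError("Moran's I requires weights without self-neighbors")
    x = np.asarray(values, dtype=float)
    n = w.n
    if x.shape != (n,):
        raise ValueError("values length must match weight order")
    z = x - x.mean()
    m2 = float(z @ z)
    if m2 == 0.0:
        raise ValueError("zero variance: values are constant")
    s0, s1, s2 = w.s0, w.s1, w.s2
    num = float(z @ (w.W @ z))
    I = (n / s0) * num / m2
    e_i = -1.0 / (n - 1)
    b2 = n * float((z**4).sum()) / m2**2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(zscore))
    return MoranResult(I=I, expected=e_i, variance=var, z=zscore, p=p, n=n)


def incremental_moran(
    values: np.ndarray, points: np.ndarray, d_grid: np.ndarray
) -> IncrementalMoranResult:
    """Moran's I at each distance band of an ascending grid.

    Distances that leave any unit without a neighbor are skipped (and
    listed in ``skipped``).  ``peak_distance`` is the first distance
    maximizing the z-score — the neighborhood scale for hot-spot
    analysis.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0 or np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be non-empty and strictly ascending")
    used_d, Is, zs, ps, skipped = [], [], [], [], []
    for d in d_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IslandWarning)
            w = distance_band_weights(points, float(d), include_self=False)
        if w.islands().size:
            skipped.append(float(d))
            continue
        res = morans_i(values, w)
        used_d.append(float(d))
        Is.append(res.I)
        zs.append(res.z)
        ps.append(res.p)
    if not used_d:
        raise ValueError("every distance in the grid leaves islands")
    zs_arr = np.asarray(zs)
    peak = used_d[int(np.argmax(zs_arr))]  # argmax returns the first maximum
    return IncrementalMoranResult(
        distances=np.asarray(used_d),
        I=np.asarray(Is),
        z=zs_arr,
        p=np.asarray(ps),
        skipped=skipped,
        peak_distance=peak,
    )


def classify_z(z: np.ndarray) -> np.ndarray:
    """Map z-scores to the 99/95/90 hot/cold class ladder."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, "ns", dtype=object)
    c99, c95, c90 = _Z_LADDER
    out[z >= c90] = "hot90"
    out[z >= c95] = "hot95"
    out[z >= c99] = "hot99"
    out[z <= -c90] = "cold90"
    out[z <= -c95] = "cold95"
    out[z <= -c99] = "cold99"
    return out


def hotspot_z(values: np.ndarray, w: SpatialWeights) -> HotSpotLayer:
    """Getis-Ord Gi*-style local hot-spot z-scores.

    For each unit i with neighborhood weights w_ij (self included),

        z_i = (sum_j w_ij x_j - xbar * W_i)
              / (S * sqrt[(n * sum_j w_ij^2 - W_i^2) / (n - 1)])

    with W_i = sum_j w_ij, xbar and S the global mean and population
    standard deviation of x.  z_i = 0 where the denominator vanishes
    (e.g. a constant field).
    """
    if not w.include_self:
        raise ValueError("hot-spot weights must include self (w_ii = 1)")
    x = np.asarray(values, dtype=float)
    n = w.n
    if n < 3:
        raise ValueError("need n >= 3 units")
    if x.shape != (n,):
        raise ValueError("values length must match weight order")
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)
    Wi = w.row_sums
    lag = w.W @ x
    sq = np.asarray(w.W.multiply(w.W).sum(axis=1)).ravel()
    inner = (n * sq - Wi**2) / (n - 1)
    denom = S * np.sqrt(np.maximum(inner, 0.0))
    z = np.zeros(n)
    ok = denom > 0
    z[ok] = (lag[ok] - xbar * Wi[ok]) / denom[ok]
    return HotSpotLayer(z=z, classes=classify_z(z))


SD_BREAKS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
SD_CLASS_LABELS = (
    "lt_m2.5sd",
    "m2.5_m1.5sd",
    "m1.5_m0.5sd",
    "m0.5_p0.5sd",
    "p0.5_p1.5sd",
    "p1.5_p2.5sd",
    "gt_p2.5sd",
)


def sd_classes(values: np.ndarray) -> np.ndarray:
    """Standard-deviation class breaks around the cross-unit mean."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0.0:
        return np.full(x.shape, SD_CLASS_LABELS[3], dtype=object)
    scaled = (x - x.mean()) / sd
    idx = np.searchsorted(np.asarray(SD_BREAKS), scaled, side="left")
    return np.asarray(SD_CLASS_LABELS, dtype=object)[idx]


def region_aggregate(
    households: pd.DataFrame, level: str, flag: str
) -> pd.DataFrame:
    """Per-region prevalence of a household flag, with an SD class.

    Parameters
    ----------
    households
        Must carry ``commune_id`` and ``county_id`` columns plus the
        0/1 ``flag`` column.
    level
        ``'commune'`` or ``'county'``.

    Empty regions cannot occur (regions enter through their households);
    a ``n_households`` column lets callers drop sparse regions.
    """
    if level not in ("commune", "county"):
        raise ValueError("level must be 'commune' or 'county'")
    key = f"{level}_id"
    grouped = households.groupby(key, sort=True)[flag]
    out = pd.DataFrame(
        {"prevalence": grouped.mean(), "n_households": grouped.size()}
    )
    out["sd_class"] = sd_classes(out["prevalence"].to_numpy())
    return out


def cumulative_need(
    flags: pd.DataFrame, include: list[str] | tuple[str, ...]
) -> pd.Series:
    """Per-household count of adverse flags among the included set."""
    include = list(include)
    if not include:
        raise ValueError("include set must be non-empty")
    missing = [c for c in include if c not in flags.columns]
    if missing:
        raise ValueError(f"unknown flag column(s): {', '.join(missing)}")
    return flags[include].astype(int).sum(axis=1).rename("cumulative_need")


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional multiple-testing switch)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask
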