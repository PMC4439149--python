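"""Global Moran's I and local Getis-Ord Gi* over fixed distance bands.

Neighbourhoods are binary fixed-distance bands on cell centroids: w_ij = 1
iff 0 < d(i, j) <= band (Euclidean metres).  Moran's I uses self-exclusive
weights and, by default, the randomization (permutation) variance for its
z-score; Gi* is the self-inclusive z-form local statistic.  Both are
computed from first principles — the statistics are the point of this
module, not a wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

DEFAULT_BANDS = (125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0)


@dataclass
class SpatialWeights:
    """Binary symmetric distance-band weights on n points.

    pairs_i/pairs_j hold each unordered neighbour pair once (i < j).
    ``include_self`` marks whether w_ii = 1 (Gi* convention) — the pair
    lists never contain self-pairs; consumers add the self term.
    """

    n: int
    band_m: float
    pairs_i: np.ndarray
    pairs_j: np.ndarray
    include_self: bool = False

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour count per point, excluding self."""
        deg = np.bincount(self.pairs_i, minlength=self.n)
        deg += np.bincount(self.pairs_j, minlength=self.n)
        return deg

    @property
    def s0(self) -> float:
        """Sum of all off-diagonal weights."""
        return 2.0 * len(self.pairs_i)

    @property
    def n_isolates(self) -> int:
        return int((self.degrees == 0).sum())

    def neighbor_sum(self, values: np.ndarray) -> np.ndarray:
        """Per-point sum of neighbour values (self excluded)."""
        out = np.zeros(self.n)
        np.add.at(out, self.pairs_i, values[self.pairs_j])
        np.add.at(out, self.pairs_j, values[self.pairs_i])
        return out


def build_weights(cell_centroids: np.ndarray, band_m: float,
                  include_self: bool = False) -> SpatialWeights:
    """Fixed-distance-band binary weights from centroid coordinates."""
    pts = np.asarray(cell_centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be (n, 2)")
    if len(pts) < 2:
        raise ValueError("need at least two cells")
    if band_m <= 0:
        raise ValueError("band must be positive")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(band_m, output_type="ndarray")
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    return SpatialWeights(n=len(pts), band_m=float(band_m),
                          pairs_i=pairs[:, 0].astype(int),
                          pairs_j=pairs[:, 1].astype(int),
                          include_self=include_self)


# ---------------------------------------------------------------------------
# global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    band_m: float
    I: float
    expected: float
    variance: float
    z: float
    p: float
    n: int
    n_isolates: int
    variance_assumption: str = "randomization"


def _moran_core(z: np.ndarray, wi: np.ndarray, wj: np.ndarray,
                w: np.ndarray | None) -> tuple[float, float, float, float]:
    """Returns (I, S0, S1, S2) for centred values z and pair lists.

    ``w`` holds per-pair weights for style "W" (asymmetric: w[k, 0] is
    w_ij, w[k, 1] is w_ji); None means binary weight 1 both ways.
    """
    n = len(z)
    if w is None:
        s0 = 2.0 * len(wi)
        cross = 2.0 * float(np.sum(z[wi] * z[wj]))
        s1 = 2.0 * s0  # sum over ordered pairs of (w_ij + w_ji)^2 / 2, binary
        deg = np.bincount(wi, minlength=n) + np.bincount(wj, minlength=n)
        s2 = float(np.sum((2.0 * deg) ** 2))
    else:
        s0 = float(np.sum(w))
        cross = float(np.sum((w[:, 0] + w[:, 1]) * z[wi] * z[wj]))
        s1 = float(np.sum((w[:, 0] + w[:, 1]) ** 2))
        row = np.zeros(n); col = np.zeros(n)
        np.add.at(row, wi, w[:, 0]); np.add.at(col, wj, w[:, 0])
        np.add.at(row, wj, w[:, 1]); np.add.at(col, wi, w[:, 1])
        s2 = float(np.sum((row + col) ** 2))
    m2 = float(np.sum(z * z))
    I = (n / s0) * cross / m2
    return I, s0, s1, s2


def global_morans_i(values: np.ndarray, weights: SpatialWeights,
                    variance: str = "randomization",
                    style: str = "B") -> MoranResult:
    """Global Moran's I with analytic null inference.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    E[I] = -1/(n-1), with variance under the randomization (permutation)
    assumption by default ("normality" optional).  Style "B" keeps binary
    weights; "W" row-standardizes (w_ij = 1/deg_i).  Isolated cells are
    dropped from the statistic with their count reported.
    """
    if weights.include_self:
        raise ValueError("Moran's I requires self-exclusive weights")
    if variance not in {"randomization", "normality"}:
        raise ValueError("variance must be 'randomization' or 'normality'")
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values not aligned with weights")

    deg = weights.degrees
    keep = deg > 0
    n_iso = int((~keep).sum())
    if keep.sum() < 4:
        raise ValueError("fewer than 4 connected cells in this band")
    # relabel pairs onto the kept subset (isolates carry no pairs)
    relabel = np.full(weights.n, -1)
    relabel[keep] = np.arange(keep.sum())
    wi = relabel[weights.pairs_i]
    wj = relabel[weights.pairs_j]
    x = x[keep]
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("zero variance: values are constant")
    z = x - x.mean()

    w = None
    if style == "W":
        d = deg[keep].astype(float)
        w = np.column_stack([1.0 / d[wi], 1.0 / d[wj]])
    elif style != "B":
        raise ValueError("style must be 'B' (binary) or 'W' (row-standardized)")

    I, s0, s1, s2 = _moran_core(z, wi, wj, w)
    e = -1.0 / (n - 1)
    if variance == "normality":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e * e
    else:
        m2 = np.sum(z * z) / n
        b2 = (np.sum(z ** 4) / n) / (m2 * m2)
        num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
               - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e * e
    if not var > 1e-15:
        raise ValueError("null variance not positive (degenerate "
                         "neighbourhood graph at this band)")
    zscore = (I - e) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(band_m=weights.band_m, I=float(I), expected=float(e),
                       variance=float(var), z=float(zscore), p=float(p),
                       n=n, n_isolates=n_iso, variance_assumption=variance)


def morans_profile(values: np.ndarray, centroids: np.ndarray,
                   bands: tuple[float, ...] = DEFAULT_BANDS,
                   variance: str = "randomization", style: str = "B"
                   ) -> tuple[list[MoranResult], dict[float, str]]:
    """Moran's I across a ladder of distance bands.

    Bands where the statistic is undefined (all isolates, constant values)
    are collected in the error map rather than raising.
    """
    results: list[MoranResult] = []
    errors: dict[float, str] = {}
    for band in bands:
        try:
            w = build_weights(centroids, band, include_self=False)
            results.append(global_morans_i(values, w, variance=variance,
                                           style=style))
        except ValueError as exc:
            errors[float(band)] = str(exc)
    return results, errors


def profile_to_frame(results: list[MoranResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "band_m": r.band_m, "I": r.I, "expected": r.expected,
        "variance": r.variance, "z": r.z, "p": r.p,
        "n": r.n, "n_isolates": r.n_isolates,
    } for r in results])


# ---------------------------------------------------------------------------
# local Getis-Ord Gi*
# ---------------------------------------------------------------------------

@dataclass
class GiResult:
    """Per-cell Gi* z-scores aligned with the input value vector."""

    gi_star: np.ndarray
    band_m: float
    n: int
    star: bool = True


def local_gi_star(values: np.ndarray, weights: SpatialWeights,
                  star: bool = True) -> GiResult:
    """Local Getis-Ord statistic in z-score form per cell.

    Gi* (default) includes the focal cell in its own neighbourhood — the
    behaviour of standard GIS hot-spot tooling; ``star=False`` computes the
    plain Gi, which excludes it.  With binary weights,

        Gi* = (S_i - xbar W_i) / (S sqrt[(n W_i - W_i^2) / (n - 1)])

    where S_i is the neighbourhood sum, W_i the neighbourhood size, and
    xbar, S the global mean and population standard deviation.
    """
    x = np.asarray(values, dtype=float)
    n = weights.n
    if len(x) != n:
        raise ValueError("values not aligned with weights")
    if n <= 3:
        raise ValueError("need more than 3 cells")
    nsum = weights.neighbor_sum(x)
    deg = weights.degrees.astype(float)
    if star:
        if not weights.include_self:
            raise ValueError("Gi* requires include_self weights")
        s_i = nsum + x
        w_i = deg + 1.0
        xbar = x.mean()
        s = np.sqrt(np.mean(x * x) - xbar * xbar)
        if s == 0:
            raise ValueError("zero variance: values are constant")
        num = s_i - xbar * w_i
        den = s * np.sqrt((n * w_i - w_i ** 2) / (n - 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(den > 0, num / den, np.nan)
    else:
        # plain Gi: focal value excluded from mean and SD as well
        m = n - 1.0
        xbar_i = (x.sum() - x) / m
        var_i = (np.sum(x * x) - x * x) / m - xbar_i ** 2
        s_loc = np.sqrt(np.maximum(var_i, 0.0))
        num = nsum - xbar_i * deg
        den = s_loc * np.sqrt((m * deg - deg ** 2) / (m - 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(den > 0, num / den, np.nan)
    return GiResult(gi_star=g, band_m=weights.band_m, n=n, star=star)
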