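"""KDE-based dequantization of banded variables.

The empirical distribution of each continuous variable is estimated per
stratum with a Gaussian-kernel KDE (bandwidth from statsmodels
``KDEMultivariate``, normal-reference rule); the CDF is evaluated on a
discretised grid, giving a probability mass per grid subinterval.  Banded
values are regenerated by two-stage sampling: pick a subinterval inside the
band proportionally to its mass, then draw uniformly inside it.  Correlated
pairs use rectangle masses obtained from the joint CDF by
inclusion–exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

POOLED = "__pooled__"
MIN_STRATUM_N = 30


def _normal_reference_bw(x: np.ndarray) -> float:
    """Scott/normal-reference bandwidth via statsmodels KDEMultivariate."""
    from statsmodels.nonparametric.kernel_density import KDEMultivariate

    if np.std(x) == 0:
        return 0.0
    kde = KDEMultivariate(data=[x], var_type="c", bw="normal_reference")
    return float(kde.bw[0])


def _kde_cdf(x: np.ndarray, bw: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel KDE CDF on ``grid``: mean_i Phi((g - x_i)/h)."""
    if bw <= 0:  # degenerate: point mass
        return (grid[:, None] >= x[None, :]).mean(1)
    return ndtr((grid[:, None] - x[None, :]) / bw).mean(1)


@dataclass
class StratumGrid:
    grid: np.ndarray          # strictly increasing grid points
    cdf: np.ndarray           # KDE CDF at grid points (normalized to [0,1])
    bandwidth: float
    n_obs: int
    pooled_fallback: bool = False

    def interval_masses(self) -> np.ndarray:
        m = np.diff(self.cdf)
        m = np.clip(m, 0, None)
        s = m.sum()
        return m / s if s > 0 else m

    def cdf_at(self, x) -> np.ndarray:
        return np.interp(x, self.grid, self.cdf, left=0.0, right=1.0)


@dataclass
class KdeGrid:
    """Stratified grid-evaluated distribution for one variable (or a pair)."""

    variables: tuple[str, ...]
    strata: dict = field(default_factory=dict)   # key -> StratumGrid | JointStratumGrid
    fallback_count: int = 0
    zero_mass_fallbacks: int = 0

    def stratum(self, key):
        key = _norm_key(key)
        return self.strata.get(key, self.strata[POOLED])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"variables": list(self.variables), "strata": {}}
        for k, s in self.strata.items():
            if isinstance(s, JointStratumGrid):
                d["strata"][k] = {
                    "joint": True,
                    "grid_x": s.grid_x.tolist(), "grid_y": s.grid_y.tolist(),
                    "cdf": s.cdf.tolist(), "bandwidths": list(s.bandwidths),
                    "n_obs": s.n_obs, "pooled_fallback": s.pooled_fallback,
                }
            else:
                d["strata"][k] = {
                    "joint": False,
                    "grid": s.grid.tolist(), "cdf": s.cdf.tolist(),
                    "bandwidth": s.bandwidth, "n_obs": s.n_obs,
                    "pooled_fallback": s.pooled_fallback,
                }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KdeGrid":
        out = cls(variables=tuple(d["variables"]))
        for k, s in d["strata"].items():
            if s["joint"]:
                out.strata[k] = JointStratumGrid(
                    np.asarray(s["grid_x"]), np.asarray(s["grid_y"]),
                    np.asarray(s["cdf"]), tuple(s["bandwidths"]),
                    s["n_obs"], s["pooled_fallback"],
                )
            else:
                out.strata[k] = StratumGrid(
                    np.asarray(s["grid"]), np.asarray(s["cdf"]),
                    s["bandwidth"], s["n_obs"], s["pooled_fallback"],
                )
        return out


def _norm_key(key) -> str:
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return str(key)


def _make_grid(values: np.ndarray, resolution: Optional[float],
               n_points: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    pad = 0.0
    if resolution is not None and resolution > 0:
        start = np.floor(lo / resolution) * resolution
        stop = np.ceil(hi / resolution) * resolution
        grid = np.arange(start, stop + resolution / 2, resolution)
        if len(grid) > 4 * n_points:  # cap excessively fine grids
            grid = np.linspace(start, stop, 4 * n_points)
    else:
        grid = np.linspace(lo - pad, hi + pad, n_points)
    return grid.astype(float)


def fit_marginal_kde(
    values: Sequence[float],
    strata_labels: Optional[Sequence] = None,
    grid_resolution: Optional[float] = None,
    grid_points: int = 200,
    min_stratum_n: int = MIN_STRATUM_N,
    variable: str = "value",
) -> KdeGrid:
    """Per-stratum CDF on a grid; small strata fall back to pooled data."""
    values = np.asarray(values, float)
    keep = np.isfinite(values)
    values = values[keep]
    if values.size == 0:
        raise ValueError("no observations")
    if strata_labels is None:
        labels = np.array([POOLED] * len(values))
    else:
        labels = np.asarray([_norm_key(k) for k in strata_labels])[keep]

    out = KdeGrid(variables=(variable,))
    grid = _make_grid(values, grid_resolution, grid_points)
    pooled_bw = _normal_reference_bw(values)
    pooled_cdf = _normalize_cdf(_kde_cdf(values, pooled_bw, grid))
    out.strata[POOLED] = StratumGrid(grid, pooled_cdf, pooled_bw, len(values))

    for key in sorted(set(labels) - {POOLED}):
        x = values[labels == key]
        if len(x) < min_stratum_n:
            out.strata[key] = StratumGrid(grid, pooled_cdf, pooled_bw,
                                          len(x), pooled_fallback=True)
            out.fallback_count += 1
            continue
        bw = _normal_reference_bw(x)
        out.strata[key] = StratumGrid(grid, _normalize_cdf(_kde_cdf(x, bw, grid)),
                                      bw, len(x))
    return out


def _normalize_cdf(cdf: np.ndarray) -> np.ndarray:
    cdf = np.maximum.accumulate(np.clip(cdf, 0, 1))
    lo, hi = cdf[0], cdf[-1]
    if hi > lo:
        cdf = (cdf - lo) / (hi - lo)
    return cdf


# ---------------------------------------------------------------------------
# joint grids
# ---------------------------------------------------------------------------


@dataclass
class JointStratumGrid:
    grid_x: np.ndarray
    grid_y: np.ndarray
    cdf: np.ndarray               # (len(grid_x), len(grid_y))
    bandwidths: tuple[float, float]
    n_obs: int
    pooled_fallback: bool = False

    def cdf_at(self, x, y) -> float:
        """Bilinear interpolation of the joint CDF, clamped to the grid."""
        gx, gy = self.grid_x, self.grid_y
        x = np.clip(x, gx[0], gx[-1])
        y = np.clip(y, gy[0], gy[-1])
        i = np.clip(np.searchsorted(gx, x) - 1, 0, len(gx) - 2)
        j = np.clip(np.searchsorted(gy, y) - 1, 0, len(gy) - 2)
        tx = (x - gx[i]) / (gx[i + 1] - gx[i])
        ty = (y - gy[j]) / (gy[j + 1] - gy[j])
        c = self.cdf
        return (
            c[i, j] * (1 - tx) * (1 - ty)
            + c[i + 1, j] * tx * (1 - ty)
            + c[i, j + 1] * (1 - tx) * ty
            + c[i + 1, j + 1] * tx * ty
        )


def fit_joint_kde(
    x: Sequence[float],
    y: Sequence[float],
    strata_labels: Optional[Sequence] = None,
    grid_points: int = 60,
    min_stratum_n: int = MIN_STRATUM_N,
    variables: tuple[str, str] = ("x", "y"),
    max_fit_n: int = 5000,
    seed: int = 0,
) -> KdeGrid:
    """Joint Gaussian-KDE CDF on a product grid, per stratum.

    The CDF of a product Gaussian kernel factorizes, so the grid evaluation
    is a single matrix product of per-axis Phi tables.  Fits are subsampled
    to ``max_fit_n`` points for large strata.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no complete pairs")
    if strata_labels is None:
        labels = np.array([POOLED] * len(x))
    else:
        labels = np.asarray([_norm_key(k) for k in strata_labels])[keep]

    gx = np.linspace(float(x.min()), float(x.max()), grid_points)
    gy = np.linspace(float(y.min()), float(y.max()), grid_points)
    rng = np.random.default_rng(seed)

    def fit(xs, ys) -> JointStratumGrid:
        n = len(xs)
        if n > max_fit_n:
            idx = rng.choice(n, max_fit_n, replace=False)
            xs, ys = xs[idx], ys[idx]
        bx, by = _normal_reference_bw(xs), _normal_reference_bw(ys)
        if bx <= 0 or by <= 0:
            px = (gx[:, None] >= xs[None, :]).astype(float)
            py = (gy[:, None] >= ys[None, :]).astype(float)
        else:
            px = ndtr((gx[:, None] - xs[None, :]) / bx)
            py = ndtr((gy[:, None] - ys[None, :]) / by)
        cdf = px @ py.T / len(xs)
        # normalize so the grid corners span [0, 1]
        lo, hi = cdf[0, 0], cdf[-1, -1]
        if hi > lo:
            cdf = np.clip((cdf - lo) / (hi - lo), 0, 1)
        return JointStratumGrid(gx, gy, cdf, (bx, by), n)

    out = KdeGrid(variables=variables)
    pooled = fit(x, y)
    out.strata[POOLED] = pooled
    for key in sorted(set(labels) - {POOLED}):
        m = labels == key
        if m.sum() < min_stratum_n:
            out.strata[key] = JointStratumGrid(
                pooled.grid_x, pooled.grid_y, pooled.cdf, pooled.bandwidths,
                int(m.sum()), pooled_fallback=True,
            )
            out.fallback_count += 1
        else:
            out.strata[key] = fit(x[m], y[m])
    return out


def joint_interval_mass(joint: JointStratumGrid,
                        x_interval: tuple[float, float],
                        y_interval: tuple[float, float]) -> float:
    """Rectangle probability F(b,d) - F(a,d) - F(b,c) + F(a,c), clipped at 0."""
    a, b = x_interval
    c, d = y_interval
    m = (joint.cdf_at(b, d) - joint.cdf_at(a, d)
         - joint.cdf_at(b, c) + joint.cdf_at(a, c))
    return float(max(m, 0.0))


# ---------------------------------------------------------------------------
# two-stage sampling
# ---------------------------------------------------------------------------


def _band_breakpoints(band: tuple[float, float], grid: np.ndarray) -> np.ndarray:
    lo, hi = band
    inner = grid[(grid > lo) & (grid < hi)]
    return np.concatenate([[lo], inner, [hi]])


def sample_within_band(band: tuple[float, float], kde_grid: KdeGrid,
                       stratum, rng: np.random.Generator) -> float:
    """Two-stage draw: subinterval by KDE mass, then uniform inside it."""
    sg = kde_grid.stratum(stratum)
    bp = _band_breakpoints(band, sg.grid)
    masses = np.clip(np.diff(sg.cdf_at(bp)), 0, None)
    total = masses.sum()
    if total <= 0:
        kde_grid.zero_mass_fallbacks += 1
        return float(rng.uniform(band[0], band[1]))
    j = rng.choice(len(masses), p=masses / total)
    return float(rng.uniform(bp[j], bp[j + 1]))


def sample_within_band_many(bands: Sequence[tuple[float, float]],
                            kde_grid: KdeGrid, strata: Sequence,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized helper grouping draws by (stratum, band)."""
    bands = list(bands)
    strata = [_norm_key(s) for s in strata]
    out = np.empty(len(bands))
    from collections import defaultdict

    groups: dict = defaultdict(list)
    for i, (b, s) in enumerate(zip(bands, strata)):
        groups[(s, b)].append(i)
    for (s, band), idxs in groups.items():
        sg = kde_grid.stratum(s)
        bp = _band_breakpoints(band, sg.grid)
        masses = np.clip(np.diff(sg.cdf_at(bp)), 0, None)
        total = masses.sum()
        if total <= 0:
            kde_grid.zero_mass_fallbacks += len(idxs)
            out[idxs] = rng.uniform(band[0], band[1], size=len(idxs))
            continue
        js = rng.choice(len(masses), p=masses / total, size=len(idxs))
        out[idxs] = rng.uniform(bp[js], bp[js + 1])
    return out


def sample_joint_within_bands(x_band: tuple[float, float],
                              y_band: tuple[float, float],
                              joint_grid: KdeGrid, rng: np.random.Generator,
                              stratum=POOLED) -> tuple[float, float]:
    """Joint cell chosen by inclusion–exclusion mass inside the band
    rectangle; uniform draw inside the chosen cell."""
    sg = joint_grid.stratum(stratum)
    bpx = _band_breakpoints(x_band, sg.grid_x)
    bpy = _band_breakpoints(y_band, sg.grid_y)
    FX, FY = np.meshgrid(bpx, bpy, indexing="ij")
    F = sg.cdf_at(FX, FY)
    cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    cell = np.clip(cell, 0, None)
    total = cell.sum()
    if total <= 0:
        joint_grid.zero_mass_fallbacks += 1
        return (float(rng.uniform(*x_band)), float(rng.uniform(*y_band)))
    flat = rng.choice(cell.size, p=(cell / total).ravel())
    i, j = np.unravel_index(flat, cell.shape)
    return (float(rng.uniform(bpx[i], bpx[i + 1])),
            float(rng.uniform(bpy[j], bpy[j + 1])))
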