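"""Ancestry surfaces: kriged rasters, Simpson's diversity, edges, transects.

Per-cluster ancestry proportions are interpolated over a regular grid by
ordinary kriging with a WLS-fitted exponential variogram (inverse-distance
weighting is available as a fallback).  The K layers are clamped and
renormalized per cell, then reduced to a single layer with Simpson's
diversity index D = 1 − Σ_k p_k², whose high-valued ridges mark "genetic
edges" — zones of rapid ancestry turnover between populations.  Because D
depends only on local ancestry composition, it is far less distorted by
long-distance translocation than pairwise-distance interpolations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as ndi_label
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RasterSpec",
    "Raster",
    "Variogram",
    "AncestrySurface",
    "EdgeSet",
    "Transect",
    "fit_variogram",
    "krige_points",
    "krige_layer",
    "idw_layer",
    "build_ancestry_surface",
    "simpson_surface",
    "extract_edges",
    "edge_displacement",
    "extract_transect",
    "write_esri_ascii",
    "read_esri_ascii",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0


@dataclass(frozen=True)
class RasterSpec:
    """Grid geometry: lower-left corner (km), cell size (km), shape.

    Row 0 of any values array on this spec is the *southernmost* row
    (y = y0 + cell/2); the ESRI ASCII writer flips to north-up on output.
    """

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.nrows < 1 or self.ncols < 1:
            raise ValueError("invalid raster geometry")

    @classmethod
    def from_points(
        cls, points: np.ndarray, n_cells_long: int = 200, pad_frac: float = 0.05
    ) -> "RasterSpec":
        """Grid covering the point extent, ``n_cells_long`` on the longest axis."""
        points = np.asarray(points, dtype=float)
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        span = hi - lo
        pad = pad_frac * span.max()
        lo, hi = lo - pad, hi + pad
        cell = (hi - lo).max() / n_cells_long
        ncols = max(1, int(np.ceil((hi[0] - lo[0]) / cell)))
        nrows = max(1, int(np.ceil((hi[1] - lo[1]) / cell)))
        return cls(float(lo[0]), float(lo[1]), float(cell), nrows, ncols)

    def cell_centers(self) -> np.ndarray:
        """(nrows*ncols, 2) x/y coordinates of cell centers, row-major from south."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack((gx.ravel(), gy.ravel()))


@dataclass
class Raster:
    """One layer of values on a :class:`RasterSpec`; NaN marks no-data."""

    spec: RasterSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError("values shape does not match raster spec")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return ~np.isnan(self.values)


@dataclass
class Variogram:
    """Exponential semivariogram γ(d) = nugget + sill·(1 − exp(−d/range))."""

    nugget: float
    sill: float
    range_: float
    bin_centers: np.ndarray | None = None
    bin_gamma: np.ndarray | None = None
    bin_counts: np.ndarray | None = None

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        gamma = self.nugget + self.sill * (1.0 - np.exp(-d / self.range_))
        return np.where(d > 0, gamma, 0.0)


@dataclass
class AncestrySurface:
    """K co-registered ancestry-proportion layers summing to 1 per cell."""

    layers: list[Raster]

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("an ancestry surface needs at least 2 layers")
        spec = self.layers[0].spec
        if any(l.spec != spec for l in self.layers):
            raise ValueError("layers must share a raster spec")

    @property
    def K(self) -> int:
        return len(self.layers)

    @property
    def spec(self) -> RasterSpec:
        return self.layers[0].spec

    def stack(self) -> np.ndarray:
        """(K, nrows, ncols) array."""
        return np.stack([l.values for l in self.layers])


@dataclass
class EdgeSet:
    """High-diversity cells, their ridge subset, and connected components."""

    cells: np.ndarray  # bool (nrows, ncols): above-threshold cells
    ridge: np.ndarray  # bool: above-threshold cells that are local maxima
    labels: np.ndarray  # int component labels (0 = background)
    areas: dict[int, int] = field(default_factory=dict)
    threshold: float = float("nan")


@dataclass
class Transect:
    """A corridor across a genetic edge with parental and intermediate members."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    half_width: float
    kA: int
    kB: int
    members: np.ndarray  # indices into the sample arrays
    parental_a: np.ndarray
    parental_b: np.ndarray
    intermediate: np.ndarray


# ---------------------------------------------------------------------------
# Variogram fitting and kriging


def fit_variogram(
    points: np.ndarray, values: np.ndarray, n_bins: int = 15
) -> Variogram:
    """Fit an exponential variogram to the empirical semivariance.

    Pairwise semivariances ½(v_a − v_b)² are averaged in ``n_bins`` equal
    distance bins up to half the maximum pairwise distance, then the model
    is fit by least squares weighted by the bin pair counts.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 points to fit a variogram")
    d = pdist(points)
    if d.max() == 0:
        raise ValueError("all points are coincident")
    sv = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    dmax = d.max() / 2.0
    edges = np.linspace(0.0, dmax, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    in_range = d <= dmax
    centers, gamma, counts = [], [], []
    for b in range(n_bins):
        sel = in_range & (idx == b)
        if sel.sum() == 0:
            continue
        centers.append(d[sel].mean())
        gamma.append(sv[sel].mean())
        counts.append(int(sel.sum()))
    centers = np.array(centers)
    gamma = np.array(gamma)
    counts = np.array(counts, dtype=float)

    var_v = max(values.var(), 1e-12)

    def resid(theta):
        n, s, r = theta
        model = n + s * (1.0 - np.exp(-centers / r))
        return np.sqrt(counts) * (model - gamma)

    x0 = np.array([max(gamma[0] * 0.5, 0.0), var_v, dmax / 3.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
    )
    n, s, r = sol.x
    return Variogram(float(n), float(s), float(r), centers, gamma, counts)


def _ok_weights(
    pts: np.ndarray, target: np.ndarray, vgm: Variogram
) -> np.ndarray:
    """Solve the ordinary-kriging system for one target location."""
    n = len(pts)
    gamma_mat = vgm(squareform(pdist(pts)))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_mat
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = vgm(np.linalg.norm(pts - target, axis=1))
    b[n] = 1.0
    return np.linalg.solve(A, b)[:n]


def krige_points(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Variogram,
    targets: np.ndarray,
    n_neighbors: int = 32,
) -> np.ndarray:
    """Ordinary-kriging predictions at arbitrary target coordinates.

    Each target is predicted from its ``n_neighbors`` nearest observations
    by solving the OK system with the unbiasedness constraint.  With a zero
    nugget the predictor interpolates exactly at data coordinates.
    Duplicate observation points make the system singular; they are
    jittered slightly and retried once before erroring.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if np.ptp(values) == 0.0:
        return np.full(len(targets), float(values[0]))
    k = min(n_neighbors, len(points))
    tree = cKDTree(points)
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr.reshape(len(targets), k))
    scale = max(pdist(points).max(), 1.0)
    out = np.empty(len(targets))
    rng = np.random.default_rng(0)
    for i, target in enumerate(targets):
        idx = nbr[i]
        pts = points[idx]
        try:
            w = _ok_weights(pts, target, variogram)
        except np.linalg.LinAlgError:
            jitter = rng.normal(0.0, 1e-9 * scale, size=pts.shape)
            try:
                w = _ok_weights(pts + jitter, target, variogram)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"singular kriging system at target {i} (duplicate points?)"
                ) from exc
        out[i] = w @ values[idx]
    return out


def krige_layer(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Variogram,
    raster_spec: RasterSpec,
    n_neighbors: int = 32,
) -> Raster:
    """Ordinary kriging onto a raster using local nearest-neighbor systems."""
    out = krige_points(
        points, values, variogram, raster_spec.cell_centers(), n_neighbors
    )
    return Raster(raster_spec, out.reshape(raster_spec.nrows, raster_spec.ncols))


def idw_layer(
    points: np.ndarray,
    values: np.ndarray,
    raster_spec: RasterSpec,
    power: float = 2.0,
) -> Raster:
    """Inverse-distance-weighted interpolation (fallback for kriging)."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = raster_spec.cell_centers()
    out = np.empty(len(targets))
    for i, t in enumerate(targets):
        d = np.linalg.norm(points - t, axis=1)
        if d.min() < 1e-12:
            out[i] = values[int(np.argmin(d))]
        else:
            w = d**-power
            out[i] = (w @ values) / w.sum()
    return Raster(raster_spec, out.reshape(raster_spec.nrows, raster_spec.ncols))


# ---------------------------------------------------------------------------
# Ancestry and diversity surfaces


def build_ancestry_surface(
    Q: np.ndarray,
    coords: np.ndarray,
    raster_spec: RasterSpec | None = None,
    method: str = "ok",
    n_neighbors: int = 32,
    buffer_km: float | None = None,
    n_cells_long: int = 200,
) -> AncestrySurface:
    """Interpolate each ancestry component and renormalize per cell.

    Each cluster's q_·k is interpolated independently, clamped to [0, 1],
    and the K layers are renormalized to sum to 1 per cell.  Cells farther
    than ``buffer_km`` (default 2× the mean nearest-neighbor spacing of the
    samples) from any sample are masked to avoid extrapolation artifacts at
    the sampling edge.
    """
    Q = np.asarray(Q, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if Q.ndim != 2 or Q.shape[1] < 2:
        raise ValueError("Q must be N×K with K ≥ 2 (diversity is undefined at K=1)")
    if raster_spec is None:
        raster_spec = RasterSpec.from_points(coords, n_cells_long=n_cells_long)
    layers = []
    for k in range(Q.shape[1]):
        if method == "ok":
            vgm = fit_variogram(coords, Q[:, k])
            layer = krige_layer(coords, Q[:, k], vgm, raster_spec, n_neighbors)
        elif method == "idw":
            layer = idw_layer(coords, Q[:, k], raster_spec)
        else:
            raise ValueError("method must be 'ok' or 'idw'")
        layers.append(layer)
    stack = np.clip(np.stack([l.values for l in layers]), 0.0, 1.0)
    total = stack.sum(axis=0)
    stack = np.where(total > 0, stack / np.maximum(total, 1e-12), 1.0 / Q.shape[1])

    if buffer_km is None:
        tree = cKDTree(coords)
        if len(coords) > 1:
            nn_d, _ = tree.query(coords, k=2)
            buffer_km = 2.0 * float(nn_d[:, 1].mean())
        else:
            buffer_km = 2.0 * raster_spec.cell
    tree = cKDTree(coords)
    d_cell, _ = tree.query(raster_spec.cell_centers())
    far = d_cell.reshape(raster_spec.nrows, raster_spec.ncols) > buffer_km
    stack[:, far] = np.nan
    return AncestrySurface([Raster(raster_spec, s) for s in stack])


def simpson_surface(surface: AncestrySurface) -> Raster:
    """Simpson's diversity D = 1 − Σ_k p_k² per cell.

    D is 0 where one ancestry dominates completely and peaks at 1 − 1/K
    where all K ancestries are equally represented — the signature of a
    transition zone between populations.
    """
    stack = surface.stack()
    return Raster(surface.spec, 1.0 - np.nansum(stack**2, axis=0) + np.where(
        np.isnan(stack[0]), np.nan, 0.0))


def extract_edges(D: Raster, percentile: float = 90.0) -> EdgeSet:
    """Threshold the diversity surface and extract ridge cells and components.

    Cells at or above the given percentile of unmasked D form the edge
    candidate set; 8-connected components are labeled, and ridge cells are
    the candidates that are local maxima along their gradient direction
    (a one-cell non-maximum suppression).
    """
    vals = D.values
    finite = D.mask
    if not finite.any():
        raise ValueError("diversity surface is fully masked")
    v = vals[finite]
    if np.ptp(v) == 0.0:
        warnings.warn("flat diversity surface: no edges", stacklevel=2)
        empty = np.zeros_like(vals, dtype=bool)
        return EdgeSet(empty, empty.copy(), np.zeros_like(vals, dtype=int), {},
                       float(v[0]))
    thr = float(np.percentile(v, percentile))
    cells = finite & (vals >= thr)

    # gradient-direction non-maximum suppression
    filled = np.where(finite, vals, np.nanmin(v))
    gy, gx = np.gradient(filled)
    ridge = np.zeros_like(cells)
    nrows, ncols = vals.shape
    rr, cc = np.nonzero(cells)
    for r, c in zip(rr, cc):
        norm = np.hypot(gx[r, c], gy[r, c])
        if norm == 0:
            ridge[r, c] = True
            continue
        dr = int(np.round(gy[r, c] / norm))
        dc = int(np.round(gx[r, c] / norm))
        ok = True
        for sr, sc in ((r + dr, c + dc), (r - dr, c - dc)):
            if 0 <= sr < nrows and 0 <= sc < ncols and finite[sr, sc]:
                if vals[sr, sc] > vals[r, c]:
                    ok = False
                    break
        ridge[r, c] = ok
    labels, n_comp = ndi_label(cells, structure=np.ones((3, 3), dtype=int))
    areas = {i: int((labels == i).sum()) for i in range(1, n_comp + 1)}
    return EdgeSet(cells, ridge, labels, areas, thr)


def edge_displacement(a: EdgeSet, b: EdgeSet) -> float:
    """Median distance (in cells) from ridge cells of ``a`` to the nearest of ``b``."""
    pa = np.argwhere(a.ridge)
    pb = np.argwhere(b.ridge)
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    tree = cKDTree(pb)
    d, _ = tree.query(pa)
    return float(np.median(d))


# ---------------------------------------------------------------------------
# Transects


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def extract_transect(
    Q: np.ndarray,
    coords: np.ndarray,
    kA: int,
    kB: int,
    endpoints: tuple[tuple[float, float], tuple[float, float]],
    half_width: float,
    q_min: float = 0.80,
) -> Transect:
    """Collect individuals in a corridor and split them by ancestry threshold.

    Members lie within ``half_width`` km of the endpoint segment; those with
    q_kA ≥ ``q_min`` are parental-A, q_kB ≥ ``q_min`` parental-B, and the
    rest intermediate.  Errors if either parental set is empty and warns if
    either has fewer than 5 individuals.
    """
    Q = np.asarray(Q, dtype=float)
    coords = np.asarray(coords, dtype=float)
    a = np.asarray(endpoints[0], dtype=float)
    b = np.asarray(endpoints[1], dtype=float)
    d = _point_segment_distance(coords, a, b)
    members = np.flatnonzero(d <= half_width)
    qa = Q[members, kA]
    qb = Q[members, kB]
    is_a = qa >= q_min
    is_b = (qb >= q_min) & ~is_a
    parental_a = members[is_a]
    parental_b = members[is_b]
    intermediate = members[~is_a & ~is_b]
    if len(parental_a) == 0 or len(parental_b) == 0:
        raise ValueError(
            f"transect has no parental individuals on one side "
            f"(A: {len(parental_a)}, B: {len(parental_b)}) at q_min={q_min}"
        )
    if min(len(parental_a), len(parental_b)) < 5:
        warnings.warn("fewer than 5 parental individuals on one side", stacklevel=2)
    return Transect(
        (tuple(a), tuple(b)), half_width, kA, kB, members,
        parental_a, parental_b, intermediate,
    )


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)


def write_esri_ascii(raster: Raster, path: str) -> None:
    """Write a raster as an ESRI ASCII grid (north-up, NODATA -9999)."""
    spec = raster.spec
    vals = np.where(raster.mask, raster.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.x0:.6f}\n")
        fh.write(f"yllcorner {spec.y0:.6f}\n")
        fh.write(f"cellsize {spec.cell:.6f}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_esri_ascii(path: str) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_esri_ascii`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    spec = RasterSpec(
        header["xllcorner"], header["yllcorner"], header["cellsize"],
        int(header["nrows"]), int(header["ncols"]),
    )
    return Raster(spec, data)
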