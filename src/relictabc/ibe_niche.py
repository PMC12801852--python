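"""Climate-difference statistics: PCA, isolation-by-environment Mantel
tests, niche-overlap indices and a background randomization test.

The niche machinery is model-agnostic: any object with a ``fit(X)`` /
``predict(X)`` contract mapping occurrence climates to per-cell
suitabilities can drive the background test.  The default is a
Mahalanobis climate envelope — suitability = exp(-mahalanobis^2 / 2)
around the occurrences' climate mean — which keeps the test fully
computable offline.  Suitability rasters use the ESRI ASCII grid format.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
CLIMATE_PREFIX = "bio"


# ---------------------------------------------------------------------------
# occurrence tables

@dataclass
class ClimateOccurrenceTable:
    """Per-occurrence climate variables with region and coordinates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"occurrence_id", "region", "latitude", "longitude"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.table[self.climate_columns].isna().any().any():
            raise ValueError("missing climate values are not supported")
        lat, lon = self.table["latitude"], self.table["longitude"]
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates out of range")

    @property
    def climate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith(CLIMATE_PREFIX)]

    def climates(self, region: str | None = None) -> np.ndarray:
        df = self.table if region is None else self.table[self.table["region"] == region]
        return df[self.climate_columns].to_numpy(dtype=float)

    def coords(self, region: str | None = None) -> np.ndarray:
        df = self.table if region is None else self.table[self.table["region"] == region]
        return df[["latitude", "longitude"]].to_numpy(dtype=float)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ClimateOccurrenceTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PCA (correlation-based)

@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame        # variables x components
    scores: np.ndarray            # occurrences x components
    variance_fraction: np.ndarray
    dropped: tuple[str, ...] = ()


def climate_pca(table: ClimateOccurrenceTable | pd.DataFrame) -> PCAResult:
    """Correlation-based PCA of the climate variables.

    Variables are standardized (the variables mix units), constant
    variables are dropped with a warning, and each loading vector is
    signed so its largest-magnitude element is positive.
    """
    if isinstance(table, ClimateOccurrenceTable):
        df = table.table[table.climate_columns]
    else:
        df = table
    if len(df) < 3:
        raise ValueError("need >= 3 occurrences")
    if df.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    sd = df.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant variables: {list(dropped)}")
        df = df.drop(columns=list(dropped))
    z = (df - df.mean()) / df.std(ddof=1)
    u, s, vt = np.linalg.svd(z.to_numpy(dtype=float), full_matrices=False)
    # sign convention: largest-|.| loading element positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = s ** 2
    names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=names),
        scores=u * s,
        variance_fraction=var / var.sum(),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# distance matrices and Mantel tests

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def great_circle_ln_distance(coords: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """ln(great-circle distance in km + 1) between sites.

    The +1 km offset keeps identical coordinates at distance ln(1) = 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("coords must be (n >= 2, 2) of lat/lon")
    if (np.abs(coords[:, 0]) > 90).any() or (np.abs(coords[:, 1]) > 180).any():
        raise ValueError("invalid coordinates")
    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = haversine_km(*coords[i], *coords[j])
            out[i, j] = out[j, i] = np.log(d + 1.0)
    return DistanceMatrix(labels or [str(i) for i in range(n)], out, "ln-geographic")


def euclidean_distance_matrix(x: np.ndarray, labels: list[str] | None = None,
                              kind: str = "climatic") -> DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(np.asarray(x, dtype=float)))
    return DistanceMatrix(labels or [str(i) for i in range(len(d))], d, kind)


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero-variance distance triangle")
    return float((a * b).sum() / denom)


def mantel(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, alternative: str = "greater") -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    r is the Pearson correlation over the lower-triangle entries; the
    permutation null jointly permutes rows/columns of `a`.  One-tailed
    (positive association) by default, matching the IBE hypothesis.
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share labels and order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    r_obs = _pearson(_triangle(a.values), _triangle(b.values))
    bt = _triangle(b.values)
    rng = np.random.default_rng(seed)
    count = 0
    n = len(a.labels)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _pearson(_triangle(a.values[np.ix_(perm, perm)]), bt)
        if alternative == "greater":
            count += rp >= r_obs
        else:
            count += abs(rp) >= abs(r_obs)
    return r_obs, (1 + count) / (1 + n_perm)


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = np.sqrt((1 - r_ac ** 2) * (1 - r_bc ** 2))
    if denom == 0:
        raise ValueError("undefined partial correlation (|r| = 1 with control)")
    return float((r_ab - r_ac * r_bc) / denom)


def partial_mantel(a: DistanceMatrix, b: DistanceMatrix, c: DistanceMatrix,
                   n_perm: int = 10_000, seed: int = 0,
                   alternative: str = "greater") -> tuple[float, float]:
    """Partial Mantel r_AB.C with permutation of A; one-tailed by default.

    Typical use: A genetic (F_ST), B climatic Euclidean, C ln-geographic —
    isolation by environment controlling for geography.
    """
    if not (a.labels == b.labels == c.labels):
        raise ValueError("matrices must share labels and order")
    at, bt, ct = _triangle(a.values), _triangle(b.values), _triangle(c.values)
    r_bc = _pearson(bt, ct)
    r_obs = partial_correlation(_pearson(at, bt), _pearson(at, ct), r_bc)
    rng = np.random.default_rng(seed)
    count = 0
    n = len(a.labels)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ap = _triangle(a.values[np.ix_(perm, perm)])
        rp = partial_correlation(_pearson(ap, bt), _pearson(ap, ct), r_bc)
        if alternative == "greater":
            count += rp >= r_obs
        else:
            count += abs(rp) >= abs(r_obs)
    return r_obs, (1 + count) / (1 + n_perm)


def linearized_fst(fst: DistanceMatrix) -> DistanceMatrix:
    """F_ST / (1 - F_ST) (Rousset linearization), optional IBE input."""
    v = fst.values / np.clip(1.0 - fst.values, 1e-12, None)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(fst.labels, v, fst.kind + "-linearized")


# ---------------------------------------------------------------------------
# suitability rasters and niche overlap

@dataclass
class SuitabilityRaster:
    """ESRI-ASCII-grid-backed raster of non-negative suitabilities."""

    data: np.ndarray          # (nrows, ncols), nodata as np.nan internally
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        vals = self.data[~np.isnan(self.data)]
        if vals.size == 0 or not (vals > 0).any():
            raise ValueError("raster needs at least one positive cell")
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValueError("suitabilities must be finite and non-negative")

    def co_registered_with(self, other: "SuitabilityRaster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def write_asc(self, path: str | Path) -> None:
        d = np.where(np.isnan(self.data), self.nodata_value, self.data)
        header = (
            f"ncols {self.data.shape[1]}\n"
            f"nrows {self.data.shape[0]}\n"
            f"xllcorner {self.xllcorner}\n"
            f"yllcorner {self.yllcorner}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {self.nodata_value}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in d:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read_asc(cls, path: str | Path) -> "SuitabilityRaster":
        meta: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                        "cellsize", "nodata_value"):
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.asarray(rows)
        nodata = meta.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError("ASCII grid dimensions do not match header")
        return cls(data, meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0),
                   meta.get("cellsize", 1.0), nodata)


def niche_overlap(r1: SuitabilityRaster, r2: SuitabilityRaster) -> tuple[float, float]:
    """Schoener's D and the standardized Hellinger similarity I.

    Suitabilities are normalized to sum to 1 over the shared non-nodata
    cells; D = 1 - 0.5*sum|p - q|, I = 1 - 0.5*sum(sqrt(p) - sqrt(q))^2.
    Both are 1 for identical rasters and 0 for disjoint supports.
    """
    if not r1.co_registered_with(r2):
        raise ValueError("rasters are not co-registered (no silent resampling)")
    shared = ~np.isnan(r1.data) & ~np.isnan(r2.data)
    p = r1.data[shared]
    q = r2.data[shared]
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("a raster is zero over the shared cells")
    p = p / p.sum()
    q = q / q.sum()
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    i = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    return float(d), float(i)


# ---------------------------------------------------------------------------
# suitability models and the background test

class MahalanobisEnvelope:
    """Climate-envelope suitability: exp(-mahalanobis^2 / 2) to the
    occurrence climate centroid.

    The covariance is shrunk toward a scaled identity,
    (1 - shrinkage)*S + shrinkage*(tr(S)/p)*I: occurrence samples are
    routinely no larger than the variable count (e.g. tens of points
    against 19 climate variables), where the raw sample covariance is
    singular and the envelope degenerates."""

    def __init__(self, shrinkage: float = 0.5):
        if not 0 <= shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        self.shrinkage = shrinkage
        self.mean_: np.ndarray | None = None
        self.prec_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "MahalanobisEnvelope":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        cov = np.atleast_2d(np.cov(x, rowvar=False))
        target = np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        cov = (1.0 - self.shrinkage) * cov + self.shrinkage * target
        self.prec_ = np.linalg.inv(cov)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("model not fitted")
        diff = np.asarray(x, dtype=float) - self.mean_
        d2 = np.einsum("ij,jk,ik->i", diff, self.prec_, diff)
        return np.exp(-0.5 * d2)


@dataclass
class ClimateGrid:
    """A gridded climate landscape: cell centers plus climate values."""

    lats: np.ndarray          # (n_cells,)
    lons: np.ndarray
    climates: np.ndarray      # (n_cells, n_vars)
    shape: tuple[int, int]
    xllcorner: float
    yllcorner: float
    cellsize: float

    def suitability_raster(self, model) -> SuitabilityRaster:
        values = np.asarray(model.predict(self.climates), dtype=float)
        data = values.reshape(self.shape)
        return SuitabilityRaster(data, self.xllcorner, self.yllcorner, self.cellsize)

    def cells_within_buffer(self, coords: np.ndarray, radius_deg: float = 0.5) -> np.ndarray:
        """Indices of cells within `radius_deg` of any of the coordinates
        (degree-space disks unioned, per the dispersal-buffer convention)."""
        coords = np.asarray(coords, dtype=float)
        d2 = (
            (self.lats[:, None] - coords[None, :, 0]) ** 2
            + (self.lons[:, None] - coords[None, :, 1]) ** 2
        )
        return np.nonzero((d2 <= radius_deg ** 2).any(axis=1))[0]


@dataclass(frozen=True)
class BackgroundTestResult:
    observed_d: float
    observed_i: float
    null_d: np.ndarray
    null_i: np.ndarray
    p_d: float
    p_i: float


def _two_tailed_p(null: np.ndarray, obs: float) -> float:
    lo = (1 + (null <= obs).sum()) / (1 + null.size)
    hi = (1 + (null >= obs).sum()) / (1 + null.size)
    return float(min(1.0, 2.0 * min(lo, hi)))


def background_test(occ_a: np.ndarray, occ_b: np.ndarray,
                    background_b: np.ndarray, grid: ClimateGrid,
                    model_factory=MahalanobisEnvelope, n_reps: int = 1000,
                    seed: int = 0, replace: bool = True) -> BackgroundTestResult:
    """Niche-identity background test of region A against region B's background.

    Observed: overlap of the suitability models fitted to A's and B's
    occurrence climates.  Null: overlaps of A's model against models
    fitted to |occ_b| climates resampled from B's background — with
    replacement by default (random background points may repeat cells).
    p-values are two-tailed from the null ranks; run with roles swapped
    for the other direction.
    """
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99")
    occ_a, occ_b = np.asarray(occ_a, float), np.asarray(occ_b, float)
    background_b = np.asarray(background_b, float)
    raster_a = grid.suitability_raster(model_factory().fit(occ_a))
    raster_b = grid.suitability_raster(model_factory().fit(occ_b))
    obs_d, obs_i = niche_overlap(raster_a, raster_b)
    rng = np.random.default_rng(seed)
    n_b = occ_b.shape[0]
    if not replace and background_b.shape[0] < n_b:
        warnings.warn("background smaller than occurrence sample; sampling with replacement")
        replace = True
    null_d = np.empty(n_reps)
    null_i = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(background_b.shape[0], size=n_b, replace=replace)
        raster_null = grid.suitability_raster(model_factory().fit(background_b[idx]))
        null_d[r], null_i[r] = niche_overlap(raster_a, raster_null)
    return BackgroundTestResult(obs_d, obs_i, null_d, null_i,
                                _two_tailed_p(null_d, obs_d), _two_tailed_p(null_i, obs_i))
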