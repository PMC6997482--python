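"""Synthetic climate stacks and two-population occurrence sets.

The generator emulates the data a presence/background modeling study needs:
a stack of spatially autocorrelated bioclimatic layers with controllable
inter-layer correlation, additive/multiplicative future-climate shifts, and
presences drawn from Gaussian niche suitability surfaces so that every
downstream stage (grouping, model fitting, projection, overlap) can be tested
against known ground truth.

Spatial autocorrelation comes from Gaussian-kernel smoothing of white noise;
cross-layer correlation is imposed afterwards by Cholesky mixing of the
standardized fields, so the empirical correlation converges to the target as
the grid grows. Presences are drawn without replacement, one per cell, with
probability proportional to the niche suitability — mirroring the
one-record-per-cell thinning convention used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .raster import OccurrenceSet, RasterGrid, RasterStack

# Plausible (center, scale) per bioclimatic variable, in natural units
# (temperatures degC, precipitation mm, Bio03/Bio15 unitless percent-like).
BIOCLIM_BASE: dict[str, tuple[float, float]] = {
    "Bio01": (12.0, 5.0), "Bio02": (9.0, 2.0), "Bio03": (40.0, 8.0),
    "Bio04": (6.0, 2.0), "Bio05": (26.0, 5.0), "Bio06": (-2.0, 5.0),
    "Bio07": (28.0, 6.0), "Bio08": (18.0, 5.0), "Bio09": (5.0, 5.0),
    "Bio10": (20.0, 5.0), "Bio11": (2.0, 5.0), "Bio12": (900.0, 300.0),
    "Bio13": (180.0, 60.0), "Bio14": (12.0, 8.0), "Bio15": (70.0, 20.0),
    "Bio16": (450.0, 150.0), "Bio17": (40.0, 25.0), "Bio18": (400.0, 130.0),
    "Bio19": (50.0, 30.0),
}

_TEMPERATURE_LAYERS = {f"Bio{i:02d}" for i in range(1, 12)}

# Factor loadings of the default two-factor (temperature / precipitation)
# correlation model. Mean-temperature and total-precipitation layers are
# nearly interchangeable (loadings ~0.95), as in real bioclim stacks, while
# seasonality / diurnal-range / extreme-month layers are far more
# independent — so a collinearity screen eliminates most of the redundant
# block and keeps the distinctive variables.
_FACTOR_LOADINGS: dict[str, float] = {
    "Bio01": 0.97, "Bio02": 0.35, "Bio03": 0.50, "Bio04": 0.45,
    "Bio05": 0.95, "Bio06": 0.94, "Bio07": 0.55, "Bio08": 0.40,
    "Bio09": 0.96, "Bio10": 0.97, "Bio11": 0.96,
    "Bio12": 0.97, "Bio13": 0.60, "Bio14": 0.40, "Bio15": 0.45,
    "Bio16": 0.96, "Bio17": 0.94, "Bio18": 0.90, "Bio19": 0.93,
}


def default_correlation(layer_names: list[str]) -> np.ndarray:
    """Two-factor correlation: temperature layers load on one latent factor
    and precipitation layers on another, with per-variable loadings from
    ``_FACTOR_LOADINGS`` (0.5 for unknown names). Positive semi-definite by
    construction (factor model)."""
    L = np.zeros((len(layer_names), 2))
    for i, name in enumerate(layer_names):
        L[i, 0 if name in _TEMPERATURE_LAYERS else 1] = _FACTOR_LOADINGS.get(name, 0.5)
    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class NichePopulation:
    """Ground truth for one locally adapted population.

    ``mu`` and ``cov`` live in the (natural-unit) climate space of
    ``niche_vars``; ``lon_range``/``lat_range`` bound the region the
    population can occupy; ``n`` presences are drawn.
    """

    name: str
    lon_range: tuple[float, float]
    lat_range: tuple[float, float]
    mu: np.ndarray
    cov: np.ndarray
    n: int = 50

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.n < 1:
            raise ValueError("each population needs n >= 1 presences")
        w = np.linalg.eigvalsh(self.cov)
        if w.min() <= 0:
            raise ValueError(f"population {self.name!r}: niche covariance not positive definite")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic landscape.

    Defaults mimic the desk-scale study window (~97-112 degE, 22-36 degN at
    0.05 deg cells) with 19 bioclimatic layers, block-correlated temperature
    and precipitation fields, and a western plus an eastern population whose
    niche optima differ in temperature seasonality (Bio04) and driest-month
    precipitation (Bio14).
    """

    nrows: int = 280
    ncols: int = 300
    xllcorner: float = 97.0
    yllcorner: float = 22.0
    cellsize: float = 0.05
    layer_names: list[str] = field(default_factory=lambda: list(BIOCLIM_BASE))
    autocorr_cells: float = 5.0
    correlation: np.ndarray | None = None
    niche_vars: list[str] = field(default_factory=lambda: ["Bio04", "Bio14"])
    populations: list[NichePopulation] = field(default_factory=lambda: [
        NichePopulation("West", (98.0, 105.0), (26.0, 33.0),
                        mu=[4.5, 6.0], cov=[[0.64, 0.0], [0.0, 4.0]], n=44),
        NichePopulation("East", (105.0, 112.0), (29.5, 35.5),
                        mu=[8.5, 26.0], cov=[[0.64, 0.0], [0.0, 9.0]], n=23),
    ])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1 or self.cellsize <= 0:
            raise ValueError("invalid grid shape or cellsize")
        lat_top = self.yllcorner + self.nrows * self.cellsize
        lon_right = self.xllcorner + self.ncols * self.cellsize
        if not (-90 <= self.yllcorner and lat_top <= 90 and
                -180 <= self.xllcorner and lon_right <= 180):
            raise ValueError("extent outside valid lon/lat bounds")


def _mixing_matrix(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise ValueError(
                "target correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            ) from None
        return V * np.sqrt(np.clip(w, 0.0, None))


def generate_climate_stack(spec: SyntheticSpec) -> RasterStack:
    """Simulate the bioclimatic layer stack described by ``spec``.

    Each layer is white noise smoothed with a Gaussian kernel of
    ``autocorr_cells`` cells, standardized, Cholesky-mixed to the target
    correlation, then affinely mapped to the plausible range of its
    variable. Deterministic given ``spec.seed``.
    """
    names = spec.layer_names
    corr = spec.correlation if spec.correlation is not None else default_correlation(names)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix shape does not match the layer count")
    L = _mixing_matrix(corr)

    rng = np.random.default_rng(spec.seed)
    fields = np.empty((spec.nrows * spec.ncols, len(names)))
    for j in range(len(names)):
        noise = rng.standard_normal((spec.nrows, spec.ncols))
        smooth = gaussian_filter(noise, sigma=spec.autocorr_cells, mode="reflect")
        smooth = (smooth - smooth.mean()) / smooth.std()
        fields[:, j] = smooth.ravel()
    mixed = fields @ L.T

    layers = {}
    for j, name in enumerate(names):
        center, scale = BIOCLIM_BASE.get(name, (0.0, 1.0))
        vals = (center + scale * mixed[:, j]).reshape(spec.nrows, spec.ncols)
        layers[name] = RasterGrid(spec.nrows, spec.ncols, spec.xllcorner,
                                  spec.yllcorner, spec.cellsize, vals)
    return RasterStack(layers)


def generate_future_stack(current: RasterStack,
                          delta: dict[str, dict[str, float]]) -> RasterStack:
    """Apply per-layer affine climate shifts: new = factor * x + offset.

    ``delta`` maps layer names to {"offset": b, "factor": a} (either key may
    be omitted; defaults b=0, a=1). Layers not named are copied unchanged.
    """
    unknown = set(delta) - set(current.layer_names)
    if unknown:
        raise KeyError(f"delta names unknown layer(s): {sorted(unknown)}")
    layers = {}
    for name, grid in current.items():
        if name in delta:
            d = delta[name]
            extra = set(d) - {"offset", "factor"}
            if extra:
                raise KeyError(f"delta[{name!r}] has unknown keys {sorted(extra)}")
            a = float(d.get("factor", 1.0))
            b = float(d.get("offset", 0.0))
            layers[name] = grid.copy_with(a * grid.values + b)
        else:
            layers[name] = grid.copy_with(grid.values.copy())
    return RasterStack(layers)


def _region_cells(stack: RasterStack, pop: NichePopulation) -> tuple[np.ndarray, np.ndarray]:
    t = stack.template
    lon = t.lon_centers
    lat = t.lat_centers
    in_lon = (lon >= pop.lon_range[0]) & (lon < pop.lon_range[1])
    in_lat = (lat >= pop.lat_range[0]) & (lat < pop.lat_range[1])
    mask = in_lat[:, None] & in_lon[None, :]
    finite = np.ones_like(mask)
    for g in stack.values():
        finite &= g.finite_mask
    rows, cols = np.nonzero(mask & finite)
    return rows, cols


def true_suitability(stack: RasterStack, spec: SyntheticSpec,
                     pop: NichePopulation) -> RasterGrid:
    """Ground-truth Gaussian niche suitability surface
    s(c) = exp(-1/2 (c-mu)^T Sigma^-1 (c-mu)) over the population's region."""
    t = stack.template
    rows, cols = _region_cells(stack, pop)
    C = np.stack([stack[v].values[rows, cols] for v in spec.niche_vars], axis=1)
    d = C - pop.mu
    prec = np.linalg.inv(pop.cov)
    s = np.exp(-0.5 * np.einsum("ij,jk,ik->i", d, prec, d))
    vals = np.full((t.nrows, t.ncols), np.nan)
    vals[rows, cols] = s
    return t.copy_with(vals)


def generate_populations(stack: RasterStack, spec: SyntheticSpec) -> OccurrenceSet:
    """Sample presences for every population in ``spec``.

    Within each population's region, cells are drawn without replacement
    (one presence per cell, at the cell center) with probability proportional
    to the Gaussian niche suitability of the cell's climate vector.
    Deterministic given ``spec.seed``; records carry true population labels.
    """
    t = stack.template
    lons, lats, labels = [], [], []
    for k, pop in enumerate(spec.populations):
        if len(pop.mu) != len(spec.niche_vars):
            raise ValueError(f"population {pop.name!r}: mu length != niche_vars")
        rows, cols = _region_cells(stack, pop)
        if rows.size == 0:
            raise ValueError(f"population {pop.name!r}: region mask selects no cells")
        C = np.stack([stack[v].values[rows, cols] for v in spec.niche_vars], axis=1)
        d = C - pop.mu
        prec = np.linalg.inv(pop.cov)
        w = np.exp(-0.5 * np.einsum("ij,jk,ik->i", d, prec, d))
        if w.sum() <= 0 or not np.isfinite(w.sum()):
            raise ValueError(f"population {pop.name!r}: all-zero suitability in region")
        if pop.n > rows.size:
            raise ValueError(f"population {pop.name!r}: n={pop.n} exceeds region cells")
        rng = np.random.default_rng([spec.seed, k])
        # exponential race = weighted sampling without replacement
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            keys = rng.exponential(size=w.size) / np.where(w > 0, w, np.nan)
        keys[~np.isfinite(keys)] = np.inf
        pick = np.argsort(keys)[: pop.n]
        lons.append(t.lon_centers[cols[pick]])
        lats.append(t.lat_centers[rows[pick]])
        labels.extend([pop.name] * pop.n)
    return OccurrenceSet.from_arrays(np.concatenate(lons), np.concatenate(lats), labels)
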