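"""Raster and occurrence data model with spherical-geometry utilities.

Grids follow the ESRI ASCII grid convention: row 0 is the northernmost row,
cells are square in decimal degrees, and the origin is the lower-left corner.
Nodata cells are represented as NaN in memory; the ``nodata`` attribute only
records the sentinel used on disk. All distances and areas use a spherical
Earth of radius R = 6371.0088 km.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("popsdm")

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Grid containers
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A single georeferenced layer of cell values.

    Parameters
    ----------
    nrows, ncols : int
        Grid shape; row 0 is the northernmost row.
    xllcorner, yllcorner : float
        Lower-left corner in decimal degrees.
    cellsize : float
        Cell edge length in decimal degrees (square cells).
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks nodata.
    nodata : float
        Sentinel written for NaN cells on disk (default -9999).
    """

    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"(nrows, ncols)=({self.nrows}, {self.ncols})"
            )
        for name in ("xllcorner", "yllcorner", "cellsize"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- geometry ----------------------------------------------------------

    @property
    def geometry(self) -> tuple:
        return (self.nrows, self.ncols, self.xllcorner, self.yllcorner, self.cellsize)

    def same_geometry(self, other: "RasterGrid") -> bool:
        a, b = self.geometry, other.geometry
        return a[:2] == b[:2] and np.allclose(a[2:], b[2:], rtol=0, atol=1e-9)

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length ncols)."""
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length nrows, row order)."""
        top = self.yllcorner + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under half-open cell ownership
        [x_left, x_right) x [y_bottom, y_top). Raises if any point falls
        outside the grid extent."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            idx = np.flatnonzero(bad)
            raise ValueError(
                f"{idx.size} point(s) outside the raster extent "
                f"(first offenders at positions {idx[:5].tolist()})"
            )
        return row, col

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))


class RasterStack(Mapping[str, RasterGrid]):
    """An ordered set of named layers sharing one grid geometry."""

    def __init__(self, layers: Mapping[str, RasterGrid]):
        if not layers:
            raise ValueError("a RasterStack needs at least one layer")
        self._layers: dict[str, RasterGrid] = dict(layers)
        first = next(iter(self._layers.values()))
        for name, grid in self._layers.items():
            if not grid.same_geometry(first):
                raise ValueError(f"layer {name!r} geometry differs from the stack's")

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def layer_names(self) -> list[str]:
        return list(self._layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self._layers.values()))

    def to_matrix(self) -> np.ndarray:
        """Stack layers into an (nrows, ncols, n_layers) array."""
        return np.stack([g.values for g in self._layers.values()], axis=-1)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Presence coordinates with optional population labels."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["lon", "lat"]))

    def __post_init__(self) -> None:
        df = self.frame
        if "lon" not in df.columns or "lat" not in df.columns:
            raise ValueError("occurrence frame needs 'lon' and 'lat' columns")
        if len(df):
            if df["lon"].abs().max() > 180 or df["lat"].abs().max() > 90:
                raise ValueError("coordinates outside [-180, 180] x [-90, 90]")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lon(self) -> np.ndarray:
        return self.frame["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.frame["lat"].to_numpy(dtype=float)

    @property
    def population(self) -> np.ndarray | None:
        if "population" in self.frame.columns:
            return self.frame["population"].to_numpy()
        return None

    def subset(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    @classmethod
    def from_arrays(cls, lon, lat, population=None, source=None) -> "OccurrenceSet":
        data = {"lon": np.asarray(lon, dtype=float), "lat": np.asarray(lat, dtype=float)}
        if population is not None:
            data["population"] = np.asarray(population)
        if source is not None:
            data["source"] = np.asarray(source)
        return cls(pd.DataFrame(data))

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value"}


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc). The xllcenter dialect is converted to
    the corner convention (corner = center - cellsize/2)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing required header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)

    try:
        values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse grid values: {exc}") from exc
    if values.size == nrows * ncols and values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({nrows} rows x {ncols} cols)"
        )
    values[values == nodata] = np.nan
    return RasterGrid(nrows, ncols, xll, yll, cellsize, values, nodata=nodata)


def write_ascii_grid(grid: RasterGrid, path, precision: int = 8) -> None:
    """Write a grid as ESRI ASCII; NaN cells become the nodata sentinel."""
    path = Path(path)
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        np.savetxt(fh, vals, fmt=f"%.{precision}g")


def read_stack(directory, pattern: str = "*.asc") -> RasterStack:
    """Read every .asc in a directory into a stack, layer name = file stem."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files under {directory}")
    return RasterStack({p.stem: read_ascii_grid(p) for p in paths})


def write_stack(stack: RasterStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.items():
        write_ascii_grid(grid, directory / f"{name}.asc")


# ---------------------------------------------------------------------------
# Spherical geometry
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def cell_area_km2(lat_center, cellsize: float) -> np.ndarray:
    """Area of a cellsize x cellsize cell centered at lat_center:
    A = R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))."""
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    half = cellsize / 2
    top = np.radians(np.clip(lat + half, -90, 90))
    bot = np.radians(np.clip(lat - half, -90, 90))
    return EARTH_RADIUS_KM ** 2 * math.radians(cellsize) * (np.sin(top) - np.sin(bot))


# ---------------------------------------------------------------------------
# Spatial thinning and the study-region buffer
# ---------------------------------------------------------------------------

def spatial_filter(occ: OccurrenceSet, cell_km: float = 20.0,
                   origin: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """One record per cell of an equal-area thinning grid.

    Records are binned on a sinusoidal equal-area projection
    (x = R*lambda*cos(phi), y = R*phi, km) into cell_km x cell_km bins
    anchored at ``origin`` (km offsets); the first record in input order wins
    per bin and input order is preserved.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if len(occ) == 0:
        return occ
    lam = np.radians(occ.lon)
    phi = np.radians(occ.lat)
    x = EARTH_RADIUS_KM * lam * np.cos(phi) - origin[0]
    y = EARTH_RADIUS_KM * phi - origin[1]
    bins = np.stack([np.floor(x / cell_km), np.floor(y / cell_km)], axis=1)
    _, first_idx = np.unique(bins, axis=0, return_index=True)
    keep = np.zeros(len(occ), dtype=bool)
    keep[first_idx] = True
    out = occ.subset(keep)
    logger.info("spatial_filter: %d -> %d records (cell %.1f km)", len(occ), len(out), cell_km)
    return out


def buffer_region(occ: OccurrenceSet, radius_km: float, template: RasterGrid) -> RasterGrid:
    """Binary mask: 1 where a cell center lies within radius_km great-circle
    distance of the nearest occurrence; NaN preserved from the template."""
    if len(occ) == 0:
        raise ValueError("cannot buffer an empty occurrence set")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lons = template.lon_centers
    lats = template.lat_centers
    inside = np.zeros((template.nrows, template.ncols), dtype=bool)
    # row-by-row keeps the distance matrix at ncols x n_occ
    for i, lat in enumerate(lats):
        d = haversine_km(lons[:, None], lat, occ.lon[None, :], occ.lat[None, :])
        inside[i] = d.min(axis=1) <= radius_km
    vals = np.where(template.finite_mask, inside.astype(float), np.nan)
    return template.copy_with(vals)


# ---------------------------------------------------------------------------
# Binary-map summaries
# ---------------------------------------------------------------------------

def suitable_area_km2(binary: RasterGrid) -> float:
    """Total spherical area of cells equal to 1."""
    suit = binary.values == 1
    if not suit.any():
        return 0.0
    areas = cell_area_km2(binary.lat_centers, binary.cellsize)  # per row
    return float((suit * areas[:, None]).sum())


def centroid(binary: RasterGrid) -> tuple[float, float] | None:
    """Cell-area-weighted centroid (lon, lat) of suitable cells, or None
    when the map has no suitable cell."""
    suit = binary.values == 1
    if not suit.any():
        return None
    areas = cell_area_km2(binary.lat_centers, binary.cellsize)
    w = suit * areas[:, None]
    total = w.sum()
    lon = float((w * binary.lon_centers[None, :]).sum() / total)
    lat = float((w * binary.lat_centers[:, None]).sum() / total)
    return lon, lat


@dataclass
class RangeSummary:
    """Suitable area and centroid of one binary range map."""

    scenario: str
    area_km2: float
    centroid_lon: float | None
    centroid_lat: float | None

    @classmethod
    def of(cls, binary: RasterGrid, scenario: str = "current") -> "RangeSummary":
        c = centroid(binary)
        return cls(scenario, suitable_area_km2(binary),
                   None if c is None else c[0], None if c is None else c[1])


# ---------------------------------------------------------------------------
# Climate extraction and background sampling
# ---------------------------------------------------------------------------

def extract_values(stack: RasterStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Climate matrix: one row per occurrence, one column per layer.

    Rows hitting nodata in any layer are excluded (count logged); the frame
    index keeps the surviving occurrences' positional indices.
    """
    template = stack.template
    row, col = template.cell_index(occ.lon, occ.lat)
    data = {name: grid.values[row, col] for name, grid in stack.items()}
    frame = pd.DataFrame(data)
    ok = frame.notna().all(axis=1).to_numpy()
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("extract_values: %d record(s) on nodata cells excluded", n_bad)
    return frame.loc[ok]


@dataclass
class BackgroundSample:
    """Cell centers drawn from a mask, with their grid indices."""

    lon: np.ndarray
    lat: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.lon)

    def as_occurrences(self) -> OccurrenceSet:
        return OccurrenceSet.from_arrays(self.lon, self.lat)


def sample_background(mask: RasterGrid, n: int = 10_000, seed: int = 0) -> BackgroundSample:
    """Draw n distinct cells uniformly without replacement from cells where
    the mask equals 1; deterministic given seed. If fewer than n cells are
    available all are returned (with a warning)."""
    rows, cols = np.nonzero(mask.values == 1)
    if rows.size == 0:
        raise ValueError("background mask has no suitable cells")
    rng = np.random.default_rng(seed)
    if n >= rows.size:
        if n > rows.size:
            logger.warning("sample_background: requested %d of %d cells; using all", n, rows.size)
        pick = np.arange(rows.size)
    else:
        pick = rng.choice(rows.size, size=n, replace=False)
    pick.sort()
    r, c = rows[pick], cols[pick]
    return BackgroundSample(mask.lon_centers[c], mask.lat_centers[r], r, c)
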