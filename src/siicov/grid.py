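"""Equal-area grid construction and rasterization of points and range polygons.

The coverage indicator lives on a square grid of identical-area cells
(110 x 110 km by default). Geographic coordinates are mapped onto the grid
through a cylindrical equal-area projection (Lambert CEA, spherical model on
the WGS84 authalic radius) so that every cell footprint has exactly the same
projected area ``cell_size**2``. Cell membership uses the half-open convention
``[x0, x0 + w) x [y0, y0 + w)``, which makes the grid an exact partition of
its extent: every in-extent point belongs to one and only one cell.

Expert range polygons are coarsened to the grid by the *positive-area overlap*
rule: a cell belongs to a species' expected range if the projected range
polygon overlaps the cell square with strictly positive area. Cells that only
touch the range boundary are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AUTHALIC_RADIUS_M",
    "DEFAULT_CRS_ID",
    "DEFAULT_CELL_SIZE_M",
    "GridError",
    "OutOfExtentError",
    "GeometryError",
    "CylindricalEqualArea",
    "Cell",
    "GridSpec",
    "CountryPolygonSet",
    "build_grid",
    "grid_from_geographic",
    "point_to_cell",
    "polygon_to_cells",
    "clip_range_to_country",
    "load_ranges_geojson",
    "load_ranges_cells_csv",
    "load_countries_geojson",
]

#: WGS84 authalic sphere radius in metres (the sphere with the ellipsoid's area).
AUTHALIC_RADIUS_M = 6_371_007.180918475

DEFAULT_CRS_ID = "cea_sphere_30"
DEFAULT_CELL_SIZE_M = 110_000.0


class GridError(ValueError):
    """Base error for grid construction and addressing."""


class OutOfExtentError(GridError):
    """A point falls outside the grid extent."""


class GeometryError(GridError):
    """A geometry is invalid and could not be repaired."""


class CylindricalEqualArea:
    """Lambert cylindrical equal-area projection on the authalic sphere.

    Forward:  x = R * lon_rad * cos(phi_s),  y = R * sin(lat) / cos(phi_s)
    where ``phi_s`` is the standard parallel. Area is preserved exactly on
    the sphere for any ``phi_s``; 30 degrees matches the common EPSG:6933
    parameterization and keeps distortion moderate at mid latitudes.
    """

    def __init__(self, standard_parallel_deg: float = 30.0,
                 radius_m: float = AUTHALIC_RADIUS_M) -> None:
        self.standard_parallel_deg = standard_parallel_deg
        self.radius_m = radius_m
        self._k = math.cos(math.radians(standard_parallel_deg))

    def forward(self, lon, lat):
        """Geographic degrees -> projected metres. Accepts scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = self.radius_m * np.radians(lon) * self._k
        y = self.radius_m * np.sin(np.radians(lat)) / self._k
        return x, y

    def inverse(self, x, y):
        """Projected metres -> geographic degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = np.degrees(x / (self.radius_m * self._k))
        lat = np.degrees(np.arcsin(np.clip(y * self._k / self.radius_m, -1.0, 1.0)))
        return lon, lat

    def project_geometry(self, geom: BaseGeometry) -> BaseGeometry:
        def _f(coords: np.ndarray) -> np.ndarray:
            gx, gy = self.forward(coords[:, 0], coords[:, 1])
            return np.column_stack([gx, gy])

        return shapely.transform(geom, _f)


#: Registered equal-area CRSs available for grid construction.
CRS_REGISTRY: Mapping[str, CylindricalEqualArea] = {
    "cea_sphere_30": CylindricalEqualArea(30.0),
    "cea_sphere_0": CylindricalEqualArea(0.0),
}


def _resolve_crs(crs_id: str) -> CylindricalEqualArea:
    try:
        return CRS_REGISTRY[crs_id]
    except KeyError:
        raise GridError(
            f"crs_id {crs_id!r} is not a registered equal-area CRS; the grid "
            f"requires an equal-area projection so all cells have identical "
            f"area (available: {sorted(CRS_REGISTRY)})"
        ) from None


class Cell(NamedTuple):
    """One grid cell, addressed by column, row and a stable row-major id."""

    col: int
    row: int
    id: int


@dataclass(frozen=True)
class GridSpec:
    """An equal-area grid: CRS, cell size, origin and integer dimensions.

    The grid tiles the half-open rectangle
    ``[origin_x, origin_x + n_cols*w) x [origin_y, origin_y + n_rows*w)``.
    Cell ids are row-major: ``id = row * n_cols + col``.
    """

    crs_id: str
    cell_size: float
    origin_x: float
    origin_y: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise GridError("grid must have at least one cell in each axis")
        _resolve_crs(self.crs_id)

    # -- addressing ---------------------------------------------------------

    @property
    def projection(self) -> CylindricalEqualArea:
        return _resolve_crs(self.crs_id)

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def key(self) -> str:
        """Stable identity string used to check that two products share a grid."""
        return (
            f"{self.crs_id}|{self.cell_size:.6f}|{self.origin_x:.6f}|"
            f"{self.origin_y:.6f}|{self.n_cols}x{self.n_rows}"
        )

    def cell(self, col: int, row: int) -> Cell:
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise GridError(f"cell (col={col}, row={row}) outside grid "
                            f"{self.n_cols}x{self.n_rows}")
        return Cell(col, row, row * self.n_cols + col)

    def cell_from_id(self, cell_id: int) -> Cell:
        if not 0 <= cell_id < self.n_cells:
            raise GridError(f"cell id {cell_id} outside grid with {self.n_cells} cells")
        return Cell(cell_id % self.n_cols, cell_id // self.n_cols, cell_id)

    def cell_square(self, cell: Cell | int):
        """Projected shapely box of a cell's footprint (closed box geometry;
        membership semantics remain half-open)."""
        if isinstance(cell, int):
            cell = self.cell_from_id(cell)
        x0 = self.origin_x + cell.col * self.cell_size
        y0 = self.origin_y + cell.row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def cell_center_lonlat(self, cell: Cell | int) -> tuple[float, float]:
        if isinstance(cell, int):
            cell = self.cell_from_id(cell)
        cx = self.origin_x + (cell.col + 0.5) * self.cell_size
        cy = self.origin_y + (cell.row + 0.5) * self.cell_size
        lon, lat = self.projection.inverse(cx, cy)
        return float(lon), float(lat)

    # -- point assignment ---------------------------------------------------

    def point_ids(self, lon, lat) -> np.ndarray:
        """Vectorized cell-id lookup; out-of-extent points get -1."""
        x, y = self.projection.forward(lon, lat)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(np.int64)
        ids = row * self.n_cols + col
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        return np.where(bad, -1, ids)

    def to_dataframe(self) -> pd.DataFrame:
        """All cells as (cell_id, col, row, centre_lon, centre_lat)."""
        ids = np.arange(self.n_cells)
        cols = ids % self.n_cols
        rows = ids // self.n_cols
        cx = self.origin_x + (cols + 0.5) * self.cell_size
        cy = self.origin_y + (rows + 0.5) * self.cell_size
        lon, lat = self.projection.inverse(cx, cy)
        return pd.DataFrame(
            {"cell_id": ids, "col": cols, "row": rows,
             "centre_lon": lon, "centre_lat": lat}
        )


@dataclass(frozen=True)
class CountryPolygonSet:
    """A country's boundary multipolygon in geographic coordinates."""

    country_code: str
    geometry: BaseGeometry


def build_grid(
    crs_id: str = DEFAULT_CRS_ID,
    cell_size: float = DEFAULT_CELL_SIZE_M,
    extent: tuple[float, float, float, float] | None = None,
) -> GridSpec:
    """Build a grid tiling a projected bounding box ``(x0, y0, x1, y1)``.

    The grid origin sits at the extent's lower-left corner and the cell count
    per axis is ``ceil(width / cell_size)``, so the tiling always covers the
    full extent.
    """
    if extent is None:
        raise GridError("extent is required")
    x0, y0, x1, y1 = map(float, extent)
    if not (x1 > x0 and y1 > y0):
        raise GridError(f"extent must be non-empty, got {extent}")
    if cell_size <= 0:
        raise GridError("cell_size must be positive")
    _resolve_crs(crs_id)
    n_cols = math.ceil((x1 - x0) / cell_size)
    n_rows = math.ceil((y1 - y0) / cell_size)
    return GridSpec(crs_id, float(cell_size), x0, y0, n_cols, n_rows)


def grid_from_geographic(
    lon_min: float,
    lat_min: float,
    lon_max: float,
    lat_max: float,
    crs_id: str = DEFAULT_CRS_ID,
    cell_size: float = DEFAULT_CELL_SIZE_M,
) -> GridSpec:
    """Convenience: build a grid covering a geographic bounding box."""
    proj = _resolve_crs(crs_id)
    x0, y0 = proj.forward(lon_min, lat_min)
    x1, y1 = proj.forward(lon_max, lat_max)
    return build_grid(crs_id, cell_size, (float(x0), float(y0), float(x1), float(y1)))


def point_to_cell(lon: float, lat: float, grid: GridSpec) -> Cell:
    """Assign one geographic point to its unique grid cell.

    Points exactly on an interior cell edge resolve to the cell on the
    upper/right side (half-open convention, lower/left edge inclusive).
    """
    ids = grid.point_ids([lon], [lat])
    if ids[0] < 0:
        raise OutOfExtentError(
            f"point (lon={lon}, lat={lat}) falls outside the grid extent"
        )
    return grid.cell_from_id(int(ids[0]))


def _repair(geom: BaseGeometry, label: str | None = None) -> BaseGeometry:
    if geom.is_valid:
        return geom
    fixed = shapely.make_valid(geom)
    if fixed.is_valid:
        return fixed
    raise GeometryError(
        f"geometry{' for ' + label if label else ''} is invalid and could not "
        f"be repaired"
    )


def _as_single_geometry(geoms) -> BaseGeometry:
    if isinstance(geoms, BaseGeometry):
        return geoms
    parts = [g for g in geoms]
    if not parts:
        return shapely.geometry.Polygon()
    return shapely.union_all(parts)


#: Overlap areas at or below this (in m^2) are treated as zero. Cells are
#: ~1.2e10 m^2, so this only absorbs floating-point slivers from projection
#: round-trips, never a real overlap.
MIN_OVERLAP_AREA_M2 = 1.0


def _cells_from_projected(
    geom: BaseGeometry, grid: GridSpec, min_area: float = MIN_OVERLAP_AREA_M2
) -> set[Cell]:
    """Cells whose square overlaps a projected geometry with positive area."""
    if geom.is_empty:
        return set()
    w = grid.cell_size
    gx0, gy0, gx1, gy1 = geom.bounds
    c0 = max(0, int(math.floor((gx0 - grid.origin_x) / w)))
    c1 = min(grid.n_cols - 1, int(math.floor((gx1 - grid.origin_x) / w)))
    r0 = max(0, int(math.floor((gy0 - grid.origin_y) / w)))
    r1 = min(grid.n_rows - 1, int(math.floor((gy1 - grid.origin_y) / w)))
    out: set[Cell] = set()
    for row in range(r0, r1 + 1):
        for col in range(c0, c1 + 1):
            cell = grid.cell(col, row)
            sq = grid.cell_square(cell)
            if sq.intersects(geom) and sq.intersection(geom).area > min_area:
                out.add(cell)
    return out


def polygon_to_cells(
    range_polygons,
    grid: GridSpec,
    species: str | None = None,
    geographic: bool = True,
) -> set[Cell]:
    """Coarsen a range polygon (or iterable of polygons) to grid cells.

    A cell is included iff the projected range overlaps its square with
    positive area; cells touched only along a boundary are excluded. Invalid
    geometries are repaired automatically where possible; an unrepairable
    geometry raises :class:`GeometryError` naming the species.
    """
    geom = _as_single_geometry(range_polygons)
    if geom.is_empty:
        return set()
    geom = _repair(geom, species)
    if geographic:
        geom = grid.projection.project_geometry(geom)
        geom = _repair(geom, species)
    return _cells_from_projected(geom, grid)


def clip_range_to_country(
    range_polygons,
    country: CountryPolygonSet,
    grid: GridSpec,
    species: str | None = None,
) -> set[Cell]:
    """Cells of the portion of a species range inside a country's borders.

    Equivalent to coarsening ``range ∩ country``; a range disjoint from the
    country yields an empty set (flagged by the caller, not an error here).
    """
    geom = _repair(_as_single_geometry(range_polygons), species)
    cgeom = _repair(country.geometry, country.country_code)
    proj = grid.projection
    inter = proj.project_geometry(geom).intersection(proj.project_geometry(cgeom))
    return _cells_from_projected(inter, grid)


# -- vector / tabular readers ------------------------------------------------

_SPECIES_KEYS = ("species", "sci_name", "scientificName", "binomial")
_COUNTRY_KEYS = ("country_code", "code", "ISO_A3", "GID_0")


def _feature_prop(props: Mapping, keys: Sequence[str], what: str) -> str:
    for k in keys:
        if k in props and props[k]:
            return str(props[k])
    raise GridError(f"GeoJSON feature lacks a {what} property (tried {keys})")


def load_ranges_geojson(path) -> dict[str, BaseGeometry]:
    """Read species range polygons from a GeoJSON FeatureCollection.

    Features carry the species name in a ``species`` (or ``sci_name`` /
    ``scientificName`` / ``binomial``) property; multiple features for one
    species are unioned.
    """
    import json

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out: dict[str, BaseGeometry] = {}
    for feat in data.get("features", []):
        name = _feature_prop(feat.get("properties", {}), _SPECIES_KEYS, "species")
        geom = shape(feat["geometry"])
        out[name] = geom if name not in out else shapely.union_all([out[name], geom])
    return out


def load_countries_geojson(path) -> list[CountryPolygonSet]:
    """Read country boundary polygons from a GeoJSON FeatureCollection."""
    import json

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out: list[CountryPolygonSet] = []
    seen: set[str] = set()
    for feat in data.get("features", []):
        code = _feature_prop(feat.get("properties", {}), _COUNTRY_KEYS, "country code")
        if code in seen:
            raise GridError(f"duplicate country code {code!r}")
        seen.add(code)
        out.append(CountryPolygonSet(code, _repair(shape(feat["geometry"]), code)))
    return out


def load_ranges_cells_csv(path, grid: GridSpec) -> dict[str, set[int]]:
    """Read pre-coarsened ranges from a CSV of (species, cell_id) rows."""
    df = pd.read_csv(path)
    missing = {"species", "cell_id"} - set(df.columns)
    if missing:
        raise GridError(f"range cell CSV missing columns: {sorted(missing)}")
    bad = df[(df.cell_id < 0) | (df.cell_id >= grid.n_cells)]
    if len(bad):
        raise GridError(
            f"range cell CSV contains {len(bad)} cell ids outside the grid "
            f"(first offender: {bad.iloc[0].to_dict()})"
        )
    return {
        sp: set(int(c) for c in sub.cell_id)
        for sp, sub in df.groupby("species", sort=True)
    }
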