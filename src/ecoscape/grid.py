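"""Raster data model and GeoTIFF I/O.

Every stage of the pipeline operates on single-band rasters sharing a
:class:`GridSpec` — the grid geometry contract (shape, cell size, origin).
Categorical land-use/land-cover (LULC) maps are :class:`LULCMap`; continuous
surfaces (habitat quality, degradation, driver layers) travel as plain float
arrays tied to the same grid.

GeoTIFFs are written with ``tifffile`` carrying the minimal geo tags needed
for a bit-exact round trip: pixel scale, top-left tiepoint, nodata and a CRS
label. Reprojection between CRSs is out of scope; all inputs must be
co-registered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Land-cover class coding used throughout: code -> name.
CLASS_LABELS: dict[int, str] = {
    1: "Farmland",
    2: "Forests",
    3: "Shrubs",
    4: "Grasslands",
    5: "Water bodies",
    6: "Construction land",
    7: "Barren",
}

DEFAULT_NODATA = 0

# TIFF tag codes for the geo metadata we persist.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

#: Relative tolerance on origin/cell_size when deciding two grids are equal,
#: expressed as a fraction of one cell (absorbs float geotransforms).
GRID_TOLERANCE = 1e-6


class GridMismatchError(ValueError):
    """Two rasters that must be co-registered are not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    The convention is row-major with the origin at the *top-left cell
    corner*; cell centres sit at ``origin + (k + 0.5) * cell_size`` with the
    y axis pointing down (north-up raster).

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; both at least 1.
    cell_size : float
        Cell edge length in metres (cells are square).
    origin : (float, float)
        ``(x, y)`` of the top-left corner in projected coordinates.
    crs_label : str
        Free-text CRS identifier; carried through I/O, never interpreted.
    nodata_code : int
        Integer code marking invalid cells in categorical rasters. Must not
        collide with a valid class code.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"
    nodata_code: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_code in CLASS_LABELS:
            raise ValueError(
                f"nodata_code {self.nodata_code} collides with a class code"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km²."""
        return self.cell_size**2 / 1e6

    def matches(self, other: "GridSpec") -> bool:
        """Whether two grids are co-registered within tolerance."""
        tol = GRID_TOLERANCE * self.cell_size
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_match(self, other: "GridSpec", what: str = "rasters") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} are not co-registered: {self} vs {other}"
            )


@dataclass
class LULCMap:
    """A categorical land-cover raster on a :class:`GridSpec`.

    ``codes`` is an integer matrix whose valid entries are keys of
    ``class_labels``; anything else must equal ``grid.nodata_code``.
    """

    grid: GridSpec
    codes: np.ndarray
    class_labels: dict[int, str] = field(default_factory=lambda: dict(CLASS_LABELS))
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise TypeError("LULC codes must be integers")
        if self.codes.shape != self.grid.shape:
            raise ValueError(
                f"codes shape {self.codes.shape} != grid shape {self.grid.shape}"
            )
        valid = set(self.class_labels) | {self.grid.nodata_code}
        present = set(np.unique(self.codes).tolist())
        if not present <= valid:
            raise ValueError(f"unknown class codes present: {sorted(present - valid)}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.grid.nodata_code

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def class_counts(self) -> dict[int, int]:
        """Cell count per class code (valid cells only)."""
        codes, counts = np.unique(self.codes[self.valid_mask], return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def class_areas_km2(self) -> dict[int, float]:
        """Area per class code in km², zero-filled over all labelled classes."""
        counts = self.class_counts()
        return {
            c: counts.get(c, 0) * self.grid.cell_area_km2 for c in self.class_labels
        }

    def copy(self, epoch_label: str | None = None) -> "LULCMap":
        return LULCMap(
            grid=self.grid,
            codes=self.codes.copy(),
            class_labels=dict(self.class_labels),
            epoch_label=self.epoch_label if epoch_label is None else epoch_label,
        )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_extratags(grid: GridSpec, nodata) -> list:
    sx = sy = float(grid.cell_size)
    ox, oy = (float(v) for v in grid.origin)
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GEO_ASCII_PARAMS, "s", 0, grid.crs_label + "|"),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def _parse_grid(page: tifffile.TiffPage, default_nodata: int) -> tuple[GridSpec, str]:
    n_rows, n_cols = page.shape[:2]
    cell = 1.0
    origin = (0.0, 0.0)
    crs = "local"
    nodata = str(default_nodata)
    tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
    if tag is not None:
        cell = float(tag.value[0])
    tag = page.tags.get(_TAG_MODEL_TIEPOINT)
    if tag is not None:
        v = tag.value
        origin = (float(v[3]), float(v[4]))
    tag = page.tags.get(_TAG_GEO_ASCII_PARAMS)
    if tag is not None:
        crs = str(tag.value).rstrip("|")
    tag = page.tags.get(_TAG_GDAL_NODATA)
    if tag is not None:
        nodata = str(tag.value).strip().rstrip("\x00")
    return (
        GridSpec(
            n_rows=int(n_rows),
            n_cols=int(n_cols),
            cell_size=cell,
            origin=origin,
            crs_label=crs,
            nodata_code=default_nodata,
        ),
        nodata,
    )


def write_lulc_raster(lulc: LULCMap, path) -> None:
    """Write a categorical map as a single-band integer GeoTIFF.

    The nodata code, pixel scale, origin and CRS label are stored as TIFF
    tags so that :func:`read_lulc_raster` inverts the write bit-exactly.
    """
    data = lulc.codes.astype(np.int32)
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        extratags=_geo_extratags(lulc.grid, lulc.grid.nodata_code),
    )


def read_lulc_raster(path, class_codes=None, nodata_code: int | None = None) -> LULCMap:
    """Read a single-band integer GeoTIFF as an :class:`LULCMap`.

    Cells carrying a code outside ``class_codes`` (default: the standard
    seven-class scheme) are mapped to nodata; the count is logged and a
    warning emitted, since stray codes usually indicate a mis-specified
    legend rather than corrupt data.
    """
    if class_codes is None:
        class_codes = set(CLASS_LABELS)
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: expected an integer band, got {data.dtype}")
        grid, nodata_str = _parse_grid(page, DEFAULT_NODATA)
    file_nodata = int(float(nodata_str))
    if nodata_code is None:
        nodata_code = file_nodata
    grid = replace(grid, nodata_code=nodata_code)

    codes = data.astype(np.int64)
    stray = (codes != file_nodata) & ~np.isin(codes, sorted(class_codes))
    n_stray = int(stray.sum())
    if n_stray:
        warnings.warn(
            f"{path}: {n_stray} cells carry codes outside the class set; "
            "mapped to nodata",
            stacklevel=2,
        )
        logger.warning("%s: %d stray-code cells mapped to nodata", path, n_stray)
    codes[stray | (codes == file_nodata)] = nodata_code
    if not np.any(codes != nodata_code):
        raise ValueError(f"{path}: empty valid extent")
    labels = {c: CLASS_LABELS.get(c, f"class {c}") for c in sorted(class_codes)}
    return LULCMap(grid=grid, codes=codes, class_labels=labels)


def write_float_raster(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write a continuous surface as a float32 GeoTIFF (NaN = nodata)."""
    tifffile.imwrite(
        str(path),
        np.asarray(values, dtype=np.float32),
        photometric="minisblack",
        extratags=_geo_extratags(grid, "nan"),
    )


def read_float_raster(path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band float GeoTIFF; returns (values, grid), NaN = nodata."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=np.float64)
        grid, nodata_str = _parse_grid(page, DEFAULT_NODATA)
    if nodata_str.lower() not in ("nan", ""):
        data[data == float(nodata_str)] = np.nan
    return data, grid
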