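"""Minimal georeferenced raster/vector plumbing.

Rasters are plain numpy band stacks with an axis-aligned world transform
(meters, north-up: x increases with column, y decreases with row) and are
persisted as GeoTIFFs via tifffile (ModelPixelScale / ModelTiepoint tags,
auxiliary metadata as JSON in ImageDescription).  Vector layers are GeoJSON
feature collections handled with shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape as shapely_shape

from .errors import GeometryError, UnitsError

#: canonical band order of the 5-band camera
BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")

#: center wavelength / full bandwidth (nm) per band
DEFAULT_BAND_META = (
    {"name": "blue", "center_nm": 450, "bandwidth_nm": 32},
    {"name": "green", "center_nm": 560, "bandwidth_nm": 32},
    {"name": "red", "center_nm": 650, "bandwidth_nm": 32},
    {"name": "red_edge", "center_nm": 730, "bandwidth_nm": 32},
    {"name": "nir", "center_nm": 840, "bandwidth_nm": 52},
)

UNITS_DN = "dn"
UNITS_REFLECTANCE = "reflectance"

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class GridTransform:
    """Raster-to-world mapping: square pixels, pixel-is-area convention.

    The world coordinate of the *center* of pixel (row, col) is
    ``(origin_x + (col + 0.5) * pixel_size, origin_y - (row + 0.5) * pixel_size)``.
    """

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise GeometryError(f"pixel_size must be positive, got {self.pixel_size}")

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) world coordinates of all pixel centers, each of `shape`."""
        rows, cols = shape
        x = self.origin_x + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.origin_y - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def window_for_bounds(self, bounds, shape):
        """Half-open (row0, row1, col0, col1) covering world `bounds` within `shape`."""
        minx, miny, maxx, maxy = bounds
        rows, cols = shape
        c0 = max(int(np.floor((minx - self.origin_x) / self.pixel_size)), 0)
        c1 = min(int(np.ceil((maxx - self.origin_x) / self.pixel_size)), cols)
        r0 = max(int(np.floor((self.origin_y - maxy) / self.pixel_size)), 0)
        r1 = min(int(np.ceil((self.origin_y - miny) / self.pixel_size)), rows)
        return r0, max(r1, r0), c0, max(c1, c0)


@dataclass
class BandStack:
    """Five co-registered raster bands plus radiometric units and georeferencing."""

    data: np.ndarray  # (5, rows, cols)
    units: str
    transform: GridTransform
    band_meta: tuple = field(default_factory=lambda: DEFAULT_BAND_META)
    nodata: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(BAND_NAMES):
            raise GeometryError(f"expected (5, rows, cols) array, got {self.data.shape}")
        if self.units not in (UNITS_DN, UNITS_REFLECTANCE):
            raise UnitsError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.data[BAND_NAMES.index(name)]

    def valid_mask(self) -> np.ndarray:
        """True where no band is nodata/NaN."""
        ok = np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating):
            ok &= np.isfinite(self.data).all(axis=0)
        if self.nodata is not None:
            ok &= ~(self.data == self.nodata).any(axis=0)
        return ok

    def with_data(self, data, units=None, nodata=None) -> "BandStack":
        return BandStack(
            data=data,
            units=units or self.units,
            transform=self.transform,
            band_meta=self.band_meta,
            nodata=nodata if nodata is not None else self.nodata,
        )


def _geo_extratags(transform: GridTransform):
    ps = float(transform.pixel_size)
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (ps, ps, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, float(transform.origin_x), float(transform.origin_y), 0.0),
        ),
    ]


def write_band_stack(path, stack: BandStack) -> None:
    meta = {
        "units": stack.units,
        "band_meta": list(stack.band_meta),
        "nodata": stack.nodata,
    }
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        extratags=_geo_extratags(stack.transform),
        description=json.dumps(meta),
    )


def _read_geotags(page) -> GridTransform:
    try:
        sx, sy, _ = page.tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
        tp = page.tags[_TAG_MODEL_TIEPOINT].value
    except KeyError as exc:  # pragma: no cover - malformed input
        raise GeometryError("raster lacks GeoTIFF georeferencing tags") from exc
    # tiepoint maps raster (i, j) = (0, 0) to world (tp[3], tp[4])
    return GridTransform(origin_x=tp[3], origin_y=tp[4], pixel_size=sx)


def read_band_stack(path) -> BandStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        transform = _read_geotags(page)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if data.ndim == 2:
        data = data[None]
    return BandStack(
        data=data,
        units=meta.get("units", UNITS_DN),
        transform=transform,
        band_meta=tuple(meta.get("band_meta", DEFAULT_BAND_META)),
        nodata=meta.get("nodata"),
    )


def write_single_band(path, array: np.ndarray, transform: GridTransform, meta: dict | None = None):
    tifffile.imwrite(
        path,
        array,
        photometric="minisblack",
        extratags=_geo_extratags(transform),
        description=json.dumps(meta or {}),
    )


def read_single_band(path):
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        transform = _read_geotags(tif.pages[0])
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return data, transform, meta


def pixel_center_mask(transform: GridTransform, shape, polygon) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside `polygon`.

    Containment is evaluated at pixel centers in world coordinates (the
    standard, unambiguous rule for zonal work); pixels on the boundary are
    excluded, matching shapely's strict `contains`.
    """
    out = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = transform.window_for_bounds(polygon.bounds, shape)
    if r1 <= r0 or c1 <= c0:
        return out
    x = transform.origin_x + (np.arange(c0, c1) + 0.5) * transform.pixel_size
    y = transform.origin_y - (np.arange(r0, r1) + 0.5) * transform.pixel_size
    X, Y = np.meshgrid(x, y)
    out[r0:r1, c0:c1] = shapely.contains_xy(polygon, X, Y)
    return out


def read_feature_collection(path):
    """Read a GeoJSON FeatureCollection as a list of (geometry, properties)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeometryError(f"{path} is not a GeoJSON FeatureCollection")
    return [(shapely_shape(f["geometry"]), dict(f.get("properties") or {})) for f in gj["features"]]


def write_feature_collection(path, features) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)
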