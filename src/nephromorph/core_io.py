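"""Data model, calibration and I/O for kidney-structure label maps.

The segmentation layer works on single-channel label rasters ("semantic
maps") in which each pixel carries an integer class code from a fixed
schema of kidney compartments: full glomerulus (including the tuft),
glomerular tuft, tubule, artery (including lumen, intima and media),
arterial lumen and non-tissue background, plus an optional artificial
border class used to separate touching instances of the same class.

Conventions used throughout the package: pixel coordinates are 0-based
and row-major; tile and bounding-box extents are half-open; physical
units are micrometres, attached to every raster through a
:class:`PixelCalibration`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
import imageio.v3 as iio
from shapely.geometry import Polygon, shape as shapely_shape
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

__all__ = [
    "PixelCalibration",
    "ClassSchema",
    "SemanticMap",
    "Tile",
    "TileSet",
    "DEFAULT_SCHEMA",
    "read_label_image",
    "write_label_image",
    "rasterize_annotations",
    "read_geojson_annotations",
    "tile_grid",
]

#: Default scan calibration (40x objective), configurable everywhere.
DEFAULT_MICRONS_PER_PIXEL = 0.25


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel size of a raster.

    Parameters
    ----------
    microns_per_pixel : float
        Edge length of one pixel in micrometres; must be positive.
    """

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    @property
    def area_per_pixel(self) -> float:
        """Area of one pixel in square micrometres."""
        return self.microns_per_pixel**2

    def px_to_um(self, px: float) -> float:
        return px * self.microns_per_pixel

    def um_to_px(self, um: float) -> float:
        return um / self.microns_per_pixel


# canonical class names
BACKGROUND = "background"
GLOMERULUS = "full_glomerulus"
TUFT = "glomerular_tuft"
TUBULE = "tubule"
ARTERY = "artery"
LUMEN = "arterial_lumen"
BORDER = "border"

#: parent -> child containment pairs (tuft inside glomerulus, lumen inside artery)
CONTAINMENT = {TUFT: GLOMERULUS, LUMEN: ARTERY}


@dataclass(frozen=True)
class ClassSchema:
    """Ordered mapping of class names to integer label codes.

    Exactly one class must be the background (which by annotation
    convention also absorbs large veins); the border class is optional
    and is only present in rasters prepared for instance separation.
    """

    codes: Mapping[str, int] = field(
        default_factory=lambda: {
            BACKGROUND: 0,
            GLOMERULUS: 1,
            TUFT: 2,
            TUBULE: 3,
            ARTERY: 4,
            LUMEN: 5,
        }
    )

    def __post_init__(self) -> None:
        vals = list(self.codes.values())
        if len(set(vals)) != len(vals):
            raise ValueError(f"duplicate label codes in schema: {self.codes}")
        if BACKGROUND not in self.codes:
            raise ValueError("schema must contain a background class")

    # -- lookups ---------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.codes

    def code(self, name: str) -> int:
        try:
            return self.codes[name]
        except KeyError:
            raise KeyError(f"unknown class name {name!r}; known: {list(self.codes)}")

    def name(self, code: int) -> str:
        for k, v in self.codes.items():
            if v == code:
                return k
        raise KeyError(f"unknown label code {code}; known: {dict(self.codes)}")

    @property
    def background_code(self) -> int:
        return self.codes[BACKGROUND]

    @property
    def border_code(self) -> int | None:
        return self.codes.get(BORDER)

    @property
    def structure_names(self) -> list[str]:
        """Class names that represent tissue structures (not background/border)."""
        return [n for n in self.codes if n not in (BACKGROUND, BORDER)]

    def with_border(self, code: int | None = None) -> "ClassSchema":
        """Return a copy of the schema with a border class added."""
        if BORDER in self.codes:
            raise ValueError("schema already has a border class")
        if code is None:
            code = max(self.codes.values()) + 1
        return ClassSchema({**self.codes, BORDER: code})

    def without_border(self) -> "ClassSchema":
        return ClassSchema({k: v for k, v in self.codes.items() if k != BORDER})


DEFAULT_SCHEMA = ClassSchema()


@dataclass
class SemanticMap:
    """A 2-D class-label raster with calibration and provenance keys."""

    labels: np.ndarray
    schema: ClassSchema = field(default_factory=ClassSchema)
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    slide_id: str | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist())
        known = set(self.schema.codes.values())
        unknown = present - known
        if unknown:
            raise ValueError(
                f"raster contains label codes not in schema: {sorted(unknown)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == self.schema.code(name)

    def tissue_area_um2(self) -> float:
        """Area of non-background (and non-border) pixels in um^2."""
        bg = self.schema.background_code
        mask = self.labels != bg
        border = self.schema.border_code
        if border is not None:
            mask &= self.labels != border
        return float(mask.sum()) * self.calibration.area_per_pixel


# ---------------------------------------------------------------------------
# Label-image I/O
# ---------------------------------------------------------------------------

def read_label_image(
    path: str | Path,
    schema: ClassSchema = DEFAULT_SCHEMA,
    calibration: PixelCalibration | None = None,
    slide_id: str | None = None,
    patient_id: str | None = None,
) -> SemanticMap:
    """Read a single-channel integer label image (TIFF/PNG) as a SemanticMap.

    Raises if the image is multi-channel or contains codes outside the
    schema (the offending codes are named in the error).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel label image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path}: label image must be integer-typed, got {arr.dtype}")
    return SemanticMap(
        labels=arr.astype(np.int32),
        schema=schema,
        calibration=calibration or PixelCalibration(),
        slide_id=slide_id,
        patient_id=patient_id,
    )


def write_label_image(sm: SemanticMap, path: str | Path) -> Path:
    """Write a SemanticMap as an 8- or 16-bit single-channel image.

    Round-trips bit-exactly with :func:`read_label_image`.
    """
    path = Path(path)
    maxcode = max(sm.schema.codes.values())
    dtype = np.uint8 if maxcode < 256 else np.uint16
    arr = sm.labels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    return path


# ---------------------------------------------------------------------------
# QuPath-style GeoJSON annotations
# ---------------------------------------------------------------------------

def _classification_name(props: Mapping) -> str | None:
    cls = props.get("classification")
    if isinstance(cls, Mapping):
        return cls.get("name")
    if isinstance(cls, str):
        return cls
    return props.get("name")


def read_geojson_annotations(path: str | Path) -> list[tuple[Polygon, str]]:
    """Read a QuPath-dialect GeoJSON FeatureCollection.

    Returns (polygon, class-name) pairs; the class name is taken from the
    feature's ``classification.name`` property.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    out: list[tuple[Polygon, str]] = []
    for feat in feats:
        geom = shapely_shape(feat["geometry"])
        name = _classification_name(feat.get("properties", {}))
        if name is None:
            raise ValueError("annotation feature lacks a classification name")
        if geom.geom_type == "MultiPolygon":
            for g in geom.geoms:
                out.append((g, name))
        else:
            out.append((geom, name))
    return out


#: draw order guaranteeing that nested children overwrite their parents
_DRAW_ORDER = {BACKGROUND: 0, TUBULE: 1, GLOMERULUS: 2, ARTERY: 2, TUFT: 3, LUMEN: 3}


def rasterize_annotations(
    annotations: Iterable[tuple[Polygon, str]],
    schema: ClassSchema = DEFAULT_SCHEMA,
    calibration: PixelCalibration | None = None,
    canvas_shape: tuple[int, int] = (512, 512),
    class_map: Mapping[str, str] | None = None,
) -> SemanticMap:
    """Rasterize polygon annotations onto a label canvas.

    Nested structures are drawn parent-first so that tuft pixels overwrite
    their glomerulus and lumen pixels overwrite their artery, matching the
    annotation convention in which the full glomerulus (or artery) region
    includes its child.

    Parameters
    ----------
    annotations : iterable of (shapely Polygon, class name)
    class_map : optional mapping from annotation class names to schema names.
    """
    labels = np.full(canvas_shape, schema.background_code, dtype=np.int32)
    items = []
    for poly, name in annotations:
        mapped = (class_map or {}).get(name, name)
        if mapped not in schema:
            raise KeyError(
                f"annotation class {name!r} (mapped to {mapped!r}) not in schema"
            )
        if not poly.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon for class {name!r}")
        items.append((poly, mapped))
    items.sort(key=lambda it: _DRAW_ORDER.get(it[1], 1))
    for poly, name in items:
        ext = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(ext[:, 1], ext[:, 0], shape=canvas_shape)
        mask = np.zeros(canvas_shape, dtype=bool)
        mask[rr, cc] = True
        for ring in poly.interiors:
            hole = np.asarray(ring.coords)
            rr, cc = draw_polygon(hole[:, 1], hole[:, 0], shape=canvas_shape)
            mask[rr, cc] = False
        labels[mask] = schema.code(name)
    return SemanticMap(
        labels=labels, schema=schema, calibration=calibration or PixelCalibration()
    )


# ---------------------------------------------------------------------------
# WSI-style grid tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tile:
    """One grid tile; ``row0:row1, col0:col1`` are half-open pixel extents."""

    row0: int
    col0: int
    row1: int
    col1: int
    raster: np.ndarray


@dataclass
class TileSet:
    tiles: list[Tile]
    source_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


def tile_grid(
    raster: np.ndarray,
    calibration: PixelCalibration,
    tile_size_um: float = 2500.0,
    out_px: int = 512,
    white_fraction_cutoff: float = 0.9,
    white_threshold: float = 230.0,
) -> TileSet:
    """Extract a non-overlapping grid of tiles and drop near-empty ones.

    Square regions of ``tile_size_um`` a side are taken in a grid over the
    raster, any tile whose white-background fraction is at least
    ``white_fraction_cutoff`` is discarded, and retained tiles are resampled
    to ``out_px`` x ``out_px``. "White" is mean channel intensity >=
    ``white_threshold`` for RGB rasters, and the background code 0 for
    integer label rasters.
    """
    raster = np.asarray(raster)
    h, w = raster.shape[:2]
    size_px = int(round(calibration.um_to_px(tile_size_um)))
    if size_px > max(h, w):
        warnings.warn(
            f"tile size {size_px} px exceeds image extent {(h, w)}; "
            "returning the whole image as one tile",
            stacklevel=2,
        )
        size_px = max(h, w)
    tiles: list[Tile] = []
    for r0 in range(0, h - size_px + 1, size_px):
        for c0 in range(0, w - size_px + 1, size_px):
            sub = raster[r0 : r0 + size_px, c0 : c0 + size_px]
            if _white_fraction(sub, white_threshold) >= white_fraction_cutoff:
                continue
            tiles.append(Tile(r0, c0, r0 + size_px, c0 + size_px, _resample(sub, out_px)))
    return TileSet(tiles=tiles, source_shape=(h, w))


def _white_fraction(sub: np.ndarray, white_threshold: float) -> float:
    if sub.ndim == 3:
        white = sub.mean(axis=-1) >= white_threshold
    elif np.issubdtype(sub.dtype, np.integer):
        white = sub == 0
    else:
        white = sub >= white_threshold
    return float(white.mean())


def _resample(sub: np.ndarray, out_px: int) -> np.ndarray:
    if sub.shape[0] == out_px and sub.shape[1] == out_px:
        return sub.copy()
    if np.issubdtype(sub.dtype, np.integer):
        out = resize(sub, (out_px, out_px) + sub.shape[2:], order=0,
                     preserve_range=True, anti_aliasing=False)
        return out.astype(sub.dtype)
    return resize(sub, (out_px, out_px) + sub.shape[2:], preserve_range=True)
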