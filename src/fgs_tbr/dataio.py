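"""Domain containers and file I/O for fluorescence cases.

A "case" is a monochrome fluorescence image (16-bit TIFF by convention), an
aligned ground-truth label mask (8-bit PNG: 0 unlabeled, 1 tumor, 2 healthy),
an optional color photograph (8-bit RGB PNG), and a patient record from the
study manifest (CSV).  Everything downstream — TBR computation, cohort
comparison, pixel classification — consumes these containers.

Coordinate convention is 0-based (row, col); polygon rasterization labels a
pixel iff its center lies inside the polygon.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path as FsPath
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .exceptions import DataIntegrityError

logger = logging.getLogger(__name__)

LABEL_UNLABELED, LABEL_TUMOR, LABEL_HEALTHY = 0, 1, 2
VALID_LABELS = frozenset({LABEL_UNLABELED, LABEL_TUMOR, LABEL_HEALTHY})

ACQUISITION_CONTEXTS = ("in_situ", "ex_vivo_whole", "cavity", "grossing")
COHORTS = ("EPR", "ANGIO")

MANIFEST_COLUMNS = [
    "patient_id",
    "cohort",
    "image_path",
    "mask_path",
    "color_path",
    "injection_to_imaging_min",
    "tumor_depth_mm",
    "age_years",
    "bmi",
    "subtype",
    "receptor_status",
    "acquisition_context",
]


@dataclass
class FluorescenceImage:
    """2D intensity raster with bit depth and acquisition context."""

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_scale_mm: float | None = None
    acquisition_context: str = "ex_vivo_whole"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DataIntegrityError("fluorescence raster must be non-empty and 2D")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if np.any(self.pixels < 0):
                raise DataIntegrityError("pixel values must be nonnegative")
        if self.pixels.max(initial=0) >= 2**self.bit_depth:
            raise DataIntegrityError(
                f"pixel values exceed {self.bit_depth}-bit range"
            )
        if self.acquisition_context not in ACQUISITION_CONTEXTS:
            raise DataIntegrityError(
                f"unknown acquisition context {self.acquisition_context!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionMask:
    """Per-pixel label map aligned to a fluorescence image.

    Labels: 0 unlabeled, 1 tumor, 2 healthy.  Analysis operations require at
    least one pixel of each labeled class.
    """

    labels: np.ndarray
    source: str = "synthetic"  # "contour" | "synthetic"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise DataIntegrityError("mask must be non-empty and 2D")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise DataIntegrityError(
                f"mask contains labels outside {{0,1,2}}: {sorted(present - VALID_LABELS)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class PatientRecord:
    """Per-patient study metadata: cohort, injection timing, demographics,
    tumor depth and histological subtype."""

    patient_id: str
    cohort: str
    injection_to_imaging_min: float = float("nan")
    age_years: float = float("nan")
    bmi: float = float("nan")
    subtype: str = "unknown"
    receptor_status: str = "unknown"
    tumor_depth_mm: float = float("nan")
    invasive_size_mm: float = float("nan")

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise DataIntegrityError(f"unknown cohort {self.cohort!r}")
        if np.isfinite(self.tumor_depth_mm) and self.tumor_depth_mm < 0:
            raise DataIntegrityError("tumor depth must be nonnegative")


@dataclass
class Case:
    """A loaded image/mask/patient triple plus optional color photograph."""

    image: FluorescenceImage
    mask: RegionMask
    patient: PatientRecord
    color: np.ndarray | None = None
    image_id: str = ""


# ---------------------------------------------------------------------------
# file I/O


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise DataIntegrityError(f"unsupported image dtype {arr.dtype}")


def read_fluorescence(path, acquisition_context: str = "ex_vivo_whole") -> FluorescenceImage:
    path = FsPath(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise DataIntegrityError(f"{path} is not a single-channel image")
    return FluorescenceImage(arr, _bit_depth_of(arr), acquisition_context=acquisition_context)


def write_fluorescence(path, image: FluorescenceImage) -> None:
    path = FsPath(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def read_mask(path, source: str = "contour") -> RegionMask:
    arr = np.asarray(iio.imread(FsPath(path)))
    if arr.ndim != 2:
        raise DataIntegrityError(f"{path} is not a single-channel label image")
    return RegionMask(arr, source=source)


def write_mask(path, mask: RegionMask) -> None:
    path = FsPath(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, mask.labels.astype(np.uint8))


def write_color(path, rgb: np.ndarray) -> None:
    path = FsPath(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb.astype(np.uint8))


def patient_from_row(row: Mapping) -> PatientRecord:
    def _f(key, default=float("nan")):
        v = row.get(key, default) if hasattr(row, "get") else row[key]
        try:
            return float(v)
        except (TypeError, ValueError):
            return default

    return PatientRecord(
        patient_id=str(row["patient_id"]),
        cohort=str(row["cohort"]),
        injection_to_imaging_min=_f("injection_to_imaging_min"),
        age_years=_f("age_years"),
        bmi=_f("bmi"),
        subtype=str(row.get("subtype", "unknown")),
        receptor_status=str(row.get("receptor_status", "unknown")),
        tumor_depth_mm=_f("tumor_depth_mm"),
        invasive_size_mm=_f("invasive_size_mm"),
    )


def load_case(row: Mapping, root: FsPath | str | None = None) -> Case:
    """Load one manifest row into a validated :class:`Case`.

    ``root`` resolves relative paths in the manifest.  Raises
    :class:`DataIntegrityError` when the mask shape disagrees with the image
    or the mask contains labels outside {0, 1, 2}.
    """
    root = FsPath(root) if root is not None else FsPath(".")

    def _resolve(p):
        p = FsPath(str(p))
        return p if p.is_absolute() else root / p

    context = str(row.get("acquisition_context", "ex_vivo_whole"))
    image = read_fluorescence(_resolve(row["image_path"]), acquisition_context=context)
    mask = read_mask(_resolve(row["mask_path"]))
    if mask.shape != image.shape:
        raise DataIntegrityError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    color = None
    color_path = row.get("color_path", "")
    if color_path and str(color_path) != "nan":
        color = np.asarray(iio.imread(_resolve(color_path)))
    patient = patient_from_row(row)
    image_id = str(row.get("image_id", "") or FsPath(str(row["image_path"])).stem)
    return Case(image=image, mask=mask, patient=patient, color=color, image_id=image_id)


# ---------------------------------------------------------------------------
# contours


def rasterize_contours(polygons: Sequence[Mapping], shape: tuple[int, int]) -> RegionMask:
    """Rasterize labeled polygons to a :class:`RegionMask`.

    Each polygon is ``{"label": "tumor"|"healthy", "vertices": [[r, c], ...]}``
    with 0-based (row, col) vertices.  A pixel is labeled iff its center lies
    inside the polygon.  Where tumor and healthy polygons overlap, tumor wins
    and a warning is logged.
    """
    h, w = shape
    labels = np.zeros((h, w), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    label_codes = {"tumor": LABEL_TUMOR, "healthy": LABEL_HEALTHY}
    masks: list[tuple[int, np.ndarray]] = []
    for poly in polygons:
        name = poly["label"]
        if name not in label_codes:
            raise ValueError(f"unknown contour label {name!r}")
        verts = np.asarray(poly["vertices"], dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise ValueError("polygon needs at least 3 (row, col) vertices")
        if np.any(verts < -0.5) or np.any(verts[:, 0] > h - 0.5) or np.any(verts[:, 1] > w - 0.5):
            raise ValueError("polygon vertices outside raster bounds")
        if not ShapelyPolygon(verts).is_valid:
            raise ValueError("self-intersecting polygon")
        inside = MplPath(verts).contains_points(centers).reshape(h, w)
        masks.append((label_codes[name], inside))

    # healthy first so tumor takes precedence on overlap
    for code, inside in masks:
        if code == LABEL_HEALTHY:
            labels[inside] = LABEL_HEALTHY
    for code, inside in masks:
        if code == LABEL_TUMOR:
            overlap = inside & (labels == LABEL_HEALTHY)
            if np.any(overlap):
                logger.warning(
                    "tumor and healthy contours overlap on %d px; tumor takes precedence",
                    int(overlap.sum()),
                )
                warnings.warn(
                    "tumor and healthy contours overlap; tumor takes precedence",
                    stacklevel=2,
                )
            labels[inside] = LABEL_TUMOR
    return RegionMask(labels, source="contour")


def read_contours(path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise DataIntegrityError("contour file must hold a JSON list")
    return data


# ---------------------------------------------------------------------------
# pixel extraction


def extract_pixel_samples(
    image: FluorescenceImage, mask: RegionMask
) -> tuple[np.ndarray, np.ndarray]:
    """All tumor-labeled and all healthy-labeled intensities, in that order.

    Unlabeled pixels are never included; the two collections partition the
    labeled pixels exactly.  Raises if either class is absent.
    """
    if mask.shape != image.shape:
        raise DataIntegrityError("mask and image shapes differ")
    tumor = np.asarray(image.pixels[mask.labels == LABEL_TUMOR], dtype=float)
    healthy = np.asarray(image.pixels[mask.labels == LABEL_HEALTHY], dtype=float)
    if tumor.size == 0 or healthy.size == 0:
        raise ValueError("mask must contain both tumor and healthy pixels")
    return tumor, healthy
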