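"""Raster and annotation I/O.

The pipeline works on single-frame grayscale slices.  Intensities are kept
as floats in [0, 255] internally and quantized (round half up) only on
export.  All coordinates are 0-based with x = column, y = row and the
origin at the top-left corner; point files and the label JSON use the same
convention.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ImageIOError, UnsupportedFormatError, ValidationError

MODALITIES = ("PET", "CT", "FUSED")
SUV_CLASSES = ("malignant", "critical", "benign", "unknown")

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}
_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def round_half_up(values):
    """Round with ties away from zero-point-five upward (127.5 -> 128)."""
    return np.floor(np.asarray(values, dtype=float) + 0.5)


@dataclass
class GrayImage:
    """A 2-D grayscale slice.

    ``pixels`` is a float array indexed ``[row, col]`` i.e. ``[y, x]``;
    values live in [0, 255] (floats until export).
    """

    pixels: np.ndarray
    modality: str = "CT"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixel grid must be a nonempty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel values must be finite")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        """(width, height)."""
        return self.width, self.height

    def to_uint8(self) -> np.ndarray:
        return round_half_up(np.clip(self.pixels, 0, 255)).astype(np.uint8)


def read_gray_image(path, modality: str = "CT") -> GrayImage:
    """Read a single-frame grayscale DICOM, PNG or TIFF slice.

    DICOM stored values are rescaled to [0, 255] by linear min-max scaling
    (round half up); a constant slice maps to all zeros.  PNG/TIFF 8-bit
    values pass through unchanged.
    """
    path = Path(path)
    if not path.is_file():
        raise ImageIOError(f"cannot read image: no such file {path}")
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        pixels = _read_dicom(path)
    elif suffix in _RASTER_SUFFIXES:
        pixels = _read_raster(path)
    else:
        raise UnsupportedFormatError(
            f"unrecognized image extension {suffix!r} for {path}"
        )
    return GrayImage(pixels, modality=modality, source_id=path.name)


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises a mixed bag of types
        raise ImageIOError(f"cannot read DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1 or arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: only single-frame grayscale DICOM is supported"
        )
    arr = arr.astype(float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return round_half_up((arr - lo) / (hi - lo) * 255.0)


def _read_raster(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) != 1:
                raise UnsupportedFormatError(
                    f"{path}: multi-frame images are not supported"
                )
            if im.mode != "L":
                raise UnsupportedFormatError(
                    f"{path}: expected 8-bit grayscale (mode 'L'), got {im.mode!r}"
                )
            return np.asarray(im, dtype=float)
    except UnidentifiedImageError as exc:
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc


def write_gray_image(img: GrayImage, path) -> None:
    """Write an 8-bit grayscale PNG (values rounded half up, clipped)."""
    path = Path(path)
    try:
        Image.fromarray(img.to_uint8(), mode="L").save(str(path), format="PNG")
    except OSError as exc:
        raise ImageIOError(f"cannot write image to {path}: {exc}") from exc


def write_rgb_image(rgb: np.ndarray, path) -> None:
    """Write an (H, W, 3) uint8 array as an RGB PNG (pseudocolor overlays)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) RGB array")
    path = Path(path)
    try:
        Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(str(path), format="PNG")
    except OSError as exc:
        raise ImageIOError(f"cannot write image to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# control points
# ---------------------------------------------------------------------------

@dataclass
class ControlPointSet:
    """Paired landmarks: ``source`` on the moving (PET) image, ``target``
    on the fixed (CT) image; shape (n, 2) each, columns (x, y)."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValidationError(
                "source and target must be equal-length lists of (x, y) pairs"
            )
        if len(self) < 3:
            raise ValidationError(
                f"at least 3 point pairs are required, got {len(self)}"
            )
        if points_collinear(self.source):
            raise ValidationError("source points must not all be collinear")

    def __len__(self) -> int:
        return self.source.shape[0]


def points_collinear(points: np.ndarray, rtol: float = 1e-9) -> bool:
    """True when all points lie (numerically) on a single line."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv.size < 2 or sv[0] == 0.0:
        return True
    return sv[1] < rtol * max(1.0, sv[0])


_CP_HEADER = ["x", "y", "x_prime", "y_prime"]


def read_control_points(path) -> ControlPointSet:
    """Read a ``x,y,x_prime,y_prime`` CSV of landmark pairs."""
    path = Path(path)
    if not path.is_file():
        raise ImageIOError(f"cannot read control points: no such file {path}")
    src, tgt = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty control-point file") from None
        if [c.strip() for c in header] != _CP_HEADER:
            raise ValidationError(
                f"{path}: expected header {','.join(_CP_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y, xp, yp = (float(c) for c in row)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: malformed control-point row {lineno}: {row!r}"
                ) from exc
            src.append((x, y))
            tgt.append((xp, yp))
    return ControlPointSet(np.array(src, dtype=float).reshape(-1, 2),
                           np.array(tgt, dtype=float).reshape(-1, 2))


def write_control_points(points: ControlPointSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CP_HEADER)
        for (x, y), (xp, yp) in zip(points.source, points.target):
            writer.writerow([repr(float(x)), repr(float(y)),
                             repr(float(xp)), repr(float(yp))])


# ---------------------------------------------------------------------------
# label export
# ---------------------------------------------------------------------------

@dataclass
class LabelRecord:
    """One annotated lesion on one image: the boundary polygon traced on
    the registered PET, its tight bounding rectangle, the refined seed and
    an SUV-based class (``unknown`` when no tracer reading is available)."""

    image_id: str
    lesion_id: int
    polygon: list = field(default_factory=list)
    bbox: tuple = (0, 0, 0, 0)
    label_text: str = ""
    seed: tuple = (0, 0)
    suv_class: str = "unknown"

    def validate(self) -> None:
        ident = f"record image_id={self.image_id!r} lesion_id={self.lesion_id}"
        if int(self.lesion_id) < 1:
            raise ValidationError(f"{ident}: lesion_id must be >= 1")
        if self.suv_class not in SUV_CLASSES:
            raise ValidationError(
                f"{ident}: suv_class must be one of {SUV_CLASSES}"
            )
        x_min, y_min, x_max, y_max = self.bbox
        if x_min > x_max or y_min > y_max:
            raise ValidationError(f"{ident}: bbox min exceeds max")
        if min(x_min, y_min) < 0:
            raise ValidationError(f"{ident}: bbox has negative coordinates")
        if len(self.polygon) < 1:
            raise ValidationError(f"{ident}: polygon needs at least 1 vertex")
        for (vx, vy) in self.polygon:
            if not (x_min <= vx <= x_max and y_min <= vy <= y_max):
                raise ValidationError(
                    f"{ident}: polygon vertex ({vx}, {vy}) outside bbox"
                )


def export_labels(records: Sequence[LabelRecord], path) -> None:
    """Write the label JSON document.

    Schema::

        {"images": [{"image_id": ..., "lesions": [
            {"lesion_id", "seed", "polygon", "bbox", "label_text",
             "suv_class"}]}]}

    Coordinates are 0-based, x = column, y = row.
    """
    grouped: dict[str, list[LabelRecord]] = {}
    for rec in records:
        rec.validate()
        grouped.setdefault(rec.image_id, []).append(rec)
    doc = {
        "images": [
            {
                "image_id": image_id,
                "lesions": [
                    {
                        "lesion_id": int(rec.lesion_id),
                        "seed": [int(rec.seed[0]), int(rec.seed[1])],
                        "polygon": [[int(x), int(y)] for x, y in rec.polygon],
                        "bbox": [int(v) for v in rec.bbox],
                        "label_text": rec.label_text,
                        "suv_class": rec.suv_class,
                    }
                    for rec in recs
                ],
            }
            for image_id, recs in grouped.items()
        ]
    }
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise ImageIOError(f"cannot write labels to {path}: {exc}") from exc


def import_labels(path) -> list[LabelRecord]:
    """Inverse of :func:`export_labels` (round-trip support)."""
    with open(path) as fh:
        doc = json.load(fh)
    records: list[LabelRecord] = []
    for image in doc["images"]:
        for les in image["lesions"]:
            records.append(
                LabelRecord(
                    image_id=image["image_id"],
                    lesion_id=int(les["lesion_id"]),
                    polygon=[tuple(v) for v in les["polygon"]],
                    bbox=tuple(les["bbox"]),
                    label_text=les["label_text"],
                    seed=tuple(les["seed"]),
                    suv_class=les["suv_class"],
                )
            )
    for rec in records:
        rec.validate()
    return records
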