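"""Calibrated raster images, label maps, and TIFF / CSV / JSON round-trips.

Conventions used everywhere in this package:

* pixel coordinates are ``(row, col)``, 0-based, origin at the top-left;
* lengths are reported in µm via ``pixel_size_um`` and areas in µm² via
  ``pixel_size_um ** 2``;
* label maps use 0 for background and contiguous positive integers
  ``1..n`` for objects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Type, TypeVar

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "RasterImage",
    "LabelMap",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "write_records",
    "read_records",
]


@dataclass(frozen=True)
class RasterImage:
    """A single 2-D fluorescence channel with its spatial calibration.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary units).
    pixel_size_um
        Physical pixel pitch in µm/pixel; must be positive.
    channel_name
        Free-text channel label (e.g. ``"talin-1"``, ``"F-actin"``).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.number):
            raise ValueError(f"pixels must be numeric, got dtype {px.dtype}")
        if not np.all(np.isfinite(px.astype(np.float64, copy=False))):
            raise ValueError("pixels contain NaN or Inf")
        if np.any(px < 0):
            raise ValueError("pixels contain negative intensities")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        return RasterImage(pixels, self.pixel_size_um, self.channel_name)


@dataclass(frozen=True)
class LabelMap:
    """Integer label image: 0 background, objects labelled 1..n with no gaps."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise ValueError("labels contain negative values")
        present = np.unique(lab)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if present.size != n:
            raise ValueError("label set has gaps; expected exactly {1..n}")
        object.__setattr__(self, "labels", lab)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


# --- TIFF I/O ----------------------------------------------------------------

#: TIFF ResolutionUnit tag value for centimetres.
_RESUNIT_CM = 3
_UM_PER_CM = 1.0e4


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write a channel as a single-plane 16-bit grayscale TIFF.

    Intensities are rounded and clipped to the 16-bit range; the pixel size
    is stored in the TIFF X/YResolution tags (pixels per centimetre).
    """
    data = np.clip(np.round(np.asarray(image.pixels, dtype=np.float64)), 0, 65535)
    px_per_cm = _UM_PER_CM / image.pixel_size_um
    tifffile.imwrite(
        Path(path),
        data.astype(np.uint16),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit=_RESUNIT_CM,
    )


def read_image(path: str | Path, pixel_size_um: float | None = None,
               channel_name: str = "") -> RasterImage:
    """Read a single-plane grayscale TIFF as a :class:`RasterImage`.

    Calibration comes from ``pixel_size_um`` when given; otherwise it is
    derived from the TIFF resolution tags. An explicit argument always wins
    over the tags.
    """
    path = Path(path)
    if pixel_size_um is not None and pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-plane TIFF not supported (pages={len(tif.pages)})")
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise ValueError(f"{path}: expected single-channel grayscale, got shape {data.shape}")
        if pixel_size_um is None:
            pixel_size_um = _pixel_size_from_tags(page)
            if pixel_size_um is None:
                raise ValueError(
                    f"{path}: no usable resolution tags; pass pixel_size_um explicitly")
    return RasterImage(data, pixel_size_um, channel_name)


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    px_per_unit = num / den
    unit_value = getattr(unit, "value", unit)
    unit_value = getattr(unit_value, "value", unit_value)  # enum -> int
    if unit_value == _RESUNIT_CM:
        um_per_unit = _UM_PER_CM
    elif unit_value == 2:  # inch
        um_per_unit = 2.54e4
    else:
        return None
    return um_per_unit / px_per_unit


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a 16-bit TIFF (labels above 65535 are an error)."""
    if labels.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored in a 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_label_map(path: str | Path) -> LabelMap:
    data = tifffile.imread(Path(path))
    if data.ndim != 2:
        raise ValueError(f"{path}: label map must be 2-D, got shape {data.shape}")
    return LabelMap(data.astype(np.int32))


# --- record CSV I/O ----------------------------------------------------------

R = TypeVar("R")


def write_records(records: Sequence, path: str | Path, record_type: Type | None = None) -> None:
    """Write a list of dataclass records to CSV with a stable column order.

    Floats are written with :func:`repr` precision so that numeric fields
    round-trip exactly. An empty list writes a header-only file, which
    requires ``record_type`` to supply the columns.
    """
    if record_type is None:
        if not records:
            raise ValueError("record_type is required to write an empty record list")
        record_type = type(records[0])
    if not dataclasses.is_dataclass(record_type):
        raise TypeError(f"{record_type} is not a dataclass")
    columns = [f.name for f in dataclasses.fields(record_type)]
    rows = [[getattr(r, c) for c in columns] for r in records]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(Path(path), index=False)


def read_records(path: str | Path, record_type: Type[R]) -> list[R]:
    """Read records written by :func:`write_records` back into dataclasses."""
    if not dataclasses.is_dataclass(record_type):
        raise TypeError(f"{record_type} is not a dataclass")
    try:
        df = pd.read_csv(Path(path), float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    expected = [f.name for f in dataclasses.fields(record_type)]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: columns {list(df.columns)} do not match {record_type.__name__} "
            f"fields {expected}")
    out: list[R] = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for f, value in zip(dataclasses.fields(record_type), row):
            if f.type in ("int", int):
                value = int(value)
            elif f.type in ("float", float) and value is not None:
                value = float(value)
            elif f.type in ("str", str):
                value = "" if (isinstance(value, float) and np.isnan(value)) else str(value)
            kwargs[f.name] = value
        out.append(record_type(**kwargs))
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
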