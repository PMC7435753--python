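"""Readers/writers for standard imaging formats, intensity windowing and
run configuration.

Conventions used everywhere in this package: 0-based (row, col) pixel
indexing with pixel centers at integer coordinates; spacing and origin
enter only through the world<->voxel conversion of annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .phantom import NoduleAnnotation

__all__ = [
    "ImageSlice",
    "RunConfig",
    "read_slice",
    "write_slice",
    "normalize_hu",
    "read_annotations",
    "write_annotations",
]

DEFAULT_HU_WINDOW = (-1000.0, 400.0)


@dataclass
class ImageSlice:
    """A 2D grid of intensities with optional spatial metadata."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)  # mm per pixel (row, col)
    origin: tuple[float, float] | None = None  # world coordinates of pixel (0, 0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("an image slice must be a non-empty 2D grid")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".png"):
        return "png"
    if suffixes.endswith(".mhd") or suffixes.endswith(".mha"):
        return "metaimage"
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def read_slice(path: str | Path, format: str | None = None,
               slice_index: int | None = None) -> ImageSlice:
    """Read a 2D slice from PNG, MetaImage (.mhd/.raw) or NIfTI.

    For volumetric formats ``slice_index`` selects one axial plane
    (defaults to the middle plane); in-plane spacing metadata is kept.
    PNG values are rescaled from their integer range to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format)
    if fmt == "png":
        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse any color channels
            arr = arr.mean(axis=2)
        scale = 65535.0 if arr.dtype == np.uint16 else 255.0
        return ImageSlice(arr.astype(np.float32) / scale)
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        vol = sitk.GetArrayFromImage(img)  # (z, y, x) or (y, x)
        sp = img.GetSpacing()  # (x, y[, z])
        if vol.ndim == 2:
            return ImageSlice(vol.astype(np.float32), spacing=(sp[1], sp[0]),
                              origin=tuple(img.GetOrigin()[1::-1]))
        k = vol.shape[0] // 2 if slice_index is None else slice_index
        if not 0 <= k < vol.shape[0]:
            raise IndexError(f"slice index {k} out of range [0, {vol.shape[0]})")
        return ImageSlice(vol[k].astype(np.float32), spacing=(sp[1], sp[0]),
                          origin=tuple(img.GetOrigin()[1::-1]))
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        if vol.ndim == 2:
            return ImageSlice(vol.astype(np.float32), spacing=(zooms[0], zooms[1]))
        k = vol.shape[2] // 2 if slice_index is None else slice_index
        if not 0 <= k < vol.shape[2]:
            raise IndexError(f"slice index {k} out of range [0, {vol.shape[2]})")
        return ImageSlice(vol[:, :, k].astype(np.float32),
                          spacing=(zooms[0], zooms[1]))
    raise ValueError(f"unknown format {fmt!r}")


def write_slice(image: ImageSlice | np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 16-bit grayscale PNG."""
    values = image.values if isinstance(image, ImageSlice) else np.asarray(image)
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ValueError("write_slice writes 16-bit PNG; use SimpleITK/nibabel for volumes")
    iio.imwrite(path, np.round(np.clip(values, 0, 1) * 65535).astype(np.uint16))


def normalize_hu(values, window: tuple[float, float] = DEFAULT_HU_WINDOW) -> np.ndarray:
    """Clip a raw HU grid to ``[low, high]`` and map it affinely to [0, 1]."""
    low, high = window
    if low >= high:
        raise ValueError(f"inverted HU window: [{low}, {high}]")
    arr = np.asarray(values, dtype=np.float32)
    return (np.clip(arr, low, high) - low) / (high - low)


def read_annotations(path: str | Path, spacing: tuple[float, float] | None = None,
                     origin: tuple[float, float] | None = None) -> list[NoduleAnnotation]:
    """Read a nodule annotation CSV.

    Pixel mode header: ``id,center_row,center_col,diameter``.  World mode
    header: ``id,x_mm,y_mm,diameter_mm`` (requires ``spacing``/``origin``;
    x maps to columns, y to rows).  Malformed rows are reported with
    their line number.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    annotations = []
    if cols[:4] == ["id", "center_row", "center_col", "diameter"]:
        for i, row in df.iterrows():
            try:
                annotations.append(NoduleAnnotation(float(row.center_row),
                                                    float(row.center_col),
                                                    float(row.diameter)))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path.name} line {i + 2}: {exc}") from exc
        return annotations
    if cols[:4] == ["id", "x_mm", "y_mm", "diameter_mm"]:
        if spacing is None or origin is None:
            raise ValueError("world-coordinate annotations need spacing and origin")
        sr, sc = spacing
        orow, ocol = origin
        for i, row in df.iterrows():
            try:
                annotations.append(NoduleAnnotation(
                    center_row=(float(row.y_mm) - orow) / sr,
                    center_col=(float(row.x_mm) - ocol) / sc,
                    diameter=float(row.diameter_mm) / ((sr + sc) / 2.0)))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path.name} line {i + 2}: {exc}") from exc
        return annotations
    raise ValueError(
        f"{path.name}: unrecognised annotation header {cols!r}")


def write_annotations(annotations: list[NoduleAnnotation], path: str | Path) -> None:
    """Write annotations in pixel mode (lossless round-trip)."""
    import pandas as pd

    pd.DataFrame(
        [(i, a.center_row, a.center_col, a.diameter)
         for i, a in enumerate(annotations)],
        columns=["id", "center_row", "center_col", "diameter"],
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Nested run configuration; round-trips losslessly through YAML."""

    phantom: dict = field(default_factory=dict)
    architecture: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
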