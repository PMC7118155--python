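"""Greyscale image and dataset-manifest I/O.

Images are integer-valued 2-D grids with a declared number of quantized grey
levels ``L`` (default 256, matching 8-bit B-mode exports).  Coordinates are
0-based ``(row, column)`` with the origin at the top-left corner; for
ultrasound frames the row index therefore increases with imaging depth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GreyImage",
    "DatasetManifest",
    "load_image",
    "save_image",
    "crop_roi",
    "read_manifest",
    "write_manifest",
]

# ITU-R BT.601 luma weights for RGB -> grey convenience conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GreyImage:
    """An integer grey-level image with ``levels`` quantized grey values.

    Parameters
    ----------
    pixels
        2-D integer array, shape ``(M, N)``; every value must lie in
        ``[0, levels - 1]``.
    levels
        Number of quantized grey levels ``L``.
    source_id
        Free-text provenance tag (file path, phantom spec, ...).
    """

    pixels: np.ndarray
    levels: int = 256
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ValueError("pixels must be integer-valued")
            px = px.astype(np.int64)
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if px.min() < 0 or px.max() > self.levels - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        px = px.astype(np.int64, copy=True)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered (image path, class label) records for one dataset.

    ``labels`` holds the distinct class labels in first-appearance order, so
    downstream class ordering (confusion matrices, tie-breaks) is reproducible
    from the manifest alone.
    """

    entries: tuple[tuple[str, str], ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValueError(f"duplicate image paths in manifest: {dupes}")
        seen: list[str] = []
        for _, lab in self.entries:
            if lab not in seen:
                seen.append(lab)
        labels = self.labels or tuple(seen)
        if set(lab for _, lab in self.entries) - set(labels):
            raise ValueError("every entry label must be a member of labels")
        object.__setattr__(self, "labels", tuple(labels))

    def __len__(self) -> int:
        return len(self.entries)


def _grey_from_array(arr: np.ndarray, levels: int, source_id: str) -> GreyImage:
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = np.rint(arr[:, :, :3].astype(float) @ _LUMA)
    elif arr.ndim != 2:
        raise ValueError(
            f"expected a single-frame greyscale or RGB image, got shape {arr.shape} "
            "(multi-frame images are rejected rather than silently truncated)"
        )
    arr = np.asarray(np.rint(arr), dtype=np.int64)
    if levels < 256:
        # optional requantization of 8-bit input down to L grey levels
        arr = (arr * levels) // 256
    arr = np.clip(arr, 0, levels - 1)
    return GreyImage(arr, levels=levels, source_id=source_id)


def load_image(path: str | Path, levels: int = 256) -> GreyImage:
    """Load a PNG/TIFF/PGM image or CSV integer matrix as a :class:`GreyImage`.

    RGB input is converted to grey with the BT.601 luma weights and rounded.
    For raster formats with ``levels < 256`` the 8-bit values are requantized
    by ``floor(v * levels / 256)``; CSV matrices are taken as already
    quantized and only validated against ``[0, levels - 1]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() == ".csv":
        try:
            arr = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse integer CSV matrix {path}: {exc}") from None
        arr = np.clip(arr, 0, levels - 1)
        return GreyImage(arr, levels=levels, source_id=str(path))
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read image {path}: {exc}") from exc
    return _grey_from_array(np.asarray(arr), levels, source_id=str(path))


def save_image(image: GreyImage, path: str | Path) -> None:
    """Write a :class:`GreyImage` to PNG/TIFF/PGM (8-bit) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, image.pixels, fmt="%d", delimiter=",")
        return
    if image.levels > 256:
        raise ValueError("raster export supports at most 256 grey levels")
    iio.imwrite(path, image.pixels.astype(np.uint8))


def crop_roi(image: GreyImage, top: int, left: int, height: int, width: int) -> GreyImage:
    """Crop a rectangular region of interest; the rectangle must lie inside."""
    M, N = image.shape
    if height < 1 or width < 1:
        raise ValueError("crop height and width must be >= 1")
    if top < 0 or left < 0 or top + height > M or left + width > N:
        raise ValueError(
            f"crop rectangle (top={top}, left={left}, height={height}, width={width}) "
            f"exceeds image bounds {M}x{N}"
        )
    return GreyImage(
        image.pixels[top : top + height, left : left + width].copy(),
        levels=image.levels,
        source_id=image.source_id,
    )


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a ``path,label`` CSV manifest; labels keep first-appearance order."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValueError(f"manifest {path} must have header columns 'path,label'")
        entries = []
        for i, row in enumerate(reader, start=2):
            p, lab = row.get("path"), row.get("label")
            if not p or lab is None or lab == "":
                raise ValueError(f"manifest {path} line {i}: missing path or label")
            entries.append((p, lab))
    if not entries:
        raise ValueError(f"manifest {path} contains no entries")
    return DatasetManifest(tuple(entries))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(manifest.entries)
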