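"""Reading and writing grayscale images (PNG, TIFF, DICOM).

Only lossless formats are accepted.  Images are stored as integers; pixel
values are rounded and clipped to ``[0, 2**bit_depth - 1]`` at write time.
12-bit data travels in a 16-bit TIFF/PNG container with the effective depth
declared by the caller.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ImageIOError, ValidationError
from .image import ImageGrid

_PNG_EXTS = {".png"}
_TIFF_EXTS = {".tif", ".tiff"}
_DICOM_EXTS = {".dcm", ".dicom"}
_LOSSY_EXTS = {".jpg", ".jpeg", ".webp"}


def _infer_bit_depth(arr: np.ndarray, declared: int | None) -> int:
    if declared is not None:
        return declared
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ImageIOError(f"cannot infer bit depth from dtype {arr.dtype}")


def read_image(path: str | Path, bit_depth: int | None = None) -> ImageGrid:
    """Read a grayscale PNG, TIFF or DICOM file.

    ``bit_depth`` overrides the container depth, e.g. declare 12 for 12-bit
    data stored in a 16-bit TIFF.  Multi-channel images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    ext = path.suffix.lower()
    if ext in _LOSSY_EXTS:
        raise ImageIOError(f"lossy format {ext} is not supported")
    if ext in _PNG_EXTS:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    elif ext in _TIFF_EXTS:
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    elif ext in _DICOM_EXTS:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if bit_depth is None and hasattr(ds, "BitsStored"):
            bit_depth = int(ds.BitsStored)
    else:
        raise ImageIOError(f"unknown image extension {ext!r}")
    if arr.ndim != 2:
        raise ImageIOError(
            f"{path.name}: expected a single-channel grayscale image, "
            f"got shape {arr.shape}"
        )
    depth = _infer_bit_depth(arr, bit_depth)
    if depth not in (8, 12, 16):
        raise ValidationError(f"unsupported bit depth {depth}")
    return ImageGrid(pixels=arr.astype(np.float64), bit_depth=depth)


def write_image(image: ImageGrid, path: str | Path) -> None:
    """Write an image losslessly; values are rounded and clipped first."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _LOSSY_EXTS:
        raise ImageIOError(f"refusing lossy output format {ext}")
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = image.clipped().astype(dtype)
    if ext in _PNG_EXTS:
        import imageio.v3 as iio

        iio.imwrite(path, data)
    elif ext in _TIFF_EXTS:
        import tifffile

        tifffile.imwrite(path, data)
    else:
        raise ImageIOError(f"unsupported output extension {ext!r} (PNG/TIFF only)")
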