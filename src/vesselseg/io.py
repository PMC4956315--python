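"""Raster I/O for fundus images and masks.

Images are held internally as floating-point arrays in ``[0, 1]``
(row-major, origin at the top-left corner); integer quantization happens
only at file boundaries.  Color images are ``(H, W, 3)`` arrays, grayscale
images and masks are ``(H, W)``.  The supported formats are the ones the
DRIVE/STARE ecosystem distributes: TIFF, GIF, PPM/PGM, plus PNG and JPEG.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

__all__ = [
    "ImageReadError",
    "UnsupportedFormatError",
    "ImageWriteError",
    "MissingChannelError",
    "read_image",
    "extract_green",
    "estimate_fov_mask",
    "write_binary",
]

SUPPORTED_EXTENSIONS = {
    ".png", ".tif", ".tiff", ".ppm", ".pgm", ".pbm", ".gif", ".jpg", ".jpeg",
}


class ImageReadError(OSError):
    """The file exists but could not be decoded as a raster image."""


class UnsupportedFormatError(ImageReadError):
    """The file extension is outside the supported raster formats."""


class ImageWriteError(OSError):
    """The output path could not be written."""


class MissingChannelError(ValueError):
    """A color-channel operation was applied to a single-channel image."""


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Map integer samples to [0,1] by the format's maximum sample value."""
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        return arr.astype(np.float64) / maxval
    # float input: assume already normalized, clamp defensively
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster image, normalized to [0,1].

    Returns a ``(H, W)`` array for single-channel files and ``(H, W, 3)``
    for color files.  An alpha channel, if present, is dropped; paletted
    GIFs are expanded to RGB by the decoder.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    UnsupportedFormatError
        If the extension is not a supported raster format.
    ImageReadError
        If the file cannot be decoded.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"unsupported image format {ext!r}; expected one of "
            f"{sorted(SUPPORTED_EXTENSIONS)}"
        )
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder errors vary by plugin
        raise ImageReadError(f"could not decode {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 4:  # animated GIF: take the first frame
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3):
        raise ImageReadError(f"unexpected raster shape {arr.shape} in {path!r}")
    return _normalize(arr)


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green channel of a color image, unchanged.

    The green band of a fundus photograph shows the highest vessel/background
    contrast, so the whole pipeline runs on it.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise MissingChannelError(
            "extract_green requires an (H, W, 3) color image; "
            f"got shape {img.shape} (no green channel)"
        )
    return np.array(img[:, :, 1], dtype=np.float64)


def estimate_fov_mask(
    img: np.ndarray, luminance_threshold: float = 0.05
) -> np.ndarray:
    """Estimate the circular field-of-view aperture of a fundus photograph.

    The camera aperture is bright against the dark frame surround, so the
    mask is taken as channel-mean luminance above *luminance_threshold*,
    cleaned by a morphological closing (disk radius 5), keeping only the
    largest connected component.  Use a supplied mask file instead whenever
    one exists (DRIVE ships them; STARE does not).

    An all-dark image yields an empty mask; downstream evaluation rejects
    empty FOVs explicitly.
    """
    if not 0.0 < luminance_threshold < 1.0:
        raise ValueError("luminance_threshold must lie in (0, 1)")
    img = np.asarray(img, dtype=np.float64)
    lum = img.mean(axis=2) if img.ndim == 3 else img
    mask = lum > luminance_threshold
    # skimage's closing treats pixels beyond the border as foreground during
    # the erosion step, so an aperture touching the frame edge is preserved
    mask = closing(mask, footprint=disk(5)).astype(bool)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(lum.shape, dtype=np.uint8)
    sizes = np.bincount(labels.ravel())[1:]
    keep = 1 + int(np.argmax(sizes))
    return (labels == keep).astype(np.uint8)


def write_binary(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit single-channel raster with values {0,255}.

    The format follows the file extension (PNG by convention for masks).
    Reading the result back and thresholding at 0.5 reproduces the mask
    exactly.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    out = np.where(mask > 0, 255, 0).astype(np.uint8)
    path = os.fspath(path)
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise ImageWriteError(f"could not write {path!r}: {exc}") from exc
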