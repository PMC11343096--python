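"""Raster ingestion: read eye images and normalize them to a canonical form.

All downstream stages operate on :class:`EyeImage`, a float grayscale
raster with intensities in [0, 1], the acquisition mode (bright-field or
SEM), and a source label used in output rows.  Orientation is controlled
solely by the ``horizontal`` flag: images are assumed to have the eye's
long axis vertical; horizontally oriented images are rotated a quarter
turn counter-clockwise on load so everything downstream is
orientation-uniform.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "AcquisitionMode",
    "EyeImage",
    "SUPPORTED_EXTENSIONS",
    "UnsupportedFormatError",
    "DegenerateImageError",
    "load_image",
]

SUPPORTED_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")

#: Minimum side length for a raster to be considered a plausible eye image.
MIN_SIDE_PX = 64

# ITU-R BT.601 luma weights, the common convention for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


class AcquisitionMode(str, enum.Enum):
    """How the image was acquired; selects the detection preset."""

    BRIGHTFIELD = "brightfield"
    SEM = "sem"


class UnsupportedFormatError(ValueError):
    """Raised for file extensions outside the supported raster formats."""


class DegenerateImageError(ValueError):
    """Raised for rasters too small to contain an analyzable eye."""


@dataclass(frozen=True)
class EyeImage:
    """A normalized 2-D grayscale eye raster.

    Attributes
    ----------
    pixels:
        2-D float array with values in [0, 1].
    mode:
        Acquisition modality; SEM images have inverted spot polarity.
    source_path:
        Text label (usually the file name) carried into output rows.
    """

    pixels: np.ndarray
    mode: AcquisitionMode = AcquisitionMode.BRIGHTFIELD
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE_PX or px.shape[1] < MIN_SIDE_PX:
            raise DegenerateImageError(
                f"image {self.source_path!r} is {px.shape[1]}x{px.shape[0]}; "
                f"at least {MIN_SIDE_PX}x{MIN_SIDE_PX} required"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mode", AcquisitionMode(self.mode))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _dtype_scale(arr: np.ndarray, pil_mode: str) -> float:
    """Maximum representable value used to rescale intensities to [0, 1]."""
    if pil_mode in ("I;16", "I;16B", "I;16L", "I"):
        return 65535.0
    if pil_mode == "F":
        return 1.0
    if arr.dtype == np.uint16:
        return 65535.0
    return 255.0


def load_image(path: str | os.PathLike, horizontal: bool = False,
               sem: bool = False) -> EyeImage:
    """Read a raster file into a normalized :class:`EyeImage`.

    Parameters
    ----------
    path:
        Image file; one of PNG, JPG/JPEG, BMP, TIF/TIFF (case-insensitive).
    horizontal:
        True if the eye's long axis runs horizontally; the raster is then
        rotated 90 degrees counter-clockwise.
    sem:
        True for scanning-electron-microscopy images.

    Raises
    ------
    UnsupportedFormatError
        For extensions outside the supported set, or multi-page TIFFs.
    DegenerateImageError
        For rasters smaller than 64x64 after rotation.
    OSError
        If the file is missing or unreadable.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"unsupported extension {ext!r} for {path!r}; expected one of "
            + ", ".join(SUPPORTED_EXTENSIONS)
        )
    try:
        with Image.open(path) as img:
            if getattr(img, "n_frames", 1) > 1:
                raise UnsupportedFormatError(
                    f"{path!r} is a multi-page TIFF; single-page only"
                )
            pil_mode = img.mode
            arr = np.asarray(img)
    except FileNotFoundError:
        raise
    except UnsupportedFormatError:
        raise
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise OSError(f"could not read image {path!r}: {exc}") from exc

    arr = arr.astype(float)
    if arr.ndim == 3:
        # Drop alpha if present, then luminance-weight the color channels.
        if arr.shape[2] == 4 or arr.shape[2] == 2:
            arr = arr[..., :-1]
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            arr = arr @ _LUMA
    scale = _dtype_scale(arr, pil_mode)
    px = np.clip(arr / scale, 0.0, 1.0)
    if horizontal:
        px = np.rot90(px, k=1)
    mode = AcquisitionMode.SEM if sem else AcquisitionMode.BRIGHTFIELD
    return EyeImage(pixels=px, mode=mode,
                    source_path=os.path.basename(path))
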