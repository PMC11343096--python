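"""Ommatidium detection: morphological enhancement plus sub-pixel peaks.

The eye region is enhanced with a percentile contrast stretch followed by
a white top-hat (disk structuring element), which flattens smooth
illumination while preserving ommatidium-scale bright spots, and a light
Gaussian smoothing for peak finding.  Candidate centroids are local maxima
of the enhanced raster above a relative threshold; each is refined to
sub-pixel precision by a background-subtracted intensity centroid over a
window sized from the lattice's own median nearest-neighbor spacing, then
deduplicated so no two detections lie within ``merge_distance_px``.

SEM images are handled by the same code path under an inverted-contrast
preset: their ommatidia are shaded domes (dark centers on a bright field)
rather than bright spots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import gaussian
from skimage.morphology import disk, white_tophat

from .image_ingest import AcquisitionMode, EyeImage

__all__ = [
    "DetectionConfig",
    "OmmatidiumDetection",
    "ConfigurationError",
    "preprocess",
    "detect_ommatidia",
    "draw_overlay",
]


class ConfigurationError(ValueError):
    """Raised for detection settings inconsistent with the image."""


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable detection parameters; one preset per acquisition mode.

    ``structuring_radius_px`` must exceed the ommatidium radius (so the
    top-hat keeps the spots) but stay well below the eye scale (so it
    removes shading); ``peak_threshold`` is relative to the brightest
    enhanced peak; ``merge_distance_px`` enforces one circle per
    ommatidium and defaults to ``min_spot_radius_px``.
    """

    preset: AcquisitionMode = AcquisitionMode.BRIGHTFIELD
    structuring_radius_px: int = 9
    min_spot_radius_px: float = 1.5
    max_spot_radius_px: float = 12.0
    peak_threshold: float = 0.25
    merge_distance_px: float | None = None
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "preset", AcquisitionMode(self.preset))
        if self.structuring_radius_px < 1:
            raise ValueError("structuring_radius_px must be a positive "
                             "integer")
        if not 0 < self.min_spot_radius_px < self.max_spot_radius_px:
            raise ValueError("need 0 < min_spot_radius_px < "
                             "max_spot_radius_px")
        if not 0 < self.peak_threshold < 1:
            raise ValueError("peak_threshold must lie strictly in (0, 1)")
        if self.merge_distance_px is None:
            object.__setattr__(self, "merge_distance_px",
                               float(self.min_spot_radius_px))
        if self.merge_distance_px < 0:
            raise ValueError("merge_distance_px must be >= 0")

    @classmethod
    def for_mode(cls, mode: AcquisitionMode) -> "DetectionConfig":
        """The default preset for an acquisition mode."""
        mode = AcquisitionMode(mode)
        if mode is AcquisitionMode.SEM:
            # Shaded domes are broader than bright-field spots; a larger
            # structuring element keeps the whole facet after inversion.
            return cls(preset=mode, structuring_radius_px=12)
        return cls(preset=mode)


@dataclass(frozen=True)
class OmmatidiumDetection:
    """One detected ommatidium: sub-pixel centroid and fitted radius.

    Coordinates are 0-based pixel centers, x rightward, y downward.
    """

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _check_config(image: EyeImage, config: DetectionConfig) -> None:
    if config.preset is not image.mode:
        raise ConfigurationError(
            f"config preset {config.preset.value!r} does not match image "
            f"mode {image.mode.value!r}")
    limit = min(image.height, image.width) / 4
    if config.structuring_radius_px > limit:
        raise ConfigurationError(
            f"structuring_radius_px={config.structuring_radius_px} exceeds "
            f"min(height, width)/4 = {limit:.0f}")


def _contrast_stretch(px: np.ndarray) -> np.ndarray:
    """Affine stretch from the 0.5th percentile up to the maximum onto [0, 1].

    The floor is clipped (it is background); the ceiling is the true
    maximum, never a percentile, so spot peaks are rescaled but not
    saturated — saturation would flatten peak tops and bias sub-pixel
    centroid refinement.
    """
    lo = float(np.percentile(px, 0.5))
    hi = float(px.max())
    if hi <= lo:
        return np.zeros_like(px)
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


def _enhance(image: EyeImage,
             config: DetectionConfig) -> tuple[np.ndarray, np.ndarray]:
    """(top-hat, smoothed top-hat) rasters used by peak finding."""
    px = _contrast_stretch(image.pixels)
    if config.preset is AcquisitionMode.SEM:
        px = 1.0 - px
    tophat = white_tophat(px, footprint=disk(config.structuring_radius_px))
    smooth = gaussian(tophat, sigma=config.smoothing_sigma_px,
                      preserve_range=True)
    return tophat, smooth


def preprocess(image: EyeImage, config: DetectionConfig | None = None
               ) -> EyeImage:
    """Enhanced raster in which ommatidia are maxima on a flat background."""
    if config is None:
        config = DetectionConfig.for_mode(image.mode)
    _check_config(image, config)
    _, smooth = _enhance(image, config)
    return EyeImage(pixels=np.clip(smooth, 0.0, 1.0), mode=image.mode,
                    source_path=image.source_path)


def _local_maxima(smooth: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Integer (row, col) peak candidates above the relative threshold."""
    from skimage.feature import peak_local_max

    peak = float(smooth.max())
    if peak <= 1e-9:
        return np.empty((0, 2), dtype=int)
    # Two maxima closer than one spot diameter cannot be two ommatidia;
    # merge_distance_px is additionally enforced after sub-pixel refinement.
    min_dist = max(1, int(round(max(config.merge_distance_px,
                                    2.0 * config.min_spot_radius_px))))
    # The top-hat is unreliable within one structuring radius of the
    # border (the footprint hangs off the raster there), so peaks are not
    # accepted from that rim.
    return peak_local_max(smooth, min_distance=min_dist,
                          threshold_abs=config.peak_threshold * peak,
                          exclude_border=config.structuring_radius_px)


def _refine_centroid(tophat: np.ndarray, cy: float, cx: float,
                     win: float) -> tuple[float, float]:
    """Background-subtracted center of mass in a circular window."""
    h, w = tophat.shape
    half = int(np.ceil(win))
    iy, ix = int(round(cy)), int(round(cx))
    y0, y1 = max(0, iy - half), min(h, iy + half + 1)
    x0, x1 = max(0, ix - half), min(w, ix + half + 1)
    patch = tophat[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = r2 <= win * win
    vals = patch[mask]
    ring = patch[(r2 > (0.8 * win) ** 2) & mask]
    bg = float(np.median(ring)) if ring.size else 0.0
    weights = np.clip(vals - bg, 0.0, None)
    total = weights.sum()
    if total <= 0:
        return cx, cy
    return (float((xx[mask] * weights).sum() / total),
            float((yy[mask] * weights).sum() / total))


def _halfmax_radius(tophat: np.ndarray, cy: float, cx: float,
                    win: float) -> float:
    """Equivalent radius of the above-half-peak area around a centroid."""
    h, w = tophat.shape
    half = int(np.ceil(win))
    iy, ix = int(round(cy)), int(round(cx))
    y0, y1 = max(0, iy - half), min(h, iy + half + 1)
    x0, x1 = max(0, ix - half), min(w, ix + half + 1)
    patch = tophat[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= win * win
    vals = patch[mask]
    if vals.size == 0 or vals.max() <= 0:
        return float("nan")
    area = float(np.count_nonzero(vals >= 0.5 * vals.max()))
    return float(np.sqrt(area / np.pi))


def detect_ommatidia(image: EyeImage, config: DetectionConfig | None = None
                     ) -> list[OmmatidiumDetection]:
    """All ommatidium detections of *image*, sorted by (cy, cx).

    The length of the returned list is the detected count Z.  A blank or
    featureless image yields an empty list; downstream scoring decides how
    to report that.
    """
    if config is None:
        config = DetectionConfig.for_mode(image.mode)
    _check_config(image, config)
    tophat, smooth = _enhance(image, config)
    peaks = _local_maxima(smooth, config)
    if len(peaks) == 0:
        return []

    # Window for centroid refinement: just under half the lattice spacing,
    # so a window never overlaps a neighboring spot's support.
    if len(peaks) >= 2:
        tree = cKDTree(peaks[:, ::-1].astype(float))
        nn = tree.query(peaks[:, ::-1].astype(float), k=2)[0][:, 1]
        spacing = float(np.median(nn))
    else:
        spacing = 4.0 * config.min_spot_radius_px
    win = float(np.clip(0.49 * spacing, 2.0,
                        3.0 * config.structuring_radius_px))

    brightness = smooth[peaks[:, 0], peaks[:, 1]]
    candidates = []
    for (py, px_), b in zip(peaks, brightness):
        cx, cy = _refine_centroid(tophat, float(py), float(px_), win)
        # One recentering pass: the window tracks the refined position.
        cx, cy = _refine_centroid(tophat, cy, cx, win)
        radius = _halfmax_radius(tophat, cy, cx, win)
        if not np.isfinite(radius) or radius <= 0:
            radius = spacing / 2.0           # fall back on lattice spacing
        if not (config.min_spot_radius_px <= radius
                <= config.max_spot_radius_px):
            continue
        if not (0 <= cx < image.width and 0 <= cy < image.height):
            continue
        candidates.append((float(b), cy, cx, radius))

    # Duplicate merging: brightest first, ties by (cy, cx); a candidate
    # within merge_distance_px of an accepted one is discarded.
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[float, float, float]] = []
    md2 = config.merge_distance_px ** 2
    for _, cy, cx, radius in candidates:
        if any((cy - ay) ** 2 + (cx - ax) ** 2 <= md2
               for ay, ax, _ in accepted):
            continue
        accepted.append((cy, cx, radius))

    accepted.sort(key=lambda t: (t[0], t[1]))
    return [OmmatidiumDetection(cx=cx, cy=cy, radius=r)
            for cy, cx, r in accepted]


def draw_overlay(image: EyeImage, detections, out_path) -> None:
    """Write a PNG copy of *image* with detected circles drawn on top.

    Debug aid only; never feeds back into the scores.
    """
    from PIL import Image as PILImage
    from skimage.draw import circle_perimeter

    rgb = np.stack([image.pixels] * 3, axis=-1)
    for det in detections:
        rr, cc = circle_perimeter(int(round(det.cy)), int(round(det.cx)),
                                  max(1, int(round(det.radius))),
                                  shape=image.pixels.shape)
        rgb[rr, cc] = [1.0, 0.1, 0.1]
    PILImage.fromarray((rgb * 255).astype(np.uint8)).save(out_path,
                                                          format="PNG")
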