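"""Disorderliness indices for an ommatidial lattice.

Given the detected ommatidium centroids of one eye, each ommatidium's six
nearest neighbors define a *neighbor fan*: six vectors from its centroid
to theirs.  In a perfectly ordered (wild-type) eye every interior fan is a
regular hexagon — six equal lengths, six 60-degree angular gaps.  Disorder
shows up as unequal lengths and gaps, and is quantified per ommatidium as

    odi_d = sum over the five longest lengths of (length - v_min)
    odi_a = sum over the five largest gaps   of (gap    - theta_min)

where ``v_min`` is the shortest vector and ``theta_min`` the smallest gap
(degrees).  Eye-level indices ODI_D, ODI_A and their sum ODI total these
contributions over the N most-ordered *stable* ommatidia (those with a
geometrically plausible full fan), and the phenotypic severity score is

    P = (ODI / n_used) * (n_requested / Z)

— the mean disorder of the selected ommatidia, amplified when fewer
ommatidia are detected (Z) than requested, since fused or lost facets are
themselves a sign of severity.  Higher P means a rougher eye.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .detection import DetectionConfig, OmmatidiumDetection, detect_ommatidia
from .image_ingest import EyeImage

__all__ = [
    "NeighborFan",
    "LocalDisorder",
    "EyeScore",
    "DEFAULT_N_REQUESTED",
    "STABLE_NEIGHBOR_FACTOR",
    "build_neighbor_fans",
    "local_disorder",
    "select_most_ordered",
    "score_eye",
    "score_points",
    "score_image",
]

logger = logging.getLogger(__name__)

#: Default number of most-ordered ommatidia totalled into ODI (the -n flag).
DEFAULT_N_REQUESTED = 200

#: An ommatidium is *stable* when its six nearest neighbors all lie
#: strictly within this multiple of the image's median nearest-neighbor
#: distance; border and isolated detections fail this and are excluded
#: from fan building.  (Strict: on a regular hexagon of seven points the
#: rim points' sixth neighbor sits exactly at twice the spacing, and only
#: the central point has a geometrically meaningful fan.)
STABLE_NEIGHBOR_FACTOR = 2.0


@dataclass(frozen=True)
class NeighborFan:
    """Six neighbor vectors of one stable ommatidium, sorted by bearing."""

    center_index: int
    neighbor_indices: tuple[int, ...]
    lengths: tuple[float, ...]          # pixels, > 0
    bearings: tuple[float, ...]         # degrees in [0, 360), ascending
    gaps: tuple[float, ...]             # consecutive angular gaps, sum 360

    def __post_init__(self) -> None:
        if len(self.neighbor_indices) != 6:
            raise ValueError("a neighbor fan has exactly six neighbors")
        if len(set(self.neighbor_indices)) != 6 \
                or self.center_index in self.neighbor_indices:
            raise ValueError("neighbor indices must be distinct and "
                             "exclude the center")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("all vector lengths must be positive")
        if abs(sum(self.gaps) - 360.0) > 1e-6:
            raise ValueError("angular gaps must sum to 360 degrees")


@dataclass(frozen=True)
class LocalDisorder:
    """Per-ommatidium disorder contributions; ``odi_local`` orders them."""

    center_index: int
    odi_d: float        # pixels
    odi_a: float        # degrees

    @property
    def odi_local(self) -> float:
        return self.odi_d + self.odi_a


@dataclass(frozen=True)
class EyeScore:
    """Eye-level output row: the five phenotypic values plus bookkeeping.

    ``p`` is None (undefined) when no ommatidia were detected or no stable
    fan exists; the CSV writer renders that as ``NA``.
    """

    odi_d_total: float
    odi_a_total: float
    odi: float
    z: int
    n_requested: int
    n_used: int
    p: float | None

    def __post_init__(self) -> None:
        if self.n_used > self.z:
            raise ValueError("n_used cannot exceed the detected count z")
        if not math.isclose(self.odi, self.odi_d_total + self.odi_a_total,
                            rel_tol=0.0, abs_tol=1e-9):
            raise ValueError("odi must equal odi_d_total + odi_a_total")


def _as_points(detections) -> np.ndarray:
    if isinstance(detections, np.ndarray):
        pts = np.asarray(detections, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (cx, cy)")
        return pts
    return np.array([[d.cx, d.cy] for d in detections], dtype=float)


def build_neighbor_fans(detections) -> list[NeighborFan]:
    """Six-nearest-neighbor fans for every stable ommatidium.

    Parameters
    ----------
    detections:
        Sequence of :class:`~ommatidia.detection.OmmatidiumDetection` or an
        (n, 2) float array of centroids ``(cx, cy)``.

    Returns
    -------
    list of NeighborFan
        One fan per stable detection, in ascending ``center_index`` order.
        Fewer than seven detections, or none passing the stability rule,
        give an empty list (not an error): such an eye has no measurable
        lattice.
    """
    pts = _as_points(detections)
    n = len(pts)
    if n < 7:
        return []
    tree = cKDTree(pts)
    # k=7: self plus the six nearest others.
    dists, idx = tree.query(pts, k=7)
    nn_dist = dists[:, 1]                      # each point's nearest other
    cutoff = STABLE_NEIGHBOR_FACTOR * float(np.median(nn_dist))

    fans: list[NeighborFan] = []
    for i in range(n):
        d6 = dists[i, 1:]
        if d6[-1] >= cutoff:
            continue                            # border / isolated: skip
        nbr = idx[i, 1:]
        vec = pts[nbr] - pts[i]
        bearings = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
        order = np.argsort(bearings, kind="stable")
        bearings = bearings[order]
        lengths = d6[order]
        nbr = nbr[order]
        gaps = np.diff(np.append(bearings, bearings[0] + 360.0))
        fans.append(NeighborFan(
            center_index=i,
            neighbor_indices=tuple(int(j) for j in nbr),
            lengths=tuple(float(l) for l in lengths),
            bearings=tuple(float(b) for b in bearings),
            gaps=tuple(float(g) for g in gaps),
        ))
    return fans


def local_disorder(fan: NeighborFan) -> LocalDisorder:
    """Distance and angle disorder of one fan.

    Both indices are sums of differences against the minimum, so each is
    zero exactly when the fan is a regular hexagon.
    """
    lengths = np.sort(np.asarray(fan.lengths))
    gaps = np.sort(np.asarray(fan.gaps))
    # The five longest vectors each compared with the shortest, v_min;
    # likewise the five largest gaps against the smallest gap.
    odi_d = float(np.sum(lengths[1:] - lengths[0]))
    odi_a = float(np.sum(gaps[1:] - gaps[0]))
    return LocalDisorder(center_index=fan.center_index,
                         odi_d=odi_d, odi_a=odi_a)


def select_most_ordered(locals_: list[LocalDisorder],
                        n_requested: int) -> list[LocalDisorder]:
    """The ``min(n_requested, len)`` entries with smallest ``odi_local``.

    Ties break by ascending ``center_index``; the result is sorted by
    (odi_local, center_index), making selection bit-reproducible.
    """
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    ranked = sorted(locals_, key=lambda l: (l.odi_local, l.center_index))
    return ranked[:min(n_requested, len(ranked))]


def score_eye(locals_: list[LocalDisorder], z: int,
              n_requested: int = DEFAULT_N_REQUESTED) -> EyeScore:
    """Total the selected per-ommatidium contributions into an EyeScore."""
    if n_requested < 1:
        raise ValueError("n_requested must be >= 1")
    if z < len(locals_):
        raise ValueError("z must be at least the number of stable "
                         "ommatidia (stable fans are a subset of "
                         "detections)")
    selected = select_most_ordered(locals_, n_requested)
    n_used = len(selected)
    odi_d_total = float(sum(l.odi_d for l in selected))
    odi_a_total = float(sum(l.odi_a for l in selected))
    odi = odi_d_total + odi_a_total
    if z > 0 and n_used > 0:
        p = (odi / n_used) * (n_requested / z)
    else:
        p = None
    return EyeScore(odi_d_total=odi_d_total, odi_a_total=odi_a_total,
                    odi=odi, z=z, n_requested=n_requested,
                    n_used=n_used, p=p)


def score_points(points: np.ndarray,
                 n_requested: int = DEFAULT_N_REQUESTED,
                 z: int | None = None) -> EyeScore:
    """Score a bare centroid set (detection-free path).

    ``z`` defaults to the number of points; pass it explicitly when the
    centroids are a subset of a larger detection list.
    """
    pts = _as_points(points)
    fans = build_neighbor_fans(pts)
    locs = [local_disorder(f) for f in fans]
    return score_eye(locs, z=len(pts) if z is None else z,
                     n_requested=n_requested)


def score_image(image: EyeImage, config: DetectionConfig | None = None,
                n_requested: int = DEFAULT_N_REQUESTED) -> EyeScore:
    """End-to-end pipeline: detect ommatidia, build fans, score the eye."""
    detections = detect_ommatidia(image, config)
    if not detections:
        logger.warning("no ommatidia detected in %s; P is undefined",
                       image.source_path)
    locs = [local_disorder(f) for f in build_neighbor_fans(detections)]
    return score_eye(locs, z=len(detections), n_requested=n_requested)
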