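"""Vessel mask -> junction-free centerline segments.

The binary vessel mask is thinned to a 1-pixel medial skeleton, junction
pixels (>= 3 skeleton neighbors in the 8-neighborhood, found by a 3x3
ones-kernel convolution) are removed, and each remaining 8-connected
component becomes one junction-to-junction vessel segment with an ordered
centerline, a per-pixel diameter from the Euclidean distance transform of
the mask, an artery/vein class voted from the label map, and a caliber
class (main vs micro) from its mean diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io import AVLabelMap, RunConfig, VesselMask

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element

ARTERIOLE = "arteriole"
VENULE = "venule"
UNKNOWN = "unknown"
MAIN = "main"
MICRO = "micro"


class InvalidSegmentError(ValueError):
    pass


@dataclass(frozen=True)
class Skeleton:
    """1-px-wide medial representation of the vessel mask."""

    pixels: np.ndarray  # 2-D bool
    junction_pixels: frozenset = field(default_factory=frozenset)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class VesselSegment:
    """One junction-to-junction vessel piece."""

    segment_id: int
    centerline: np.ndarray  # (N, 2) int array of (row, col), ordered
    diameters_px: np.ndarray  # (N,) float
    vessel_class: str = UNKNOWN
    caliber_class: str = MICRO

    @property
    def mean_diameter_px(self) -> float:
        return float(self.diameters_px.mean())

    @property
    def n_centerline_px(self) -> int:
        return len(self.centerline)


def skeletonize(mask: VesselMask) -> Skeleton:
    """Thin the vessel mask to a 1-px medial skeleton and find its junctions.

    Uses topology-preserving medial-axis thinning (8-connected).  An empty
    mask yields an empty skeleton with a warning.
    """
    m = mask.mask
    if not m.any():
        logger.warning("empty vessel mask: empty skeleton")
        return Skeleton(np.zeros_like(m, dtype=bool))
    skel = _skimage_skeletonize(m)
    junctions = detect_junctions(Skeleton(skel))
    return Skeleton(skel, frozenset(junctions))


def detect_junctions(skeleton: Skeleton) -> set[tuple[int, int]]:
    """Skeleton pixels with >= 3 skeleton neighbors in the 8-neighborhood.

    Computed by convolving the skeleton with a 3x3 ones kernel: a skeleton
    pixel whose convolution value (self included) is >= 4 is a junction.
    """
    skel = skeleton.pixels.astype(int)
    conv = ndimage.convolve(skel, _EIGHT, mode="constant", cval=0)
    jmask = (conv >= 4) & skeleton.pixels
    return set(map(tuple, np.argwhere(jmask)))


def _neighbors(px: tuple[int, int], pixel_set: set) -> list[tuple[int, int]]:
    r, c = px
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pixel_set:
                out.append(q)
    return out


def _order_centerline(component: np.ndarray) -> np.ndarray:
    """Order a component's pixels into an endpoint-to-endpoint walk.

    Start at the endpoint (pixel with <= 1 neighbor) with the smallest
    (row, col); a cyclic component has no endpoint and is opened at its
    lexicographically smallest pixel.  The walk is a depth-first traversal
    preferring 4-adjacent steps, with lexicographic tie-breaking, so the
    ordering is fully deterministic.
    """
    pts = [tuple(p) for p in component]
    pset = set(pts)
    endpoints = sorted(p for p in pts if len(_neighbors(p, pset)) <= 1)
    if endpoints:
        start = endpoints[0]
    else:
        start = min(pts)
        logger.warning("cyclic centerline component opened at %s", start)
    order = [start]
    visited = {start}
    cur = start
    while True:
        nbrs = [q for q in _neighbors(cur, pset) if q not in visited]
        if not nbrs:
            break
        # prefer 4-adjacent continuation; then lexicographic
        nbrs.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nbrs[0]
        order.append(cur)
        visited.add(cur)
    if len(order) < len(pts):
        # branch stubs can remain on near-junction geometry; append leftovers
        # deterministically so no skeleton pixel is silently lost
        leftovers = sorted(pset - visited)
        logger.debug("centerline walk left %d stub pixels", len(leftovers))
        order.extend(leftovers)
    return np.array(order, dtype=int)


def classify_caliber(mean_diameter_px: float, threshold_px: float = 6.0) -> str:
    """Main vessel iff mean diameter >= threshold (default 6 px), else micro."""
    if mean_diameter_px <= 0:
        raise InvalidSegmentError(f"non-positive diameter {mean_diameter_px}")
    return MAIN if mean_diameter_px >= threshold_px else MICRO


def classify_vessel(labels: AVLabelMap | None, roi_pixels: np.ndarray) -> str:
    """Majority vote of A/V labels over a segment's intravascular pixels.

    Ties and unlabeled segments vote ``unknown`` (excluded from A/V
    subgroups but kept in the all-vessels pool).
    """
    if labels is None or len(roi_pixels) == 0:
        return UNKNOWN
    vals = labels.labels[roi_pixels[:, 0], roi_pixels[:, 1]]
    n_a = int((vals == AVLabelMap.ARTERIOLE).sum())
    n_v = int((vals == AVLabelMap.VENULE).sum())
    if n_a > n_v:
        return ARTERIOLE
    if n_v > n_a:
        return VENULE
    return UNKNOWN


def extract_segments(
    skeleton: Skeleton,
    mask: VesselMask,
    labels: AVLabelMap | None = None,
    config: RunConfig | None = None,
) -> list[VesselSegment]:
    """Split the skeleton at junctions into ordered vessel segments.

    Junction pixels (clusters of adjacent junctions merged) are removed;
    each remaining 8-connected component is one segment.  Segments shorter
    than ``config.min_centerline_px`` are discarded (and counted), so every
    kept segment yields at least ``min_blocks_per_segment`` OD blocks.
    Per-pixel diameter is twice the Euclidean distance-transform value of
    the vessel mask at the centerline pixel.  The vessel class is assigned
    later from IROI pixels (see roi module); here it is seeded by voting
    over the centerline pixels and may be refined.
    """
    config = config or RunConfig()
    remaining = skeleton.pixels.copy()
    for (r, c) in skeleton.junction_pixels:
        remaining[r, c] = False
    lab, n_comp = ndimage.label(remaining, structure=_EIGHT)
    dist = ndimage.distance_transform_edt(mask.mask)
    segments: list[VesselSegment] = []
    n_discarded = 0
    # deterministic segment order: by smallest (row, col) pixel of component
    comps = []
    for cid in range(1, n_comp + 1):
        coords = np.argwhere(lab == cid)
        comps.append((tuple(coords.min(axis=0)), coords))
    comps.sort(key=lambda t: t[0])
    for coords_key, coords in comps:
        if len(coords) < config.min_centerline_px:
            n_discarded += 1
            continue
        centerline = _order_centerline(coords)
        diam = 2.0 * dist[centerline[:, 0], centerline[:, 1]]
        seg = VesselSegment(
            segment_id=len(segments),
            centerline=centerline,
            diameters_px=diam,
        )
        seg.vessel_class = classify_vessel(labels, centerline)
        seg.caliber_class = classify_caliber(
            seg.mean_diameter_px, config.caliber_threshold_px
        )
        segments.append(seg)
    if n_discarded:
        logger.info("discarded %d segments shorter than %d px",
                    n_discarded, config.min_centerline_px)
    return segments
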