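"""Block-wise optical density ratio (ODR) extraction.

Each vessel segment's centerline is cut into consecutive blocks of
``block_length_px`` (default 3) pixels.  For every block an intravascular
ROI (IROI: the vessel pixels nearest that block's centerline) and an
extravascular ROI (EROI: a one-vessel-diameter outward extension of the
IROI minus a guard ring around all vessels) are built, and the optical
density in a channel is

    OD = log10(O_EROI / O_IROI)

with O_* the mean pixel intensity of the ROI (saturated and zero pixels
excluded).  The per-block optical density ratio is

    ODR = OD_red / OD_green

and the global ODR variability is the mean absolute ODR difference over
all adjacent block pairs, never pairing across segment boundaries:

    ODR_v = sum_n |ODR_n - ODR_{n-1}| / n_pairs
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import disk

from . import graph
from .io import RunConfig, VesselMask

logger = logging.getLogger(__name__)

VALID = "ok"
EMPTY_ROI = "empty-roi"
ZERO_MEAN = "zero-mean"
ALL_SATURATED = "all-saturated"
LOW_GREEN_CONTRAST = "low-green-contrast"


@dataclass
class BlockROI:
    """One 3-centerline-pixel analysis block and its pixel sets."""

    segment_id: int
    block_index: int
    centerline_pixels: np.ndarray  # (block_length, 2)
    local_diameter_px: float
    iroi_pixels: np.ndarray | None = None  # (n, 2) int
    eroi_pixels: np.ndarray | None = None
    valid: bool = True
    reason: str = VALID


@dataclass
class ODRProfile:
    """Per-block OD/ODR values along one segment."""

    segment_id: int
    od_red: list[float] = field(default_factory=list)
    od_green: list[float] = field(default_factory=list)
    odr: list[float] = field(default_factory=list)
    valid: list[bool] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)


@dataclass
class SubjectFeatures:
    """The 8 per-subject functional parameters.

    Seven subgroup ODRs (all vessels, arterioles, venules, and their
    main/micro caliber splits) plus the global ODR variability.  Absent
    subgroups carry NaN with a zero valid-block count.
    """

    odr_all: float = math.nan
    odr_a: float = math.nan
    odr_v: float = math.nan
    odr_main_a: float = math.nan
    odr_main_v: float = math.nan
    odr_mic_a: float = math.nan
    odr_mic_v: float = math.nan
    odr_var: float = math.nan
    n_valid_blocks: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "odr_all": self.odr_all,
            "odr_a": self.odr_a,
            "odr_v": self.odr_v,
            "odr_main_a": self.odr_main_a,
            "odr_main_v": self.odr_main_v,
            "odr_mic_a": self.odr_mic_a,
            "odr_mic_v": self.odr_mic_v,
            "odr_var": self.odr_var,
        }


def partition_blocks(segment: graph.VesselSegment, config: RunConfig | None = None
                     ) -> list[BlockROI]:
    """Cut a centerline into consecutive non-overlapping blocks.

    A trailing remainder shorter than ``block_length_px`` is discarded so
    every block carries the same number of centerline pixels.
    """
    config = config or RunConfig()
    L = config.block_length_px
    n = segment.n_centerline_px
    blocks = []
    for k in range(n // L):
        sl = slice(k * L, (k + 1) * L)
        blocks.append(BlockROI(
            segment_id=segment.segment_id,
            block_index=k,
            centerline_pixels=segment.centerline[sl],
            local_diameter_px=float(segment.diameters_px[sl].mean()),
        ))
    n_dropped = n % L
    if n_dropped:
        logger.debug("segment %d: %d trailing centerline px discarded",
                     segment.segment_id, n_dropped)
    return blocks


def assign_mask_pixels(
    blocks: list[BlockROI],
    segment_masks: VesselMask,
) -> None:
    """Fill each block's IROI with the vessel pixels nearest its centerline.

    Every vessel-mask pixel is assigned to the globally nearest block
    centerline pixel (Euclidean; the KD-tree insertion order — segments
    then blocks then along-centerline position — makes tie-breaking
    deterministic and favors lower block indices).  The block IROIs
    therefore partition the vessel pixels.
    """
    if not blocks:
        return
    centers = np.concatenate([b.centerline_pixels for b in blocks])
    owner = np.concatenate([
        np.full(len(b.centerline_pixels), i) for i, b in enumerate(blocks)
    ])
    tree = cKDTree(centers)
    vessel_px = np.argwhere(segment_masks.mask)
    _, idx = tree.query(vessel_px)
    block_of_px = owner[idx]
    order = np.argsort(block_of_px, kind="stable")
    vessel_px = vessel_px[order]
    block_of_px = block_of_px[order]
    bounds = np.searchsorted(block_of_px, np.arange(len(blocks) + 1))
    for i, b in enumerate(blocks):
        b.iroi_pixels = vessel_px[bounds[i]:bounds[i + 1]]
        if len(b.iroi_pixels) == 0:
            b.valid = False
            b.reason = EMPTY_ROI


def build_rois(
    blocks: list[BlockROI],
    mask: VesselMask,
    all_vessels_mask: VesselMask | None = None,
    config: RunConfig | None = None,
) -> list[BlockROI]:
    """Fill IROI and EROI pixel sets for every block.

    EROI = the block IROI dilated by a disk of radius round(local vessel
    diameter) — the "one vessel diameter outward" band — minus the union of
    all vessels dilated by ``guard_ring_px`` (keeps partial-volume edge
    pixels out of the background estimate), clipped to image bounds.
    Blocks whose EROI comes out empty are flagged invalid.
    """
    config = config or RunConfig()
    if all_vessels_mask is None:
        all_vessels_mask = mask
    if any(b.iroi_pixels is None for b in blocks):
        assign_mask_pixels(blocks, mask)
    H, W = mask.shape
    if config.guard_ring_px > 0:
        forbidden = ndimage.binary_dilation(
            all_vessels_mask.mask, structure=disk(config.guard_ring_px))
    else:
        forbidden = all_vessels_mask.mask
    for b in blocks:
        if not b.valid:
            continue
        radius = max(1, round(b.local_diameter_px))
        iroi_img = np.zeros((H, W), dtype=bool)
        iroi_img[b.iroi_pixels[:, 0], b.iroi_pixels[:, 1]] = True
        dil = ndimage.binary_dilation(iroi_img, structure=disk(radius))
        eroi = dil & ~forbidden
        b.eroi_pixels = np.argwhere(eroi)
        if len(b.eroi_pixels) == 0:
            b.valid = False
            b.reason = EMPTY_ROI
            logger.info("segment %d block %d: empty EROI",
                        b.segment_id, b.block_index)
    return blocks


def _roi_mean(pixels: np.ndarray, channel: np.ndarray,
              saturation_level: float, config: RunConfig) -> float | None:
    vals = channel[pixels[:, 0], pixels[:, 1]].astype(float)
    keep = np.ones(len(vals), dtype=bool)
    if config.exclude_saturated:
        keep &= vals < saturation_level
    if config.exclude_zero:
        keep &= vals > 0
    if not keep.any():
        return None
    return float(vals[keep].mean())


def compute_od(
    block: BlockROI,
    channel: np.ndarray,
    config: RunConfig | None = None,
    saturation_level: float = 255,
) -> tuple[float | None, str]:
    """Optical density of one block in one channel: log10(O_EROI / O_IROI).

    O_EROI and O_IROI are arithmetic means of the ROI pixel intensities
    after excluding saturated (= 2**bit_depth - 1) and zero pixels.
    Returns (od, reason); od is None with a reason code when either ROI
    empties after exclusion or either mean is non-positive.
    """
    config = config or RunConfig()
    if block.iroi_pixels is None or block.eroi_pixels is None or not block.valid:
        return None, block.reason if block.reason != VALID else EMPTY_ROI
    if len(block.iroi_pixels) == 0 or len(block.eroi_pixels) == 0:
        return None, EMPTY_ROI
    o_iroi = _roi_mean(block.iroi_pixels, channel, saturation_level, config)
    o_eroi = _roi_mean(block.eroi_pixels, channel, saturation_level, config)
    if o_iroi is None or o_eroi is None:
        return None, ALL_SATURATED
    if o_iroi <= 0 or o_eroi <= 0:
        return None, ZERO_MEAN
    return math.log10(o_eroi / o_iroi), VALID


def compute_odr(od_red: float, od_green: float, config: RunConfig | None = None
                ) -> tuple[float | None, str]:
    """ODR = OD_red / OD_green, guarded against vanishing green contrast."""
    config = config or RunConfig()
    if abs(od_green) < config.od_green_epsilon:
        return None, LOW_GREEN_CONTRAST
    return od_red / od_green, VALID


def profile_segment(
    blocks: list[BlockROI],
    red: np.ndarray,
    green: np.ndarray,
    config: RunConfig | None = None,
    saturation_level: float = 255,
) -> ODRProfile:
    """Compute the OD/ODR profile over one segment's blocks."""
    config = config or RunConfig()
    if not blocks:
        return ODRProfile(segment_id=-1)
    prof = ODRProfile(segment_id=blocks[0].segment_id)
    for b in blocks:
        od_r, reason_r = compute_od(b, red, config, saturation_level)
        od_g, reason_g = compute_od(b, green, config, saturation_level)
        if od_r is None or od_g is None:
            prof.od_red.append(math.nan if od_r is None else od_r)
            prof.od_green.append(math.nan if od_g is None else od_g)
            prof.odr.append(math.nan)
            prof.valid.append(False)
            prof.reasons.append(reason_r if od_r is None else reason_g)
            continue
        odr, reason = compute_odr(od_r, od_g, config)
        prof.od_red.append(od_r)
        prof.od_green.append(od_g)
        prof.odr.append(math.nan if odr is None else odr)
        prof.valid.append(odr is not None)
        prof.reasons.append(reason)
    return prof


_SUBGROUPS = {
    "odr_all": lambda s: True,
    "odr_a": lambda s: s.vessel_class == graph.ARTERIOLE,
    "odr_v": lambda s: s.vessel_class == graph.VENULE,
    "odr_main_a": lambda s: s.vessel_class == graph.ARTERIOLE
    and s.caliber_class == graph.MAIN,
    "odr_main_v": lambda s: s.vessel_class == graph.VENULE
    and s.caliber_class == graph.MAIN,
    "odr_mic_a": lambda s: s.vessel_class == graph.ARTERIOLE
    and s.caliber_class == graph.MICRO,
    "odr_mic_v": lambda s: s.vessel_class == graph.VENULE
    and s.caliber_class == graph.MICRO,
}


def aggregate_subgroups(
    profiles: list[ODRProfile],
    segments: list[graph.VesselSegment],
) -> SubjectFeatures:
    """Per-subgroup mean of valid block ODRs, plus global ODR variability.

    Subgroup means are unweighted over blocks (a long segment contributes
    more blocks), not means of per-segment means.  A subgroup with no valid
    block reports NaN and count 0.
    """
    seg_by_id = {s.segment_id: s for s in segments}
    feats = SubjectFeatures()
    pools: dict[str, list[float]] = {k: [] for k in _SUBGROUPS}
    for prof in profiles:
        seg = seg_by_id.get(prof.segment_id)
        if seg is None:
            continue
        vals = [o for o, v in zip(prof.odr, prof.valid) if v]
        for name, member in _SUBGROUPS.items():
            if member(seg):
                pools[name].extend(vals)
    for name, vals in pools.items():
        feats.n_valid_blocks[name] = len(vals)
        if vals:
            setattr(feats, name, float(np.mean(vals)))
        else:
            logger.info("subgroup %s: no valid blocks", name)
    feats.odr_var = odr_variability(profiles)
    return feats


def odr_variability(profiles: list[ODRProfile]) -> float:
    """Mean |ODR_n - ODR_{n-1}| over all adjacent valid block pairs.

    Pairs never cross segment boundaries; a pair with an invalid member is
    skipped.  All pairs across all segments are pooled with equal weight
    (pair-count weighting).  Returns NaN when no pair exists.
    """
    total = 0.0
    n_pairs = 0
    for prof in profiles:
        for k in range(1, len(prof.odr)):
            if prof.valid[k] and prof.valid[k - 1]:
                total += abs(prof.odr[k] - prof.odr[k - 1])
                n_pairs += 1
    if n_pairs == 0:
        return math.nan
    return total / n_pairs
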