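"""End-to-end per-image feature extraction.

Chains channel separation, skeletonization, segment extraction, block/ROI
construction and ODR aggregation into one call that turns a co-registered
(image, mask, labels) case into the 8 per-subject functional parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph, odr
from .io import AVLabelMap, FundusImage, RunConfig, VesselMask, split_channels

logger = logging.getLogger(__name__)


@dataclass
class ExtractionResult:
    features: odr.SubjectFeatures
    segments: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    blocks: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def block_table(self) -> pd.DataFrame:
        """Per-block table: segment_id, block_index, od_red, od_green, odr, valid, reason."""
        rows = []
        for prof in self.profiles:
            for k in range(len(prof.odr)):
                rows.append({
                    "segment_id": prof.segment_id,
                    "block_index": k,
                    "od_red": prof.od_red[k],
                    "od_green": prof.od_green[k],
                    "odr": prof.odr[k],
                    "valid": prof.valid[k],
                    "reason": prof.reasons[k],
                })
        return pd.DataFrame(
            rows, columns=["segment_id", "block_index", "od_red",
                           "od_green", "odr", "valid", "reason"])

    def segment_table(self) -> pd.DataFrame:
        rows = [{
            "segment_id": s.segment_id,
            "n_centerline_px": s.n_centerline_px,
            "mean_diameter_px": s.mean_diameter_px,
            "vessel_class": s.vessel_class,
            "caliber_class": s.caliber_class,
        } for s in self.segments]
        return pd.DataFrame(
            rows, columns=["segment_id", "n_centerline_px",
                           "mean_diameter_px", "vessel_class", "caliber_class"])


def extract_features(
    image: FundusImage,
    mask: VesselMask,
    labels: AVLabelMap | None = None,
    config: RunConfig | None = None,
) -> ExtractionResult:
    """Run the full extraction pipeline on one case.

    Steps: split red/green planes; skeletonize the mask and cut it at
    junctions into segments; partition each centerline into 3-px blocks;
    assign every vessel pixel to its nearest block (IROI), refine each
    segment's artery/vein class by majority vote over its IROI pixels;
    dilate per-block IROIs into EROIs; compute per-block OD/ODR; aggregate
    subgroup means and global ODR variability.
    """
    config = config or RunConfig()
    red, green = split_channels(image)
    skel = graph.skeletonize(mask)
    segments = graph.extract_segments(skel, mask, labels, config)

    blocks_by_seg: dict[int, list[odr.BlockROI]] = {}
    all_blocks: list[odr.BlockROI] = []
    for seg in segments:
        blocks = odr.partition_blocks(seg, config)
        blocks_by_seg[seg.segment_id] = blocks
        all_blocks.extend(blocks)

    counts = {
        "n_segments": len(segments),
        "n_blocks": len(all_blocks),
        "n_valid_blocks": 0,
        "n_invalid_blocks": 0,
    }
    if not all_blocks:
        logger.warning("no analyzable vessel blocks in this case")
        return ExtractionResult(odr.SubjectFeatures(), segments, [], [], counts)

    # global nearest-centerline assignment: block IROIs partition the mask
    odr.assign_mask_pixels(all_blocks, mask)
    # A/V class from IROI pixels (majority vote over the segment's vessel
    # pixels, more robust than the centerline near crossings)
    for seg in segments:
        iroi = [b.iroi_pixels for b in blocks_by_seg[seg.segment_id]
                if b.iroi_pixels is not None and len(b.iroi_pixels)]
        if iroi:
            seg.vessel_class = graph.classify_vessel(labels, np.concatenate(iroi))
    odr.build_rois(all_blocks, mask, mask, config)

    profiles = []
    for seg in segments:
        prof = odr.profile_segment(
            blocks_by_seg[seg.segment_id], red, green, config,
            saturation_level=image.saturation_level)
        prof.segment_id = seg.segment_id
        profiles.append(prof)
    features = odr.aggregate_subgroups(profiles, segments)
    counts["n_valid_blocks"] = sum(sum(p.valid) for p in profiles)
    counts["n_invalid_blocks"] = counts["n_blocks"] - counts["n_valid_blocks"]
    return ExtractionResult(features, segments, profiles, all_blocks, counts)
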