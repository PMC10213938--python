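"""Raster and table I/O for fundus ODR analysis.

A *case* is a triple of co-registered rasters: the color fundus photograph,
a binary vessel mask, and an artery/vein label map (0 = background,
1 = arteriole, 2 = venule).  The red plane is the oxygen-sensitive channel
and the green plane the oxygen-insensitive channel; channel separation is a
plain plane split with no resampling or normalization.

All rasters share a single coordinate convention: row-major, 0-based, pixel
centers at integer coordinates.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: micrometres per pixel of the reference acquisition geometry
DEFAULT_PIXEL_SIZE_UM = 12.69

#: column order of the per-subject feature table
FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "odr_all",
    "odr_a",
    "odr_v",
    "odr_main_a",
    "odr_main_v",
    "odr_mic_a",
    "odr_mic_v",
    "odr_var",
]

#: the 8 functional parameters, in table order
FEATURE_NAMES = FEATURE_COLUMNS[2:]


class CoRegistrationError(ValueError):
    """Image, mask and labels do not share one pixel grid."""


class LabelValidationError(ValueError):
    """Too many A/V label pixels fall outside the vessel mask."""


class FormatError(ValueError):
    """Raster has an unsupported layout (e.g. not RGB)."""


@dataclass(frozen=True)
class FundusImage:
    """Color fundus photograph with channel-role metadata.

    ``pixels`` is a float64 (H, W, C) array holding the original integer
    intensities; ``bit_depth`` records the encoding (8 or 16) so saturated
    pixels (``2**bit_depth - 1``) can be identified downstream.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    channel_roles: dict = field(
        default_factory=lambda: {"oxygen_sensitive": 0, "oxygen_insensitive": 1}
    )
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] < 3:
            raise FormatError(
                f"expected (H, W, >=3) color raster, got shape {px.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise FormatError("intensities outside the bit-depth range")
        roles = self.channel_roles
        idx = {roles.get("oxygen_sensitive"), roles.get("oxygen_insensitive")}
        if len(idx) != 2 or any(
            i is None or not (0 <= i < px.shape[2]) for i in idx
        ):
            raise FormatError(f"invalid channel roles {roles!r}")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster, co-registered with its FundusImage."""

    mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 2:
            raise FormatError("vessel mask must be a 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class AVLabelMap:
    """Artery/vein label raster: 0 background, 1 arteriole, 2 venule."""

    labels: np.ndarray

    ARTERIOLE = 1
    VENULE = 2

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise FormatError("label map must be a 2-D raster")
        if not np.isin(lab, (0, 1, 2)).all():
            raise FormatError("label values must be in {0, 1, 2}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the extraction pipeline.

    block_length_px
        centerline pixels per OD block (ODs are computed every 3 pixels
        along the centerline).
    caliber_threshold_px
        mean-diameter split between main (>= threshold) and micro vessels.
    guard_ring_px
        dilation of the all-vessel mask subtracted from every EROI, so
        vessel-edge blur does not contaminate the background estimate.
    min_blocks_per_segment
        segments shorter than ``block_length_px * min_blocks_per_segment``
        centerline pixels are discarded, guaranteeing every kept segment
        contributes at least one adjacent-block pair to ODR variability.
    od_green_epsilon
        |OD_green| below this makes the ODR of the block invalid (division
        guard; a vessel with no green contrast indicates mask leakage).
    """

    block_length_px: int = 3
    caliber_threshold_px: float = 6.0
    guard_ring_px: int = 1
    min_blocks_per_segment: int = 2
    od_green_epsilon: float = 1e-3
    exclude_saturated: bool = True
    exclude_zero: bool = True
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self):
        if self.block_length_px < 1:
            raise ValueError("block_length_px must be >= 1")
        if self.caliber_threshold_px <= 0:
            raise ValueError("caliber_threshold_px must be > 0")
        if self.min_blocks_per_segment < 1:
            raise ValueError("min_blocks_per_segment must be >= 1")
        if self.guard_ring_px < 0:
            raise ValueError("guard_ring_px must be >= 0")

    @property
    def min_centerline_px(self) -> int:
        return self.block_length_px * self.min_blocks_per_segment

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a TOML config file; keyword overrides win over file values."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        known.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**known)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})


def _read_raster(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    return np.asarray(arr)


def _infer_bit_depth(arr: np.ndarray) -> int:
    return 16 if arr.dtype.itemsize >= 2 and arr.max() > 255 else 8


def load_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> FundusImage:
    """Read a color fundus photograph (PNG/TIFF; JPEG accepted with a warning)."""
    p = Path(path)
    if p.suffix.lower() in (".jpg", ".jpeg"):
        logger.warning(
            "%s is JPEG: lossy compression perturbs ODR estimates; prefer PNG/TIFF",
            p.name,
        )
    arr = _read_raster(p)
    if arr.ndim == 2:
        raise FormatError(f"{p.name}: expected an RGB image, got single channel")
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return FundusImage(arr[..., :3].astype(float), bit_depth=bit_depth,
                       pixel_size_um=pixel_size_um)


def load_mask(path: str | Path) -> VesselMask:
    """Read a binary vessel mask (single-channel PNG, nonzero = vessel)."""
    arr = _read_raster(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return VesselMask(arr > 0)


def load_labels(path: str | Path) -> AVLabelMap:
    """Read an A/V label raster with values {0, 1, 2}."""
    arr = _read_raster(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return AVLabelMap(arr)


def validate_case(
    image: FundusImage,
    mask: VesselMask,
    labels: AVLabelMap | None,
    max_label_slack: float = 0.005,
) -> tuple[FundusImage, VesselMask, AVLabelMap | None]:
    """Check co-registration and repair small label/mask disagreement.

    Label pixels outside the vessel mask are zeroed when they are fewer than
    ``max_label_slack`` of all labeled pixels (registration slack); beyond
    that the case is rejected as mis-registered.
    """
    if mask.shape != image.shape:
        raise CoRegistrationError(
            f"mask shape {mask.shape} != image shape {image.shape}"
        )
    if labels is None:
        return image, mask, None
    if labels.shape != image.shape:
        raise CoRegistrationError(
            f"labels shape {labels.shape} != image shape {image.shape}"
        )
    outside = (labels.labels > 0) & ~mask.mask
    n_out = int(outside.sum())
    n_lab = int((labels.labels > 0).sum())
    if n_out:
        if n_lab == 0 or n_out / n_lab >= max_label_slack:
            raise LabelValidationError(
                f"{n_out}/{n_lab} label pixels outside the vessel mask"
            )
        fixed = labels.labels.copy()
        fixed[outside] = 0
        logger.warning("zeroed %d label pixels outside the vessel mask", n_out)
        labels = AVLabelMap(fixed)
    return image, mask, labels


def load_case(
    image_path: str | Path,
    mask_path: str | Path,
    labels_path: str | Path | None,
    config: RunConfig | None = None,
) -> tuple[FundusImage, VesselMask, AVLabelMap | None]:
    """Load and validate one co-registered image/mask/labels case."""
    config = config or RunConfig()
    image = load_image(image_path, pixel_size_um=config.pixel_size_um)
    mask = load_mask(mask_path)
    labels = load_labels(labels_path) if labels_path is not None else None
    return validate_case(image, mask, labels)


def split_channels(image: FundusImage) -> tuple[np.ndarray, np.ndarray]:
    """Return (oxygen-sensitive, oxygen-insensitive) planes, values untouched."""
    sens = image.pixels[..., image.channel_roles["oxygen_sensitive"]]
    insens = image.pixels[..., image.channel_roles["oxygen_insensitive"]]
    return sens.copy(), insens.copy()


def save_image(path: str | Path, image: FundusImage) -> None:
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    iio.imwrite(path, np.round(image.pixels).astype(dtype))


def save_mask(path: str | Path, mask: VesselMask) -> None:
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def save_labels(path: str | Path, labels: AVLabelMap) -> None:
    iio.imwrite(path, labels.labels)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-subject feature table (CSV with the standard header)."""
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"feature table missing columns: {sorted(missing)}")
    return df[FEATURE_COLUMNS]


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.reindex(columns=FEATURE_COLUMNS).to_csv(path, index=False)
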