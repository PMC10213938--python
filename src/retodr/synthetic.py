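"""Synthetic fundus phantoms and cohort simulation.

Phantoms are rasterized vessel tubes of known width, artery/vein identity
and per-channel transmittance over a textured background.  Inside a vessel
the intensity in channel c is ``background_c * transmittance_c``, so the
true optical density is ``OD_c = -log10 t_c`` and the analytic ODR of the
vessel is ``log(t_red) / log(t_green)`` (any log base) — an exact ground
truth for every pipeline stage.  Cohorts are simulated directly at the
feature level as group-specific multivariate Gaussians with exchangeable
inter-parameter correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FEATURE_NAMES, AVLabelMap, FundusImage, VesselMask

ARTERIOLE = "arteriole"
VENULE = "venule"

#: reference per-group marginals of the 8 functional parameters
#: (means and SDs of the healthy-control and diabetic groups)
NORMAL_MEANS = {
    "odr_all": 0.711, "odr_a": 0.713, "odr_v": 0.709,
    "odr_main_a": 0.728, "odr_main_v": 0.717,
    "odr_mic_a": 0.634, "odr_mic_v": 0.599, "odr_var": 0.273,
}
NORMAL_SDS = {
    "odr_all": 0.060, "odr_a": 0.057, "odr_v": 0.063,
    "odr_main_a": 0.056, "odr_main_v": 0.058,
    "odr_mic_a": 0.068, "odr_mic_v": 0.082, "odr_var": 0.025,
}
DM_MEANS = {
    "odr_all": 0.754, "odr_a": 0.755, "odr_v": 0.754,
    "odr_main_a": 0.773, "odr_main_v": 0.761,
    "odr_mic_a": 0.672, "odr_mic_v": 0.627, "odr_var": 0.236,
}
DM_SDS = {
    "odr_all": 0.082, "odr_a": 0.083, "odr_v": 0.082,
    "odr_main_a": 0.083, "odr_main_v": 0.082,
    "odr_mic_a": 0.096, "odr_mic_v": 0.117, "odr_var": 0.059,
}

#: typical fundus background (8-bit): red plane bright, green mid, blue low
DEFAULT_BACKGROUND = (180.0, 100.0, 30.0)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class VesselSpec:
    """One synthetic vessel: a constant-width tube along a polyline."""

    points: tuple  # ((r, c), ...) polyline control points
    width_px: float
    vessel_class: str = ARTERIOLE
    transmittance_red: float = 0.5
    transmittance_green: float = 0.35

    def __post_init__(self):
        if not (0 < self.transmittance_red < 1
                and 0 < self.transmittance_green < 1):
            raise SpecError("transmittances must lie in (0, 1)")
        if self.width_px < 2:
            raise SpecError("width_px must be >= 2")
        if self.vessel_class not in (ARTERIOLE, VENULE):
            raise SpecError(f"unknown vessel class {self.vessel_class!r}")

    @property
    def analytic_odr(self) -> float:
        """True ODR of the tube: log(t_red)/log(t_green), any log base."""
        return math.log(self.transmittance_red) / math.log(self.transmittance_green)


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: geometry plus photometry."""

    shape: tuple = (192, 192)
    background: tuple = DEFAULT_BACKGROUND
    texture_amplitude: float = 0.0
    noise_sd: float = 0.0
    vessels: tuple = ()
    bit_depth: int = 8
    central_reflex: bool = False
    seed: int = 0

    def __post_init__(self):
        maxval = 2**self.bit_depth - 1
        if not all(0 <= b <= maxval for b in self.background):
            raise SpecError("background intensities outside bit-depth range")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise SpecError("noise/texture amplitudes must be >= 0")


@dataclass(frozen=True)
class CohortSimSpec:
    """Feature-level cohort simulator specification.

    Two groups of ``n_per_group`` subjects each; the 8 functional
    parameters are drawn from group-specific multivariate Gaussians with
    the given marginals and a single exchangeable correlation ``rho``.
    """

    n_per_group: int = 50
    normal_means: dict = field(default_factory=lambda: dict(NORMAL_MEANS))
    normal_sds: dict = field(default_factory=lambda: dict(NORMAL_SDS))
    dm_means: dict = field(default_factory=lambda: dict(DM_MEANS))
    dm_sds: dict = field(default_factory=lambda: dict(DM_SDS))
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise SpecError("rho must lie in [0, 1)")
        for sds in (self.normal_sds, self.dm_sds):
            if any(s <= 0 for s in sds.values()):
                raise SpecError("SDs must be positive")


def _polyline_distance(shape: tuple, points: np.ndarray) -> np.ndarray:
    """Distance from every pixel center to a polyline (vectorized)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    P = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    best = np.full(len(P), np.inf)
    pts = np.asarray(points, float)
    if len(pts) == 1:
        return np.linalg.norm(P - pts[0], axis=1).reshape(H, W)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(P - a, axis=1)
        else:
            t = np.clip((P - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(P - proj, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(H, W)


def _smooth_field(shape: tuple, rng: np.random.Generator, sigma: float = 12.0
                  ) -> np.ndarray:
    """Zero-mean, unit-RMS smooth random field (low-frequency texture)."""
    raw = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(raw, sigma)
    f -= f.mean()
    rms = f.std()
    return f / rms if rms > 0 else f


def render_phantom(spec: PhantomSpec
                   ) -> tuple[FundusImage, VesselMask, AVLabelMap, pd.DataFrame]:
    """Rasterize a phantom into (image, mask, labels, ground-truth table).

    Vessels are constant-width tubes: a pixel belongs to a vessel when its
    center lies within width/2 of the polyline.  Inside a vessel the
    channel intensity is background * transmittance; later vessels
    overwrite earlier ones at overlaps (overlaps are flagged in the
    ground-truth table).  Smooth multiplicative-free texture and additive
    Gaussian noise are applied afterwards and clipped to the bit range.
    """
    H, W = spec.shape
    maxval = 2**spec.bit_depth - 1
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((H, W, 3), float)
    for ch, bg in enumerate(spec.background):
        img[..., ch] = bg
    mask = np.zeros((H, W), bool)
    labels = np.zeros((H, W), np.uint8)
    truth_rows = []
    vessel_masks = []
    for i, v in enumerate(spec.vessels):
        d = _polyline_distance((H, W), np.asarray(v.points))
        vm = d <= v.width_px / 2.0
        trans = {0: v.transmittance_red, 1: v.transmittance_green,
                 2: v.transmittance_green}
        inside = vm.copy()
        for ch in range(3):
            img[..., ch][inside] = spec.background[ch] * trans[ch]
        if spec.central_reflex:
            core = d <= v.width_px / 6.0
            for ch in range(3):
                img[..., ch][core] = spec.background[ch] * min(
                    1.0, trans[ch] * 1.6)
        overlap = bool((vm & mask).any())
        mask |= vm
        labels[vm] = 1 if v.vessel_class == ARTERIOLE else 2
        vessel_masks.append(vm)
        truth_rows.append({
            "vessel_index": i,
            "width_px": v.width_px,
            "vessel_class": v.vessel_class,
            "transmittance_red": v.transmittance_red,
            "transmittance_green": v.transmittance_green,
            "analytic_odr": v.analytic_odr,
            "overlaps_previous": overlap,
        })
    if spec.texture_amplitude > 0:
        tex = _smooth_field((H, W), rng)
        img += spec.texture_amplitude * tex[..., None]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, maxval)
    truth = pd.DataFrame(truth_rows, columns=[
        "vessel_index", "width_px", "vessel_class", "transmittance_red",
        "transmittance_green", "analytic_odr", "overlaps_previous"])
    return (FundusImage(img, bit_depth=spec.bit_depth),
            VesselMask(mask), AVLabelMap(labels), truth)


def straight_vessel_spec(
    width_px: float = 8.0,
    t_red: float = 0.5,
    t_green: float = 0.25,
    vessel_class: str = ARTERIOLE,
    shape: tuple = (96, 96),
    **phantom_kwargs,
) -> PhantomSpec:
    """A single horizontal straight vessel through the image center."""
    H, W = shape
    r = H // 2
    v = VesselSpec(points=((r, 4), (r, W - 5)), width_px=width_px,
                   vessel_class=vessel_class,
                   transmittance_red=t_red, transmittance_green=t_green)
    return PhantomSpec(shape=shape, vessels=(v,), **phantom_kwargs)


def _covariance(sds: np.ndarray, rho: float) -> np.ndarray:
    corr = np.full((len(sds), len(sds)), rho)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    # exchangeable corr with rho in [0,1) is positive definite by construction
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise SpecError("covariance not positive definite")
    return cov


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a per-subject feature table for two groups.

    Returns a DataFrame with ``subject_id``, ``group`` in {normal, dm} and
    the 8 functional parameters, reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, means, sds in (("normal", spec.normal_means, spec.normal_sds),
                              ("dm", spec.dm_means, spec.dm_sds)):
        mu = np.array([means[k] for k in FEATURE_NAMES])
        sd = np.array([sds[k] for k in FEATURE_NAMES])
        cov = _covariance(sd, spec.rho)
        draws = rng.multivariate_normal(mu, cov, size=spec.n_per_group,
                                        method="cholesky")
        df = pd.DataFrame(draws, columns=FEATURE_NAMES)
        df.insert(0, "group", group)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])
    return table
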