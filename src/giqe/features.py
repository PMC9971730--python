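"""Five HVS-inspired full-reference features for motion-blurred endoscopy.

Each feature compares a distorted image against its pristine reference
through maps the human visual system is believed to be sensitive to:

* ``F_LSF`` — low-level similarity: per-pixel product of phase-congruency
  similarity and gradient-magnitude similarity, pooled with phase-congruency
  weighting (the most informative pixels count most).
* ``F_VSF`` — visual-saliency similarity fused with gradient and
  chrominance similarity (opponent color channels).
* ``F_LGF`` — mean stabilized similarity between log-Gabor subband
  amplitude maps of the two images.
* ``F_MIF`` — information-fidelity ratio: how much of the reference's
  local information (scalar Gaussian-scale-mixture model, visual noise
  variance ``eps_m^2``) survives in the distorted image.
* ``F_NSF`` — structural contrast similarity between co-located blocks,
  built from the Scharr gradient at each block's central pixel.

All five are 1 for an identical pair and fall toward 0 as blur increases.
Stabilization constants follow the convention of the similarity-index
literature, scaled to the [0, 255] intensity range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .blur import _pixels
from .loggabor import LogGaborBank, bank_responses, phase_congruency
from .saliency import saliency_map

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "ImageMaps",
    "FEATURE_NAMES",
    "scharr_gradient_map",
    "phase_congruency_map",
    "compute_maps",
    "lsf_feature",
    "vsf_feature",
    "lgf_feature",
    "mif_feature",
    "nsf_feature",
    "extract_features",
    "features_from_maps",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("lsf", "vsf", "lgf", "mif", "nsf")

# Scharr derivative pair, /16 normalization (similarity-index convention).
_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
_SCHARR_Y = _SCHARR_X.T

# Opponent chrominance channels (RGB -> M, N of the LMN color space).
_CHROMA_M = np.array([0.30, 0.04, -0.35])
_CHROMA_N = np.array([0.34, -0.60, 0.17])
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FeatureConfig:
    """Constants and filter-bank settings for the five features.

    ``a1``/``a2``/``a3`` stabilize the gradient, saliency/chroma and
    contrast similarities; they assume pixel intensities on [0, 255].
    ``a_pc`` stabilizes the phase-congruency similarity (PC maps live in
    [0, 1]).  ``alpha``/``beta`` weight the similarity terms.  ``mif_noise_var``
    is the visual-noise variance of the information-fidelity model, and
    ``block_size`` the block edge for the information and structure features.
    """

    a1: float = 0.0026 * 255.0 ** 2
    a2: float = 0.00073 * 255.0 ** 2
    a3: float = (0.03 * 255.0) ** 2
    a_pc: float = 0.85
    alpha: float = 1.0
    beta: float = 1.0
    pc_scales: int = 4
    pc_orientations: int = 4
    lgf_bank: LogGaborBank = field(default_factory=LogGaborBank)
    mif_noise_var: float = 0.1
    block_size: int = 4

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a_pc", "alpha", "beta", "mif_noise_var"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.pc_scales < 1 or self.pc_orientations < 1:
            raise ValueError("phase-congruency bank needs >= 1 scale and orientation")

    @property
    def pc_bank(self) -> LogGaborBank:
        return LogGaborBank.octave(self.pc_scales, self.pc_orientations)


@dataclass(frozen=True)
class FeatureVector:
    """The five scalar features for one (reference, distorted) pair."""

    f_lsf: float
    f_vsf: float
    f_lgf: float
    f_mif: float
    f_nsf: float

    def to_array(self) -> np.ndarray:
        return np.array([self.f_lsf, self.f_vsf, self.f_lgf, self.f_mif, self.f_nsf])

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        return cls(*(float(v) for v in np.asarray(arr, float)))


def _luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img @ _LUMA
    return img


def _check_pair(ref: np.ndarray, dist: np.ndarray) -> None:
    if ref.shape != dist.shape:
        raise ValueError(f"shape mismatch: reference {ref.shape} vs distorted {dist.shape}")
    if min(ref.shape[:2]) < 8:
        raise ValueError("images must be at least 8 pixels on each side")


def scharr_gradient_map(image) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) with the 3x3 Scharr pair."""
    img = _luminance(_pixels(image))
    gx = ndimage.correlate(img, _SCHARR_X, mode="nearest")
    gy = ndimage.correlate(img, _SCHARR_Y, mode="nearest")
    return np.hypot(gx, gy)


def phase_congruency_map(image, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Phase-congruency map of the luminance image, values in [0, 1]."""
    cfg = cfg or FeatureConfig()
    return phase_congruency(_luminance(_pixels(image)), cfg.pc_bank)


def _similarity(a: np.ndarray, b: np.ndarray, c: float) -> np.ndarray:
    """Stabilized similarity (2ab + c) / (a^2 + b^2 + c), in (0, 1]."""
    return (2.0 * a * b + c) / (a * a + b * b + c)


# ---------------------------------------------------------------------------
# Per-image map cache: every pair feature is a function of per-image maps,
# so references shared by many distorted versions are analyzed once.
# ---------------------------------------------------------------------------

@dataclass
class ImageMaps:
    """Per-image intermediate maps sufficient to compute all five features."""

    lum: np.ndarray
    grad: np.ndarray
    pc: np.ndarray
    vs: np.ndarray
    chroma_m: np.ndarray | None
    chroma_n: np.ndarray | None
    lgf_amps: np.ndarray          # (n_subbands, H, W)
    mif_info: float
    nsf_contrast: np.ndarray      # per-block central-pixel gradient


def _local_variance(img: np.ndarray, size: int = 3) -> np.ndarray:
    mean = ndimage.uniform_filter(img, size=size, mode="nearest")
    sq = ndimage.uniform_filter(img * img, size=size, mode="nearest")
    return np.clip(sq - mean * mean, 0.0, None)


def _block_reduce_mean(arr: np.ndarray, b: int) -> np.ndarray:
    h, w = arr.shape
    hb, wb = h // b, w // b
    trimmed = arr[: hb * b, : wb * b]
    return trimmed.reshape(hb, b, wb, b).mean(axis=(1, 3))


def _information(lum: np.ndarray, cfg: FeatureConfig) -> float:
    """Local information content under a scalar Gaussian-scale-mixture model.

    The 3x3 local variance, averaged within blocks, plays the role of the
    per-block signal variance x_i^2 * sigma_U^2; the information in bits is
    (1/2) sum_i log2(1 + s_i^2 / eps_m^2).
    """
    s2 = _block_reduce_mean(_local_variance(lum), cfg.block_size)
    return float(0.5 * np.sum(np.log2(1.0 + s2 / cfg.mif_noise_var)))


def _block_contrast(grad: np.ndarray, b: int) -> np.ndarray:
    """Per-block contrast: gradient magnitude at the block's central pixel."""
    h, w = grad.shape
    hb, wb = h // b, w // b
    return grad[b // 2 : hb * b : b, b // 2 : wb * b : b]


def compute_maps(image, cfg: FeatureConfig | None = None) -> ImageMaps:
    """Compute every per-image map needed by the five features."""
    cfg = cfg or FeatureConfig()
    img = _pixels(image)
    if min(img.shape[:2]) < 8:
        raise ValueError("images must be at least 8 pixels on each side")
    lum = _luminance(img)
    grad = scharr_gradient_map(lum)
    pc = phase_congruency(lum, cfg.pc_bank)
    vs = saliency_map(img)
    if img.ndim == 3:
        cm = img @ _CHROMA_M
        cn = img @ _CHROMA_N
    else:
        cm = cn = None
    resp = bank_responses(lum, cfg.lgf_bank)
    amps = np.abs(resp).reshape(-1, *lum.shape)
    return ImageMaps(
        lum=lum,
        grad=grad,
        pc=pc,
        vs=vs,
        chroma_m=cm,
        chroma_n=cn,
        lgf_amps=amps,
        mif_info=_information(lum, cfg),
        nsf_contrast=_block_contrast(grad, cfg.block_size),
    )


# ---------------------------------------------------------------------------
# The five features
# ---------------------------------------------------------------------------

def _lsf_from_maps(r: ImageMaps, d: ImageMaps, cfg: FeatureConfig) -> float:
    s_pc = _similarity(r.pc, d.pc, cfg.a_pc)
    s_gm = _similarity(r.grad, d.grad, cfg.a1)
    f_l = s_pc ** cfg.alpha * s_gm ** cfg.beta
    weight = np.maximum(r.pc, d.pc)
    wsum = weight.sum()
    if wsum <= 0:
        return float(f_l.mean())
    return float((f_l * weight).sum() / wsum)


def _vsf_from_maps(r: ImageMaps, d: ImageMaps, cfg: FeatureConfig) -> float:
    # Saliency maps are normalized to [0,1]; rescale so a2 is commensurate.
    f_vs = float(_similarity(255.0 * r.vs, 255.0 * d.vs, cfg.a2).mean())
    f_gm = float(_similarity(r.grad, d.grad, cfg.a1).mean())
    if r.chroma_m is None or d.chroma_m is None:
        f_c = 1.0  # grayscale pair: chrominance carries no information
    else:
        f_c = float(_similarity(r.chroma_m, d.chroma_m, cfg.a2).mean()) * float(
            _similarity(r.chroma_n, d.chroma_n, cfg.a2).mean()
        )
    return f_vs * f_gm ** cfg.alpha * f_c ** cfg.beta


def _lgf_from_maps(r: ImageMaps, d: ImageMaps, cfg: FeatureConfig) -> float:
    sims = _similarity(r.lgf_amps, d.lgf_amps, cfg.a1)
    return float(sims.mean(axis=(1, 2)).mean())


def _mif_from_maps(r: ImageMaps, d: ImageMaps, cfg: FeatureConfig) -> float:
    if r.mif_info <= 1e-12:
        logger.warning(
            "reference image carries no local information; "
            "information-fidelity ratio defaults to 1"
        )
        return 1.0
    return float(np.clip(d.mif_info / r.mif_info, 1e-12, 1.0))


def _nsf_from_maps(r: ImageMaps, d: ImageMaps, cfg: FeatureConfig) -> float:
    fr, fd = r.nsf_contrast, d.nsf_contrast
    m = np.maximum(fr, fd)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(m > 0, np.abs(fr - fd) / np.where(m > 0, m, 1.0), 0.0)
        k = np.where(m > 0, cfg.a3 / np.where(m > 0, m, 1.0) ** 2, np.inf)
    u = 1.0 - rr
    vals = np.where(np.isinf(k), 1.0, (2.0 * u + k) / (1.0 + u * u + k))
    return float(vals.mean())


def lsf_feature(ref, dist, cfg: FeatureConfig | None = None) -> float:
    """Low-level similarity: PC- and gradient-similarity, PC-weighted pooling."""
    cfg = cfg or FeatureConfig()
    _check_pair(_pixels(ref), _pixels(dist))
    return _lsf_from_maps(compute_maps(ref, cfg), compute_maps(dist, cfg), cfg)


def vsf_feature(ref, dist, cfg: FeatureConfig | None = None) -> float:
    """Visual-saliency feature: saliency, gradient and chrominance similarity."""
    cfg = cfg or FeatureConfig()
    _check_pair(_pixels(ref), _pixels(dist))
    return _vsf_from_maps(compute_maps(ref, cfg), compute_maps(dist, cfg), cfg)


def lgf_feature(ref, dist, cfg: FeatureConfig | None = None) -> float:
    """Mean stabilized similarity between log-Gabor subband amplitudes."""
    cfg = cfg or FeatureConfig()
    _check_pair(_pixels(ref), _pixels(dist))
    return _lgf_from_maps(compute_maps(ref, cfg), compute_maps(dist, cfg), cfg)


def mif_feature(ref, dist, cfg: FeatureConfig | None = None) -> float:
    """Information-fidelity ratio info(dist)/info(ref), clipped to (0, 1]."""
    cfg = cfg or FeatureConfig()
    _check_pair(_pixels(ref), _pixels(dist))
    return _mif_from_maps(compute_maps(ref, cfg), compute_maps(dist, cfg), cfg)


def nsf_feature(ref, dist, cfg: FeatureConfig | None = None) -> float:
    """Block-wise structural contrast similarity, mean-pooled."""
    cfg = cfg or FeatureConfig()
    r, d = _pixels(ref), _pixels(dist)
    _check_pair(r, d)
    if min(r.shape[:2]) < cfg.block_size:
        raise ValueError("image smaller than one block")
    return _nsf_from_maps(compute_maps(ref, cfg), compute_maps(dist, cfg), cfg)


def features_from_maps(
    ref_maps: ImageMaps, dist_maps: ImageMaps, cfg: FeatureConfig | None = None
) -> FeatureVector:
    """Assemble the feature vector from precomputed per-image maps."""
    cfg = cfg or FeatureConfig()
    return FeatureVector(
        f_lsf=_lsf_from_maps(ref_maps, dist_maps, cfg),
        f_vsf=_vsf_from_maps(ref_maps, dist_maps, cfg),
        f_lgf=_lgf_from_maps(ref_maps, dist_maps, cfg),
        f_mif=_mif_from_maps(ref_maps, dist_maps, cfg),
        f_nsf=_nsf_from_maps(ref_maps, dist_maps, cfg),
    )


def extract_features(ref, dist, cfg: FeatureConfig | None = None) -> FeatureVector:
    """All five features for one (reference, distorted) pair."""
    cfg = cfg or FeatureConfig()
    r, d = _pixels(ref), _pixels(dist)
    _check_pair(r, d)
    return features_from_maps(compute_maps(r, cfg), compute_maps(d, cfg), cfg)
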