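"""Synthetic gastroscope-like benchmark: sources, raters, screening, MOS.

The real subjective study behind this metric is not publicly deposited, so
this module emulates its structure end to end: 70 endoscopy-like source
images, a 5-length x 3-angle motion-blur grid (1,050 distorted images), a
latent true-quality curve anchored at the clinically reported
usable/unusable boundary (blur length 15 px maps to the scale midpoint), a
15-rater panel with per-rater bias, noise and occasional lapses, box-plot
outlier screening, and mean-opinion-score (MOS) computation.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .blur import BlurSpec, RasterImage, apply_motion_blur, make_motion_psf, _write_png

__all__ = [
    "SceneConfig",
    "RaterModel",
    "RaterScore",
    "MOSRecord",
    "default_panel",
    "generate_synthetic_source",
    "true_quality",
    "simulate_raters",
    "screen_outliers",
    "compute_mos",
    "build_synthetic_benchmark",
]

DEFAULT_LENGTHS = (5, 10, 15, 20, 25)
DEFAULT_ANGLES = (30.0, 60.0, 90.0)
N_RATERS = 15


@dataclass(frozen=True)
class SceneConfig:
    """Generator parameters for one synthetic endoscopy-like source image.

    The native study resolution is 1075x935; the default is scaled down to
    256x224 so full-grid experiments run at desk scale.
    """

    width: int = 256
    height: int = 224
    texture_scales: int = 4
    vessel_density: float = 12.0   # expected vessel filaments per image
    hue_base: tuple[float, float, float] = (0.78, 0.38, 0.30)  # reddish mucosa
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height) < 64:
            raise ValueError("scene dimensions must be >= 64 for feature validity")


@dataclass(frozen=True)
class RaterModel:
    """One panel member: additive bias, Gaussian noise, and a lapse rate
    (probability of an inattentive, uniformly random score)."""

    bias: float = 0.0
    noise_sd: float = 0.5
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")


@dataclass(frozen=True)
class RaterScore:
    image_id: str
    rater_id: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"score must be in 1..5, got {self.score}")


@dataclass(frozen=True)
class MOSRecord:
    image_id: str
    mos: float
    n_raters_used: int


def default_panel(n_raters: int = N_RATERS, seed: int = 42) -> list[RaterModel]:
    """The frozen default panel: biases ~ N(0, 0.2), noise 0.5, lapse 2%."""
    rng = np.random.default_rng(seed)
    return [
        RaterModel(bias=float(b), noise_sd=0.5, lapse_rate=0.02)
        for b in rng.normal(0.0, 0.2, size=n_raters)
    ]


def _power_law_field(rng, shape, amp_exponent: float) -> np.ndarray:
    """Random field with amplitude spectrum ~ f^-amp_exponent, unit sd."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fx, fy)
    f[0, 0] = 1.0
    amp = f ** (-amp_exponent)
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=shape)
    field = np.fft.ifft2(amp * np.exp(1j * phase)).real
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_synthetic_source(cfg: SceneConfig) -> RasterImage:
    """One synthetic mucosa-like RGB source image.

    Composition: a smooth low-frequency shading field plus mid-frequency
    texture (1/f amplitude spectrum, natural-image-like), dark-red vascular
    filaments traced as random smooth walks, vignetting, and a reddish hue.
    Deterministic given ``cfg`` (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width

    base = _power_law_field(rng, (h, w), 1.4)
    texture = sum(
        _power_law_field(rng, (h, w), 1.0) * 0.5 ** s
        for s in range(cfg.texture_scales)
    )
    shading = 0.6 * base + 0.4 * texture / max(1, cfg.texture_scales)
    shading = (shading - shading.mean()) / (shading.std() + 1e-12)

    # Vascular filaments: random smooth walks stamped into a mask.
    vessels = np.zeros((h, w))
    n_vessels = rng.poisson(cfg.vessel_density)
    for _ in range(n_vessels):
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(0.8 * max(h, w))):
            ang += rng.normal(0, 0.25)
            r += math.sin(ang)
            c += math.cos(ang)
            ir, ic = int(r), int(c)
            if 0 <= ir < h and 0 <= ic < w:
                vessels[ir, ic] = 1.0
            else:
                break
    vessels = ndimage.gaussian_filter(vessels, 0.8)
    vessels = vessels / (vessels.max() + 1e-12)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    vignette = 1.0 - 0.35 * (((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2)

    lum = (0.55 + 0.13 * shading) * vignette
    lum = np.clip(lum - 0.30 * vessels, 0.02, 1.0)

    r_ch = np.clip(cfg.hue_base[0] * lum * 1.25 + 0.05 * shading * 0.1, 0, 1)
    g_ch = np.clip(cfg.hue_base[1] * lum + 0.06 * vessels * -0.5 + 0.38 * lum * 0.2, 0, 1)
    b_ch = np.clip(cfg.hue_base[2] * lum * 0.9, 0, 1)
    rgb = np.stack([r_ch, g_ch, b_ch], axis=-1) * 255.0
    return RasterImage(rgb, source_id=f"syn{cfg.seed:04d}")


def true_quality(length_pixels: float, scale_max: float = 5.0) -> float:
    """Latent quality of a blur level on the 1..scale_max opinion scale.

    Smooth, strictly decreasing in blur length, anchored at
    q(0) = scale_max (pristine) and q(15) = scale midpoint — length 15 px is
    the clinically reported boundary between diagnostically usable and
    unusable images.  Shape: q(L) = 1 + (scale_max - 1) * 2**(-(L/15)**1.5).
    """
    if length_pixels < 0:
        raise ValueError("blur length must be non-negative")
    return 1.0 + (scale_max - 1.0) * 2.0 ** (-((length_pixels / 15.0) ** 1.5))


def simulate_raters(
    q_true: float, raters: list[RaterModel], seed: int, image_id: str = "img"
) -> list[RaterScore]:
    """Simulate one panel scoring one image (single-stimulus protocol).

    Each rater reports round(q_true + bias + N(0, noise_sd)) clipped to
    1..5, except with probability ``lapse_rate`` a uniformly random score.
    """
    if not raters:
        raise ValueError("rater panel is empty")
    rng = np.random.default_rng(seed)
    scores = []
    for i, rater in enumerate(raters, start=1):
        if rng.uniform() < rater.lapse_rate:
            s = int(rng.integers(1, 6))
        else:
            raw = q_true + rater.bias + rng.normal(0.0, rater.noise_sd)
            s = int(np.clip(round(raw), 1, 5))
        scores.append(RaterScore(image_id=image_id, rater_id=i, score=s))
    return scores


def screen_outliers(scores: list[RaterScore]) -> list[RaterScore]:
    """Box-plot screening: drop scores outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Panels with fewer than 4 scores are returned unchanged (quartiles are
    not meaningful there).
    """
    if not scores:
        raise ValueError("no scores to screen")
    if len(scores) < 4:
        return list(scores)
    vals = np.array([s.score for s in scores], dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [s for s in scores if lo <= s.score <= hi]


def compute_mos(scores: list[RaterScore]) -> MOSRecord:
    """Mean opinion score: arithmetic mean of the surviving scores."""
    if not scores:
        raise ValueError("cannot compute MOS of an empty score list")
    vals = [s.score for s in scores]
    return MOSRecord(
        image_id=scores[0].image_id,
        mos=float(np.mean(vals)),
        n_raters_used=len(vals),
    )


def build_synthetic_benchmark(
    n_sources: int = 70,
    scene: SceneConfig | None = None,
    panel: list[RaterModel] | None = None,
    lengths=DEFAULT_LENGTHS,
    angles=DEFAULT_ANGLES,
    seed: int = 42,
    out_dir: str | os.PathLike | None = None,
):
    """Build the full synthetic benchmark.

    Returns ``(manifest, raw_scores, sources)``: a manifest DataFrame with
    one row per (source x length x angle) carrying the screened MOS, the raw
    rater-score table, and the list of source ``RasterImage``s.  If
    ``out_dir`` is given, reference and distorted images are written as PNG
    and the manifest paths point at them; otherwise paths are symbolic ids
    and images stay in memory.

    Latent quality depends on blur length only — rotating the blur direction
    does not change diagnostic usability — so all angles of one (source, L)
    share a latent quality but get independent panel scores.
    """
    scene = scene or SceneConfig()
    panel = panel if panel is not None else default_panel(seed=seed)
    lengths, angles = list(lengths), list(angles)
    rng = np.random.default_rng(seed)

    sources = []
    for k in range(n_sources):
        cfg_k = SceneConfig(
            width=scene.width,
            height=scene.height,
            texture_scales=scene.texture_scales,
            vessel_density=scene.vessel_density,
            hue_base=scene.hue_base,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img = generate_synthetic_source(cfg_k)
        img.source_id = f"src{k:03d}"
        sources.append(img)

    do_write = out_dir is not None
    if do_write:
        out_dir = os.fspath(out_dir)
        os.makedirs(os.path.join(out_dir, "reference"), exist_ok=True)
        os.makedirs(os.path.join(out_dir, "distorted"), exist_ok=True)

    kernels = {(L, a): make_motion_psf(BlurSpec(L, a)) for L in lengths for a in angles}
    rows, score_rows = [], []
    for img in sources:
        sid = img.source_id
        if do_write:
            ref_path = os.path.join(out_dir, "reference", f"{sid}.png")
            _write_png(ref_path, img.pixels)
        else:
            ref_path = sid
        for L in lengths:
            q = true_quality(L)
            for a in angles:
                image_id = f"{sid}_L{L:02d}_a{int(round(a)):03d}"
                sub_seed = int(rng.integers(0, 2**31 - 1))
                raw = simulate_raters(q, panel, seed=sub_seed, image_id=image_id)
                kept = screen_outliers(raw)
                rec = compute_mos(kept)
                if do_write:
                    dist_path = os.path.join(out_dir, "distorted", f"{image_id}.png")
                    _write_png(dist_path, apply_motion_blur(img.pixels, kernels[(L, a)]))
                else:
                    dist_path = image_id
                rows.append(
                    {
                        "reference": ref_path,
                        "distorted": dist_path,
                        "length": L,
                        "angle": a,
                        "mos": rec.mos,
                    }
                )
                score_rows.extend(
                    {"image_id": s.image_id, "rater_id": s.rater_id, "score": s.score}
                    for s in raw
                )

    manifest = pd.DataFrame(rows, columns=["reference", "distorted", "length", "angle", "mos"])
    raw_scores = pd.DataFrame(score_rows, columns=["image_id", "rater_id", "score"])
    if do_write:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        raw_scores.to_csv(os.path.join(out_dir, "raw_scores.csv"), index=False)
    return manifest, raw_scores, sources
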