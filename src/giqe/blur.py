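"""Linear motion-blur simulation.

Uniform rectilinear motion of the endoscope probe over the exposure time
smears each scene point along a line segment of length ``L`` pixels at an
angle ``theta``.  The point spread function (PSF) is therefore a normalized
digital line segment: ``L`` taps of weight ``1/L`` at unit spacing along the
motion direction, distributed onto the pixel grid with bilinear
(anti-aliased) weights.  Blurring is linear shift-invariant filtering with
this kernel and replicate boundary padding.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BlurSpec",
    "BlurKernel",
    "RasterImage",
    "make_motion_psf",
    "apply_motion_blur",
    "build_distortion_grid",
]


@dataclass(frozen=True)
class BlurSpec:
    """Motion-blur parameters: extent in pixels and direction in degrees.

    The angle is measured counter-clockwise from the positive x (column)
    axis and is stored modulo 180: a line segment is symmetric under a
    half-turn, so ``theta`` and ``theta + 180`` describe the same blur.
    """

    length_pixels: int
    angle_degrees: float = 0.0

    def __post_init__(self) -> None:
        if int(self.length_pixels) != self.length_pixels or self.length_pixels < 1:
            raise ValueError(
                f"blur length must be an integer >= 1, got {self.length_pixels!r}"
            )
        object.__setattr__(self, "length_pixels", int(self.length_pixels))
        object.__setattr__(self, "angle_degrees", float(self.angle_degrees) % 180.0)


@dataclass(frozen=True)
class BlurKernel:
    """Discrete PSF: non-negative weights summing to one, with its anchor.

    ``anchor`` is the (row, col) index of the kernel's center of motion —
    always the geometric center here (kernels are padded to odd shape).
    """

    weights: np.ndarray
    anchor: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


@dataclass
class RasterImage:
    """An 8-bit-range raster held as float64, with provenance metadata."""

    pixels: np.ndarray
    source_id: str = ""
    blur: BlurSpec | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")


def _pixels(image) -> np.ndarray:
    """Accept either a bare array or a RasterImage."""
    arr = image.pixels if hasattr(image, "pixels") else image
    return np.asarray(arr, dtype=np.float64)


def make_motion_psf(spec: BlurSpec) -> BlurKernel:
    """Build the motion-blur PSF for ``spec``.

    ``L`` taps of weight ``1/L`` are placed at integer offsets
    ``j - (L-1)//2`` (j = 0..L-1) along the unit direction
    ``(cos(theta), sin(theta))`` and splatted bilinearly onto the pixel
    grid, then renormalized to unit sum.  For axis-aligned angles the taps
    land exactly on grid cells, giving L entries of exactly 1/L; oblique
    angles yield an anti-aliased line.  theta = 90 degrees is a vertical
    L-pixel line (the continuous limit of the oblique case).
    """
    if not isinstance(spec, BlurSpec):
        spec = BlurSpec(*spec) if isinstance(spec, tuple) else BlurSpec(spec)
    L = spec.length_pixels
    theta = math.radians(spec.angle_degrees)
    c, s = math.cos(theta), math.sin(theta)
    # Snap to exact axis alignment so 1/L taps stay exact in floating point.
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0

    offsets = np.arange(L, dtype=np.float64) - (L - 1) // 2
    xs = offsets * c          # column displacement
    ys = -offsets * s         # row displacement (rows grow downward)

    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0

    lo_r, hi_r = int(y0.min()), int(y0.max()) + 1
    lo_c, hi_c = int(x0.min()), int(x0.max()) + 1
    # Pad to odd shape centered on the zero-offset cell.
    half_r = max(-lo_r, hi_r)
    half_c = max(-lo_c, hi_c)
    grid = np.zeros((2 * half_r + 1, 2 * half_c + 1), dtype=np.float64)
    ar, ac = half_r, half_c

    w = 1.0 / L
    for r, cc, dy, dx in zip(y0, x0, fy, fx):
        grid[ar + r, ac + cc] += w * (1 - dy) * (1 - dx)
        grid[ar + r, ac + cc + 1] += w * (1 - dy) * dx
        grid[ar + r + 1, ac + cc] += w * dy * (1 - dx)
        grid[ar + r + 1, ac + cc + 1] += w * dy * dx

    # Trim all-zero border rows/cols symmetrically so the anchor stays centered.
    while grid.shape[0] > 1 and not grid[0].any() and not grid[-1].any():
        grid = grid[1:-1]
        ar -= 1
    while grid.shape[1] > 1 and not grid[:, 0].any() and not grid[:, -1].any():
        grid = grid[:, 1:-1]
        ac -= 1

    grid /= grid.sum()
    return BlurKernel(weights=grid, anchor=(ar, ac))


def apply_motion_blur(image, kernel: BlurKernel | BlurSpec) -> np.ndarray:
    """Filter ``image`` with a motion-blur kernel (replicate padding).

    Channels of an RGB image are filtered independently.  The output has
    the same shape and dtype float64 as the input; values stay within the
    input's range because the kernel is a convex combination.
    """
    if isinstance(kernel, BlurSpec):
        kernel = make_motion_psf(kernel)
    arr = _pixels(image)
    kh, kw = kernel.shape
    if kh > arr.shape[0] or kw > arr.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {arr.shape[:2]}"
        )
    if arr.ndim == 2:
        return ndimage.correlate(arr, kernel.weights, mode="nearest")
    out = np.empty_like(arr)
    for ch in range(arr.shape[2]):
        out[..., ch] = ndimage.correlate(arr[..., ch], kernel.weights, mode="nearest")
    return out


def build_distortion_grid(
    sources,
    lengths,
    angles,
    out_dir: str | os.PathLike | None = None,
    write_images: bool = True,
) -> pd.DataFrame:
    """Build the full (source x length x angle) distortion grid.

    Parameters
    ----------
    sources
        List of ``RasterImage`` (or ``(source_id, array)`` pairs).
    lengths, angles
        Blur extents in pixels and directions in degrees.
    out_dir
        If given, reference and distorted images are written there as
        lossless PNG and the manifest paths point into it.
    write_images
        Set False to build the manifest without touching the filesystem
        (paths are then symbolic ``<source>_L<length>_a<angle>`` ids).

    Returns
    -------
    pandas.DataFrame with columns ``reference, distorted, length, angle, mos``
    (one row per source x length x angle; ``mos`` empty).
    """
    lengths = list(lengths)
    angles = list(angles)
    sources = list(sources)
    if not sources or not lengths or not angles:
        raise ValueError("sources, lengths and angles must all be non-empty")

    imgs = []
    for src in sources:
        if isinstance(src, RasterImage):
            imgs.append(src)
        else:
            sid, arr = src
            imgs.append(RasterImage(np.asarray(arr, float), source_id=str(sid)))

    do_write = out_dir is not None and write_images
    if do_write:
        out_dir = os.fspath(out_dir)
        os.makedirs(os.path.join(out_dir, "reference"), exist_ok=True)
        os.makedirs(os.path.join(out_dir, "distorted"), exist_ok=True)

    kernels = {
        (L, a): make_motion_psf(BlurSpec(L, a)) for L in lengths for a in angles
    }
    rows = []
    for img in imgs:
        sid = img.source_id or f"src{imgs.index(img):03d}"
        if do_write:
            ref_path = os.path.join(out_dir, "reference", f"{sid}.png")
            _write_png(ref_path, img.pixels)
        else:
            ref_path = sid
        for L in lengths:
            for a in angles:
                name = f"{sid}_L{L:02d}_a{int(round(a)):03d}"
                if do_write:
                    dist_path = os.path.join(out_dir, "distorted", f"{name}.png")
                    blurred = apply_motion_blur(img.pixels, kernels[(L, a)])
                    _write_png(dist_path, blurred)
                else:
                    dist_path = name
                rows.append(
                    {
                        "reference": ref_path,
                        "distorted": dist_path,
                        "length": L,
                        "angle": a,
                        "mos": np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["reference", "distorted", "length", "angle", "mos"])


def _write_png(path: str, pixels: np.ndarray) -> None:
    import imageio.v3 as iio

    try:
        iio.imwrite(path, np.clip(np.round(pixels), 0, 255).astype(np.uint8))
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed to write image {path!r}: {exc}") from exc
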