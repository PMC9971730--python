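"""Spectral-residual visual saliency.

The spectral-residual model treats the smooth part of an image's log
amplitude spectrum as statistical redundancy; what remains after removing a
local average of the log spectrum — the residual — marks the "novel" part of
the scene.  Reconstructing from the residual amplitude and the original
phase, squaring and smoothing yields a saliency map.  The model is
parameter-light and needs no training, which is why it is used here as the
visual-saliency front end.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["saliency_map"]

_WORK_WIDTH = 64  # spectral residual operates at coarse scale by design


def saliency_map(image: np.ndarray) -> np.ndarray:
    """Spectral-residual saliency, normalized to [0, 1].

    Accepts grayscale or RGB (RGB is reduced to Rec.601 luminance).  A
    constant image has no salient structure and maps to a uniform 0.5.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2:
        raise ValueError("saliency_map expects a 2-D or 3-channel image")

    if np.ptp(img) < 1e-9:
        return np.full(img.shape, 0.5)

    h, w = img.shape
    scale = _WORK_WIDTH / max(h, w)
    small_shape = (max(8, int(round(h * scale))), max(8, int(round(w * scale))))
    small = resize(img, small_shape, order=1, mode="reflect", anti_aliasing=True)

    spectrum = np.fft.fft2(small)
    log_amp = np.log(np.abs(spectrum) + 1e-12)
    phase = np.angle(spectrum)
    residual = log_amp - ndimage.uniform_filter(log_amp, size=3, mode="wrap")
    recon = np.abs(np.fft.ifft2(np.exp(residual + 1j * phase))) ** 2
    recon = ndimage.gaussian_filter(recon, sigma=2.5, mode="reflect")

    sal = resize(recon, img.shape, order=1, mode="reflect", anti_aliasing=False)
    lo, hi = sal.min(), sal.max()
    if hi - lo < 1e-15:
        return np.full(img.shape, 0.5)
    return (sal - lo) / (hi - lo)
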