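"""Log-Gabor filter bank and phase congruency.

A log-Gabor filter is band-pass with a Gaussian profile on the log-frequency
axis (hence exactly zero DC response) and a Gaussian angular profile:

    G(f_r, f_t) = exp(-log(f_r/f_rs)^2 / (2 log(sigma_s/f_rs)^2))
                * exp(-(f_t - mu_0)^2 / (2 sigma_0^2))

with f_rs the center frequency, sigma_s/f_rs the (constant) bandwidth ratio,
mu_0 the orientation and sigma_0 the angular spread.  The angular term is
one-sided (centered at mu_0 only, not mu_0 + pi), so the spatial response is
complex: its real/imaginary parts are the even/odd symmetric pair whose local
amplitude and phase drive phase congruency.

Phase congruency measures how strongly the Fourier components at a pixel
agree in phase — a contrast-invariant edge/line detector:

    PC(i) = sum_o |sum_s F_{s,o}(i)| / (sum_{s,o} |F_{s,o}(i)| + eps)

where F_{s,o}(i) is the complex subband response at scale s, orientation o.
The resultant length |sum_s F_s| equals max over a reference phase of
sum_s |F_s| cos(phi_s - phi_ref), the classical congruency definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LogGaborBank", "log_gabor_transfer", "bank_responses", "phase_congruency"]

_PC_EPS = 1e-4  # guards the 0/0 of featureless (constant) regions


@dataclass(frozen=True)
class LogGaborBank:
    """A scale x orientation grid of log-Gabor filters.

    Defaults: 4 octave-spaced scales starting at wavelength 3 px, 4
    orientations, bandwidth ratio 0.55 (~2 octaves), angular spread 0.52 rad.
    """

    center_freqs: tuple[float, ...] = (1 / 3, 1 / 6, 1 / 12, 1 / 24)
    bandwidth_ratio: float = 0.55
    orientations: tuple[float, ...] = (
        0.0,
        math.pi / 4,
        math.pi / 2,
        3 * math.pi / 4,
    )
    angular_spread: float = 0.52

    def __post_init__(self) -> None:
        for f in self.center_freqs:
            if not 0.0 < f < 0.5:
                raise ValueError(
                    f"center frequency {f} outside (0, 0.5) cycles/pixel (Nyquist)"
                )
        if not 0.0 < self.bandwidth_ratio < 1.0:
            raise ValueError("bandwidth_ratio must lie in (0, 1)")
        for o in self.orientations:
            if not 0.0 <= o < math.pi:
                raise ValueError("orientations must lie in [0, pi)")
        if self.angular_spread <= 0:
            raise ValueError("angular_spread must be positive")

    @classmethod
    def octave(cls, n_scales: int, n_orientations: int, *,
               min_wavelength: float = 3.0, **kw) -> "LogGaborBank":
        freqs = tuple(1.0 / (min_wavelength * 2.0 ** s) for s in range(n_scales))
        orients = tuple(o * math.pi / n_orientations for o in range(n_orientations))
        return cls(center_freqs=freqs, orientations=orients, **kw)


def log_gabor_transfer(
    f_r,
    f_theta,
    f_rs: float,
    bandwidth_ratio: float,
    mu0: float,
    sigma0: float,
):
    """Evaluate the log-Gabor transfer function at (f_r, f_theta).

    Equals 1 exactly at the filter peak (f_r = f_rs, f_theta = mu0) and 0 at
    f_r = 0 (zero DC).  Angular distance is wrapped to (-pi, pi].
    """
    f_r = np.asarray(f_r, dtype=np.float64)
    f_theta = np.asarray(f_theta, dtype=np.float64)
    radial = np.zeros_like(f_r)
    nz = f_r > 0
    denom = 2.0 * math.log(bandwidth_ratio) ** 2
    radial[nz] = np.exp(-np.log(f_r[nz] / f_rs) ** 2 / denom)
    dtheta = np.arctan2(np.sin(f_theta - mu0), np.cos(f_theta - mu0))
    angular = np.exp(-(dtheta ** 2) / (2.0 * sigma0 ** 2))
    return radial * angular


def _freq_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    radius = np.hypot(fx, fy)
    # Orientation measured CCW from the +x (column) axis; rows grow downward.
    angle = np.arctan2(-fy, fx)
    return radius, angle


def bank_responses(image: np.ndarray, bank: LogGaborBank) -> np.ndarray:
    """Complex subband responses, shaped (n_scales, n_orientations, H, W)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("bank_responses expects a 2-D (luminance) image")
    min_wavelength = 1.0 / max(bank.center_freqs)
    if min(img.shape) < min_wavelength:
        raise ValueError(
            f"image {img.shape} smaller than the bank's shortest wavelength "
            f"({min_wavelength:.1f} px)"
        )
    radius, angle = _freq_grid(img.shape)
    spectrum = np.fft.fft2(img)
    out = np.empty(
        (len(bank.center_freqs), len(bank.orientations), *img.shape),
        dtype=np.complex128,
    )
    for si, f_rs in enumerate(bank.center_freqs):
        for oi, mu0 in enumerate(bank.orientations):
            filt = log_gabor_transfer(
                radius, angle, f_rs, bank.bandwidth_ratio, mu0, bank.angular_spread
            )
            out[si, oi] = np.fft.ifft2(spectrum * filt)
    return out


def phase_congruency(image: np.ndarray, bank: LogGaborBank) -> np.ndarray:
    """Phase-congruency map in [0, 1] (per-orientation resultant pooling)."""
    resp = bank_responses(image, bank)
    energy = np.abs(resp.sum(axis=0)).sum(axis=0)      # sum scales, pool orients
    total = np.abs(resp).sum(axis=(0, 1))
    return energy / (total + _PC_EPS)
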