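"""Standard IQA evaluation protocol plus PSNR/SSIM baselines.

Objective scores are first passed through a five-parameter monotone
logistic mapping

    Q(z) = beta1 * (1/2 - 1/(1 + exp(beta2 * (z - beta3)))) + beta4*z + beta5

fitted by nonlinear least squares against the subjective MOS; accuracy
(PLCC) and consistency (RMSE) are then measured on the mapped scores, while
the rank indicators (SROCC, and tie-corrected Kendall tau-b KROCC) are
computed on the raw scores since they are invariant to any monotone
mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skimage.metrics import structural_similarity

from .blur import _pixels

__all__ = [
    "LogisticParams",
    "EvalReport",
    "fit_logistic",
    "map_scores",
    "correlation_report",
    "psnr",
    "ssim",
    "PSNR_CAP",
]

PSNR_CAP = 100.0  # sentinel for identical images (MSE = 0)


@dataclass(frozen=True)
class LogisticParams:
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    converged: bool = True
    residual_norm: float = float("nan")

    def to_array(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta3, self.beta4, self.beta5])


@dataclass(frozen=True)
class EvalReport:
    plcc: float
    srocc: float
    krocc: float
    rmse: float
    n: int
    logistic: LogisticParams

    def to_dict(self) -> dict:
        return {
            "plcc": self.plcc,
            "srocc": self.srocc,
            "krocc": self.krocc,
            "rmse": self.rmse,
            "n": self.n,
            "beta": self.logistic.to_array().tolist(),
        }


def _logistic5(z, b1, b2, b3, b4, b5):
    # exp argument clipped to keep the optimizer out of overflow territory
    e = np.exp(np.clip(b2 * (z - b3), -500.0, 500.0))
    return b1 * (0.5 - 1.0 / (1.0 + e)) + b4 * z + b5


def map_scores(params: LogisticParams, objective) -> np.ndarray:
    """Apply the fitted five-parameter logistic to objective scores."""
    z = np.asarray(objective, dtype=float)
    return _logistic5(z, *params.to_array())


def fit_logistic(objective, mos) -> LogisticParams:
    """Fit the five-parameter logistic mapping by nonlinear least squares.

    Initialization: beta1 = range(mos), beta2 = 4/range(objective) signed by
    the raw correlation, beta3 = median(objective), beta4 small, beta5 =
    mean(mos); five additional jittered restarts (fixed sub-seeds) guard
    against local minima.  Deterministic given the data.
    """
    z = np.asarray(objective, dtype=float)
    y = np.asarray(mos, dtype=float)
    if z.size != y.size:
        raise ValueError("objective and mos must have equal length")
    if z.size < 6:
        raise ValueError("need at least 6 points to fit 5 parameters")
    span = np.ptp(z)
    if span == 0:
        raise ValueError("objective scores are constant; logistic fit undefined")

    corr_sign = 1.0 if np.corrcoef(z, y)[0, 1] >= 0 else -1.0
    beta0 = np.array(
        [np.ptp(y) if np.ptp(y) > 0 else 1.0,
         corr_sign * 4.0 / span,
         float(np.median(z)),
         1e-3,
         float(np.mean(y))]
    )

    def residuals(b):
        return _logistic5(z, *b) - y

    best = None
    rng = np.random.default_rng(12345)
    starts = [beta0] + [
        beta0 * (1.0 + 0.3 * rng.standard_normal(5)) + 0.05 * rng.standard_normal(5)
        for _ in range(5)
    ]
    for b_init in starts:
        try:
            sol = optimize.least_squares(residuals, b_init, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("five-parameter logistic fit failed to converge")
    res_norm = float(np.sqrt(2.0 * best.cost))
    return LogisticParams(*map(float, best.x), converged=bool(best.success),
                          residual_norm=res_norm)


def correlation_report(objective, mos) -> EvalReport:
    """The four IQA indicators between objective scores and MOS.

    PLCC and RMSE are computed after the logistic mapping; SROCC and KROCC
    (tau-b) on the raw scores.
    """
    z = np.asarray(objective, dtype=float)
    y = np.asarray(mos, dtype=float)
    if z.size != y.size or z.size < 3:
        raise ValueError("need equal-length score vectors with at least 3 points")
    if np.ptp(z) == 0 or np.ptp(y) == 0:
        raise ValueError("constant score vector: rank correlations undefined")

    params = fit_logistic(z, y)
    mapped = map_scores(params, z)
    plcc = float(stats.pearsonr(mapped, y)[0])
    srocc = float(stats.spearmanr(z, y)[0])
    krocc = float(stats.kendalltau(z, y)[0])  # tau-b, tie-corrected
    rmse = float(np.sqrt(np.mean((mapped - y) ** 2)))
    return EvalReport(plcc=plcc, srocc=srocc, krocc=krocc, rmse=rmse,
                      n=int(z.size), logistic=params)


def psnr(ref, dist) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 255] range.

    Identical images (MSE = 0) return the documented cap ``PSNR_CAP``.
    """
    r, d = _pixels(ref), _pixels(dist)
    if r.shape != d.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {d.shape}")
    mse = float(np.mean((r - d) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * math.log10(255.0 ** 2 / mse))


def ssim(ref, dist) -> float:
    """Single-scale SSIM with the standard 11x11 Gaussian window (sigma 1.5)."""
    r, d = _pixels(ref), _pixels(dist)
    if r.shape != d.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {d.shape}")
    if min(r.shape[:2]) < 11:
        raise ValueError("SSIM needs images at least 11 pixels on each side")
    if r.ndim == 3:
        luma = np.array([0.299, 0.587, 0.114])
        r, d = r @ luma, d @ luma
    return float(
        structural_similarity(
            r, d, data_range=255.0, gaussian_weights=True, sigma=1.5,
            win_size=11, use_sample_covariance=False,
        )
    )
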