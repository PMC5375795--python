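"""Reconstruction quality metrics: signal-to-error ratio and SSIM.

SER is computed directly on the complex residual; SSIM is computed on
time-frame magnitude images with the standard 11x11 Gaussian window
(sigma = 1.5) and stabilisation constants c1 = (0.01 R)^2, c2 = (0.03 R)^2
where R is the dynamic range, averaged over frames for a series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .operators import DynamicImage

__all__ = ["SsimSpec", "ser", "ssim_frame", "ssim_series"]

#: dB value reported for an exactly zero residual
SER_CAP_DB = 300.0


def _as_array(x: DynamicImage | np.ndarray) -> np.ndarray:
    return x.data if isinstance(x, DynamicImage) else np.asarray(x)


def ser(F_rec: DynamicImage | np.ndarray, F_truth: DynamicImage | np.ndarray) -> float:
    """Signal-to-error ratio in dB:
    ``-10 log10( ||F_rec - F_truth||^2 / ||F_truth||^2 )``.

    Computed over all voxels and frames on the complex values.  A ratio of
    0.01 (1% error energy) gives exactly 20 dB; a zero residual is reported
    as the cap ``SER_CAP_DB``.
    """
    rec, truth = _as_array(F_rec), _as_array(F_truth)
    if rec.shape != truth.shape:
        raise ValueError(f"shape mismatch: {rec.shape} vs {truth.shape}")
    signal = np.linalg.norm(truth) ** 2
    if signal == 0:
        raise ValueError("ground truth has zero energy; SER undefined")
    err = np.linalg.norm(rec - truth) ** 2
    if err == 0:
        return SER_CAP_DB
    return float(min(-10.0 * np.log10(err / signal), SER_CAP_DB))


@dataclass(frozen=True)
class SsimSpec:
    """SSIM parameters.

    ``dynamic_range`` R sets the default stabilisation constants
    c1 = (0.01 R)^2 and c2 = (0.03 R)^2; ``window`` is the (odd) Gaussian
    window size with standard deviation ``sigma``.
    """

    dynamic_range: float = 1.0
    c1: float | None = None
    c2: float | None = None
    window: int = 11
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        for c in (self.c1, self.c2):
            if c is not None and c <= 0:
                raise ValueError("stabilisation constants must be positive")

    @property
    def C1(self) -> float:
        return self.c1 if self.c1 is not None else (0.01 * self.dynamic_range) ** 2

    @property
    def C2(self) -> float:
        return self.c2 if self.c2 is not None else (0.03 * self.dynamic_range) ** 2


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = size // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim_frame(f_rec: np.ndarray, f_truth: np.ndarray, spec: SsimSpec | None = None) -> float:
    """Mean structural similarity between two real (magnitude) frames.

    Local means, variances and covariance are Gaussian-weighted over the
    window; the SSIM map

        ((2 mu_x mu_y + c1)(2 cov_xy + c2)) /
        ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    is averaged over positions whose window lies fully inside the frame.
    Identical frames score exactly 1.0.
    """
    x = np.asarray(f_rec, dtype=float)
    y = np.asarray(f_truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if spec is None:
        spec = SsimSpec(dynamic_range=max(float(y.max()), np.finfo(float).tiny))
    if min(x.shape) < spec.window:
        raise ValueError(f"frame smaller than the {spec.window}x{spec.window} SSIM window")
    w = _gaussian_window(spec.window, spec.sigma)

    mu_x = convolve2d(x, w, mode="valid")
    mu_y = convolve2d(y, w, mode="valid")
    # weighted (population) second moments
    var_x = convolve2d(x * x, w, mode="valid") - mu_x**2
    var_y = convolve2d(y * y, w, mode="valid") - mu_y**2
    cov = convolve2d(x * y, w, mode="valid") - mu_x * mu_y

    c1, c2 = spec.C1, spec.C2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float(np.mean(num / den))


def ssim_series(
    F_rec: DynamicImage | np.ndarray,
    F_truth: DynamicImage | np.ndarray,
    spec: SsimSpec | None = None,
) -> float:
    """Unweighted mean of :func:`ssim_frame` over the magnitude images of all
    frames.  The default dynamic range is the maximum magnitude of the whole
    truth series, shared across frames."""
    rec, truth = np.abs(_as_array(F_rec)), np.abs(_as_array(F_truth))
    if rec.shape != truth.shape:
        raise ValueError(f"shape mismatch: {rec.shape} vs {truth.shape}")
    if spec is None:
        spec = SsimSpec(dynamic_range=max(float(truth.max()), np.finfo(float).tiny))
    return float(np.mean([ssim_frame(rec[:, :, t], truth[:, :, t], spec) for t in range(rec.shape[2])]))
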