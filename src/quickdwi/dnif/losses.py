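"""Training losses: MSE, MAE, and the alpha-weighted MAE/SSIM combination.

The combined loss is ``L = alpha * MAE + (1 - alpha) * (1 - SSIM)`` so
that it decreases as structural similarity increases.  SSIM uses the
standard Gaussian-window formulation (11x11 window, sigma 1.5, K1 = 0.01,
K2 = 0.03, data range 1.0) evaluated over fully interior windows; for
images at least 11 pixels wide this matches the Gaussian-weighted SSIM of
scikit-image exactly.

Every loss returns ``(value, gradient_wrt_pred)`` so the network backward
pass can consume them directly; the SSIM gradient is analytic and is
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "loss_mse",
    "loss_mae",
    "loss_mae_ssim",
    "ssim_value",
    "gaussian_kernel",
    "LOSSES",
]

SSIM_WIN = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def gaussian_kernel(win: int = SSIM_WIN, sigma: float = SSIM_SIGMA) -> np.ndarray:
    """Truncated, normalized 2D Gaussian window (outer product of 1D)."""
    r = (win - 1) // 2
    g = np.exp(-np.arange(-r, r + 1) ** 2 / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def _check_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")


def loss_mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all pixels (and batch, if any)."""
    _check_shapes(pred, target)
    diff = pred - target
    n = diff.size
    return float(np.mean(diff**2)), 2.0 * diff / n


def loss_mae(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error over all pixels (and batch, if any)."""
    _check_shapes(pred, target)
    diff = pred - target
    n = diff.size
    return float(np.mean(np.abs(diff))), np.sign(diff) / n


def _ssim_stats(x: np.ndarray, y: np.ndarray, g: np.ndarray, data_range: float):
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    mu_x = fftconvolve(x, g, mode="valid")
    mu_y = fftconvolve(y, g, mode="valid")
    sxx = fftconvolve(x * x, g, mode="valid") - mu_x**2
    syy = fftconvolve(y * y, g, mode="valid") - mu_y**2
    sxy = fftconvolve(x * y, g, mode="valid") - mu_x * mu_y
    a1 = 2.0 * mu_x * mu_y + c1
    a2 = 2.0 * sxy + c2
    b1 = mu_x**2 + mu_y**2 + c1
    b2 = sxx + syy + c2
    return mu_x, mu_y, a1, a2, b1, b2


def ssim_value(
    pred: np.ndarray, target: np.ndarray, data_range: float = 1.0
) -> float:
    """Mean SSIM of one 2D image pair over interior Gaussian windows."""
    _check_shapes(pred, target)
    if min(pred.shape) < SSIM_WIN:
        raise ValueError(f"image smaller than the {SSIM_WIN}x{SSIM_WIN} SSIM window")
    g = gaussian_kernel()
    *_, a1, a2, b1, b2 = _ssim_stats(pred, target, g, data_range)
    return float(np.mean(a1 * a2 / (b1 * b2)))


def _ssim_and_grad(
    pred: np.ndarray, target: np.ndarray, data_range: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean SSIM of a 2D pair and its analytic gradient w.r.t. ``pred``.

    With per-window statistics mu, sigma^2 and covariance obtained by
    correlation with the Gaussian g, the chain rule gives

        d mean(S) / dx = [ G*(dS/dmu_x) + 2 x G*(dS/dvar_x)
                           - 2 G*(dS/dvar_x * mu_x) + y G*(dS/dcov)
                           - G*(dS/dcov * mu_y) ] / n_windows

    where G* denotes full correlation scattering window-centre terms back
    onto pixels.
    """
    _check_shapes(pred, target)
    g = gaussian_kernel()
    mu_x, mu_y, a1, a2, b1, b2 = _ssim_stats(pred, target, g, data_range)
    d = b1 * b2
    s = a1 * a2 / d
    n_win = s.size

    ds_dmux = 2.0 * mu_y * a2 / d - s * 2.0 * mu_x / b1
    ds_dvarx = -s / b2
    ds_dcov = 2.0 * a1 / d

    def scatter(m: np.ndarray) -> np.ndarray:
        return fftconvolve(m, g, mode="full")  # g symmetric: convolve == correlate

    grad = (
        scatter(ds_dmux)
        + 2.0 * pred * scatter(ds_dvarx)
        - 2.0 * scatter(ds_dvarx * mu_x)
        + target * scatter(ds_dcov)
        - scatter(ds_dcov * mu_y)
    ) / n_win
    return float(np.mean(s)), grad


def loss_mae_ssim(
    pred: np.ndarray, target: np.ndarray, alpha: float = 0.7
) -> tuple[float, np.ndarray]:
    """alpha * MAE + (1 - alpha) * (1 - SSIM), with SSIM averaged per image.

    Accepts a single 2D pair or a batch (leading axis); the SSIM term is
    computed per image and averaged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    _check_shapes(pred, target)
    mae, mae_grad = loss_mae(pred, target)
    if alpha == 1.0:
        return mae, mae_grad

    if pred.ndim == 2:
        pairs = [(pred, target)]
    else:
        flat_p = pred.reshape(-1, *pred.shape[-2:])
        flat_t = target.reshape(-1, *target.shape[-2:])
        pairs = list(zip(flat_p, flat_t))

    ssim_sum = 0.0
    ssim_grad = np.zeros_like(pred).reshape(-1, *pred.shape[-2:])
    for i, (p, t) in enumerate(pairs):
        s, gs = _ssim_and_grad(p, t)
        ssim_sum += s
        ssim_grad[i] = gs
    n_img = len(pairs)
    value = alpha * mae + (1.0 - alpha) * (1.0 - ssim_sum / n_img)
    grad = alpha * mae_grad - (1.0 - alpha) * ssim_grad.reshape(pred.shape) / n_img
    return float(value), grad


LOSSES = {
    "mse": loss_mse,
    "mae": loss_mae,
    "mae_ssim": loss_mae_ssim,
}
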