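"""Differentiable image losses built from autodiff primitives.

The SSIM surrogate follows the canonical formulation: local statistics under
an 11x11 Gaussian window (sigma 1.5), stabilisers c1 = 0.01^2, c2 = 0.03^2 on
data range 1, evaluated on the valid (fully overlapped) region.  Because it
is assembled from primitive ops the gradient comes for free.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor, add, add_const, bce, div, mean, mul, mul_const, sep_filter_valid, sub,
)

_F32 = np.float32


def gaussian_kernel_1d(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return (g / g.sum()).astype(_F32)


def _as_nchw(target: np.ndarray) -> np.ndarray:
    t = np.asarray(target, dtype=_F32)
    if t.ndim == 2:
        return t[None, None]
    if t.ndim == 3:
        return t[:, None]
    return t


def ssim_tensor(pred: Tensor, target: np.ndarray,
                window: int = 11, sigma: float = 1.5,
                c1: float = 0.01**2, c2: float = 0.03**2) -> Tensor:
    """Mean SSIM between a (N,1,H,W) prediction tensor and a target array."""
    k = gaussian_kernel_1d(window, sigma)
    t = Tensor(_as_nchw(target))

    def gfilter(x: Tensor) -> Tensor:
        return sep_filter_valid(x, k)

    mu_x = gfilter(pred)
    mu_y = gfilter(t)
    mu_xx = mul(mu_x, mu_x)
    mu_yy = mul(mu_y, mu_y)
    mu_xy = mul(mu_x, mu_y)
    sig_xx = sub(gfilter(mul(pred, pred)), mu_xx)
    sig_yy = sub(gfilter(mul(t, t)), mu_yy)
    sig_xy = sub(gfilter(mul(pred, t)), mu_xy)

    num = mul(add_const(mul_const(mu_xy, 2.0), c1),
              add_const(mul_const(sig_xy, 2.0), c2))
    den = mul(add_const(add(mu_xx, mu_yy), c1),
              add_const(add(sig_xx, sig_yy), c2))
    return mean(div(num, den))


def combined_loss_tensor(pred: Tensor, target: np.ndarray,
                         w_ce: float = 1.0, w_ssim: float = 1.0) -> Tensor:
    """Training objective: w_ce * BCE + w_ssim * (1 - SSIM)."""
    target = _as_nchw(target)
    if target.shape != pred.data.shape:
        raise ValueError("prediction and target must share shape")
    terms: list[Tensor] = []
    if w_ce > 0:
        terms.append(mul_const(bce(pred, target), w_ce))
    if w_ssim > 0:
        one_minus = add_const(mul_const(ssim_tensor(pred, target), -1.0), 1.0)
        terms.append(mul_const(one_minus, w_ssim))
    out = terms[0]
    for extra in terms[1:]:
        out = add(out, extra)
    return out
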