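"""Reconstruction quality metrics: RMSE and windowed SSIM.

RMSE is the root of the mean squared pixel difference.  SSIM compares
luminance, contrast and structure as a mean over a moving window:

    SSIM = (2 mu_a mu_b + c1)(2 cov_ab + c2)
           / ((mu_a^2 + mu_b^2 + c1)(sigma_a^2 + sigma_b^2 + c2))

with stabilizers c1 = (k1 L)^2, c2 = (k2 L)^2 for data range L = levels - 1.
Uniform (not Gaussian) 7x7 windows by default, 3x3 for images too small to
host a 7x7 window; local statistics use the unbiased covariance normalization
and the window map is cropped to positions fully inside the image before
averaging, matching the standard reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter


def rmse(recon: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square pixel error; symmetric, zero iff images identical."""
    a = np.asarray(recon, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class SsimConfig:
    """SSIM parameters.

    window : odd window side; if None, 7 when the image can host it, else 3.
    k1, k2 : stabilizer constants (standard defaults).
    data_range : L = levels - 1; if None, inferred from the truth image span.
    """

    window: int | None = None
    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None

    def resolve_window(self, n: int) -> int:
        win = self.window
        if win is None:
            win = 7 if n >= 7 else 3
        if win % 2 == 0 or win < 3:
            raise ValueError("SSIM window must be an odd integer >= 3")
        if win > n:
            raise ValueError(f"SSIM window {win} exceeds image size {n}")
        return win


def ssim(recon: np.ndarray, truth: np.ndarray, config: SsimConfig | None = None) -> float:
    """Mean structural similarity over uniform moving windows; in [-1, 1]."""
    a = np.asarray(recon, dtype=float)
    b = np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    cfg = config or SsimConfig()
    win = cfg.resolve_window(min(a.shape))
    L = cfg.data_range
    if L is None:
        span = float(b.max() - b.min())
        L = span if span > 0 else 1.0
    c1 = (cfg.k1 * L) ** 2
    c2 = (cfg.k2 * L) ** 2

    def f(img):
        return uniform_filter(img, size=win)

    np_win = win * win
    cov_norm = np_win / (np_win - 1)  # unbiased local (co)variance
    ua, ub = f(a), f(b)
    uaa, ubb, uab = f(a * a), f(b * b), f(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad or None, pad:-pad or None].mean())
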