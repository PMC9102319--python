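"""Edge-preserving bilateral denoising of depth frames.

Depth sensors add Gaussian noise and outlier spikes to otherwise smooth
surfaces.  A bilateral filter smooths both while keeping object boundaries
sharp, because the range kernel gives (near-)zero weight to neighbours on
the far side of a depth discontinuity.  Holes (depth 0) are not data: they
are excluded from every weighted sum and a hole pixel stays a hole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .io import DepthFrame


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral filter parameters.

    sigma_d
        Spatial standard deviation in pixels.
    sigma_r
        Range standard deviation in depth units.  Must match the unit the
        depth values are expressed in; the default 0.8 assumes depths on a
        comparable scale.
    radius
        Window half-width in pixels; ``None`` chooses ``ceil(3*sigma_d)``
        (at least 1), which captures >99% of the spatial Gaussian mass.
    """

    sigma_d: float = 0.8
    sigma_r: float = 0.8
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ContractError("sigma_d and sigma_r must be positive")
        if self.radius is not None and self.radius < 1:
            raise ContractError("radius must be >= 1")

    @property
    def effective_radius(self) -> int:
        if self.radius is not None:
            return self.radius
        return max(1, math.ceil(3.0 * self.sigma_d))


def bilateral_filter(frame: DepthFrame,
                     params: BilateralParams = BilateralParams()) -> DepthFrame:
    """Apply the bilateral filter to one depth frame.

    Each output pixel is the weight-normalized sum of valid neighbours in
    a ``(2r+1)``-square window, with weights
    ``exp(-|p-q|^2 / 2*sigma_d^2) * exp(-(I(p)-I(q))^2 / 2*sigma_r^2)``.
    Windows are truncated at the image border (no padding).  Zero-depth
    pixels contribute to neither numerator nor denominator, and an invalid
    centre pixel stays 0.
    """
    r = params.effective_radius
    vals = np.asarray(frame.values, dtype=np.float64)
    valid = vals > 0
    h, w = vals.shape
    num = np.zeros_like(vals)
    den = np.zeros_like(vals)
    inv2sd = 1.0 / (2.0 * params.sigma_d ** 2)
    inv2sr = 1.0 / (2.0 * params.sigma_r ** 2)

    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            sw = math.exp(-(dx * dx + dy * dy) * inv2sd)
            # overlapping slices of centre (c) and neighbour (n) pixels
            cy0, cy1 = max(0, -dy), min(h, h - dy)
            cx0, cx1 = max(0, -dx), min(w, w - dx)
            if cy0 >= cy1 or cx0 >= cx1:
                continue
            c = np.s_[cy0:cy1, cx0:cx1]
            n = np.s_[cy0 + dy:cy1 + dy, cx0 + dx:cx1 + dx]
            diff = vals[c] - vals[n]
            wgt = sw * np.exp(-(diff * diff) * inv2sr) * valid[n]
            num[c] += wgt * vals[n]
            den[c] += wgt

    out = np.zeros_like(vals)
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return DepthFrame(out, index=frame.index)
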