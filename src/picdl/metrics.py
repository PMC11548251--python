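"""Image-quality metrics: PSNR, SSIM and Pearson correlation.

The data range used by PSNR and SSIM defaults to the reference image's
dynamic range (max − min) and is recorded in every report, since absolute
dB values are only comparable at a fixed range convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .geometry import Image2D

__all__ = ["MetricsReport", "psnr", "ssim", "cc", "evaluate"]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Image2D) else np.asarray(x, dtype=np.float64)


def _resolve_range(ref: np.ndarray, data_range) -> float:
    if data_range is None or data_range == "auto":
        rng = float(ref.max() - ref.min())
        if rng <= 0:
            raise ValueError("reference image is constant; pass data_range explicitly")
        return rng
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(data_range)


def psnr(x, ref, data_range=None) -> float:
    """Peak signal-to-noise ratio 10·log10(R²/MSE) in dB; inf for identical images."""
    xv, rv = _values(x), _values(ref)
    if xv.shape != rv.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((xv - rv) ** 2))
    if mse == 0.0:
        return float("inf")
    r = _resolve_range(rv, data_range)
    return float(10.0 * np.log10(r * r / mse))


def ssim(x, ref, data_range=None) -> float:
    """Mean local structural similarity (11×11 Gaussian window, σ=1.5, K=.01/.03)."""
    xv, rv = _values(x), _values(ref)
    if xv.shape != rv.shape:
        raise ValueError("shape mismatch")
    if min(xv.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    r = _resolve_range(rv, data_range)
    return float(
        _sk_ssim(
            xv,
            rv,
            data_range=r,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def cc(x, ref) -> float:
    """Pearson correlation over all pixels, in [−1, 1]."""
    xv, rv = _values(x).ravel(), _values(ref).ravel()
    if xv.shape != rv.shape:
        raise ValueError("shape mismatch")
    if np.ptp(xv) == 0 or np.ptp(rv) == 0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.clip(np.corrcoef(xv, rv)[0, 1], -1.0, 1.0))


@dataclass
class MetricsReport:
    """PSNR/SSIM/CC of one image against a reference, plus the range used."""

    psnr_db: float
    ssim: float
    cc: float
    data_range: float

    def to_json(self) -> str:
        d = asdict(self)
        if np.isinf(d["psnr_db"]):
            d["psnr_db"] = "inf"
        return json.dumps(d, indent=2)


def evaluate(x, ref, data_range=None) -> MetricsReport:
    """Full metric panel of ``x`` against reference ``ref``."""
    rv = _values(ref)
    r = _resolve_range(rv, data_range)
    return MetricsReport(
        psnr_db=psnr(x, ref, r), ssim=ssim(x, ref, r), cc=cc(x, ref), data_range=r
    )
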