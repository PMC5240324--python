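"""Reconstruction quality metrics: PSNR, SSIM and relative l2 error."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "rlne", "evaluate"]


@dataclass(frozen=True)
class MetricReport:
    psnr: float
    ssim: float
    rlne: float
    peak: float = 1.0

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr, "ssim": self.ssim,
            "rlne": self.rlne, "peak": self.peak,
        }


def _check_shapes(x: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    return x, ref


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give ``inf``."""
    x, ref = _check_shapes(x, ref)
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(x: np.ndarray, ref: np.ndarray) -> float:
    """Mean structural similarity with the canonical parameters.

    11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, dynamic range 1.
    """
    x, ref = _check_shapes(x, ref)
    if min(x.shape) < 11:
        raise ValueError("images must be at least 11x11 for SSIM")
    return float(
        structural_similarity(
            x, ref,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def rlne(x: np.ndarray, ref: np.ndarray) -> float:
    """Relative l2 norm error ``||x - ref|| / ||ref||``; lower is better."""
    x, ref = _check_shapes(x, ref)
    denom = float(np.linalg.norm(ref))
    if denom == 0.0:
        raise ValueError("reference image is all zeros")
    return float(np.linalg.norm(x - ref) / denom)


def evaluate(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> MetricReport:
    """All three metrics at once."""
    return MetricReport(
        psnr=psnr(x, ref, peak), ssim=ssim(x, ref), rlne=rlne(x, ref),
        peak=peak,
    )
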