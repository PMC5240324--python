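"""Synthetic inputs: two-level toy images, multi-contrast brain-like
phantoms, the blur+downsample degradation operator and Rician noise.

The phantom generator renders one shared label structure (nested,
smoothly-perturbed ellipses) under two different label->intensity maps, so
the two output images share every boundary but differ in regional contrast
— the setting the multi-contrast interpolation engine is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.ndimage import convolve, gaussian_filter

__all__ = [
    "ContrastPair",
    "DegradationSpec",
    "make_toy_pair",
    "make_brain_phantom",
    "gaussian_kernel",
    "degrade",
    "add_rician_noise",
]


@dataclass(frozen=True)
class ContrastPair:
    """Two images rendered from one label map by different intensity maps."""

    labels: np.ndarray
    image_a: np.ndarray
    image_b: np.ndarray
    map_a: np.ndarray
    map_b: np.ndarray


@dataclass(frozen=True)
class DegradationSpec:
    """Blur + x2 downsampling (+ optional Rician noise) parameters."""

    kernel_size: int = 3
    kernel_sigma: float = 0.5
    factor: int = 2
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor != 2:
            raise ValueError("only x2 degradation is supported")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def make_toy_pair(omega_p: float, omega_q: float) -> np.ndarray:
    """9x9 two-level image constant along the main diagonal direction.

    Pixels with ``row - col >= 0`` take ``omega_p``, the rest ``omega_q``.
    On the diagonal lattice this structure yields the weights
    ``[0.5, 0, 0, 0.5]`` regardless of the two levels — rendering the same
    structure with different ``(omega_p, omega_q)`` pairs gives a family of
    contrasts with identical weights.
    """
    if omega_p == omega_q:
        raise ValueError("the two levels must differ")
    for v in (omega_p, omega_q):
        if not 0.0 <= v <= 1.0:
            raise ValueError("levels must lie in [0, 1]")
    rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
    return np.where(rr - cc >= 0, float(omega_p), float(omega_q))


#: Total intensity span allotted to the label maps; each adjacent-label
#: step has magnitude _LEVEL_SPAN / (n_labels - 1) in both contrasts.
_LEVEL_SPAN = 0.8


def _intensity_maps(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two label->intensity maps with equal-magnitude adjacent steps.

    ``map_a`` ascends (T1-like); ``map_b`` walks the same step size with a
    random sign pattern (T2-like, partially inverted).  Equal step
    magnitudes make every boundary equally strong in both contrasts, so
    the two images share one edge mask exactly — only the contrast
    (sign/ordering) differs.
    """
    step = _LEVEL_SPAN / (n - 1)
    map_a = 0.1 + step * np.arange(n)
    while True:
        signs = rng.choice([-1.0, 1.0], n - 1)
        if np.all(signs == 1.0):  # identical to map_a; reroll
            continue
        walk = np.concatenate([[0.0], np.cumsum(signs * step)])
        map_b = walk - walk.min() + 0.1
        return map_a, map_b


def make_brain_phantom(
    seed: int,
    size: Tuple[int, int] = (128, 128),
    n_regions: int = 6,
) -> ContrastPair:
    """Generate a brain-like multi-contrast phantom pair.

    Nested closed curves define ``n_regions`` labels — background, a
    smooth skull-like rim and inner tissue layers whose boundaries carry
    high-curvature convolutions (gyri-like wiggles too fine for a
    low-resolution window to resolve).  ``map_a`` renders the labels with
    ascending intensities (T1-like), ``map_b`` with an equal-step
    random-sign walk (T2-like, partially inverted), so both images share
    one structure and one edge mask but differ in contrast.  A light
    Gaussian smoothing emulates partial-volume softening.  Deterministic
    per seed.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("phantom size must be at least 64x64")
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)

    cy = h / 2 + rng.uniform(-2, 2)
    cx = w / 2 + rng.uniform(-2, 2)
    aspect = rng.uniform(1.05, 1.25)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy = (rr - cy) / aspect
    dx = cc - cx
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # one shared smooth angular perturbation keeps the boundaries nested
    modes = np.arange(2, 6)
    amps = rng.uniform(0.01, 0.05, size=modes.size)
    phases = rng.uniform(0, 2 * np.pi, size=modes.size)
    pert = np.zeros_like(theta)
    for m, a, p in zip(modes, amps, phases):
        pert += a * np.cos(m * theta + p)

    base = min(h, w) / 2.0
    fracs = np.linspace(0.88, 0.22, n_regions - 1)
    labels = np.zeros((h, w), dtype=np.int64)
    for i, frac in enumerate(fracs):
        wiggle = 0.0
        if i > 0:  # inner boundaries get fine-scale convolutions
            hi_modes = rng.integers(12, 30, size=2)
            hi_amps = rng.uniform(0.008, 0.025, size=2)
            hi_phases = rng.uniform(0, 2 * np.pi, size=2)
            wiggle = sum(
                a * np.cos(m * theta + p)
                for m, a, p in zip(hi_modes, hi_amps, hi_phases)
            )
        labels += radius < base * frac * (1.0 + pert + wiggle)

    map_a, map_b = _intensity_maps(rng, n_regions)

    # sigma 0.3 softens boundaries without spreading the variance
    # footprint beyond the immediate neighbors (keeps the edge rule crisp)
    image_a = gaussian_filter(map_a[labels], 0.3, mode="nearest")
    image_b = gaussian_filter(map_b[labels], 0.3, mode="nearest")
    return ContrastPair(
        labels=labels, image_a=image_a, image_b=image_b,
        map_a=map_a, map_b=map_b,
    )


def gaussian_kernel(size: int = 3, sigma: float = 0.5) -> np.ndarray:
    """Unit-sum separable Gaussian kernel of odd ``size``."""
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    k = np.arange(size) - size // 2
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    kernel = np.outer(w, w)
    return kernel / kernel.sum()


def degrade(hr: np.ndarray, spec: DegradationSpec = DegradationSpec()) -> np.ndarray:
    """HR -> LR: optional Rician noise, Gaussian blur, keep even rows/cols.

    The even-index decimation pairs with the ``LR(i,j) -> HR(2i,2j)``
    anchoring of the engines, so LR pixels are true (blurred) HR samples.
    """
    hr = np.asarray(hr, dtype=np.float64)
    if hr.shape[0] % 2 or hr.shape[1] % 2:
        raise ValueError("HR dimensions must be even")
    if spec.noise_level > 0:
        hr = np.clip(add_rician_noise(hr, spec.noise_level, spec.seed), 0, 1)
    kernel = gaussian_kernel(spec.kernel_size, spec.kernel_sigma)
    blurred = convolve(hr, kernel, mode="nearest")
    return blurred[::2, ::2]


def add_rician_noise(image: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Rician noise: magnitude of the image plus complex Gaussian noise.

    Zero-mean Gaussian noise with standard deviation ``level * max(image)``
    is added independently to the real and imaginary channels and the
    modulus is returned.  ``level=0`` returns ``|image|`` unchanged for
    nonnegative input.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if level == 0:
        return np.abs(image)
    peak = image.max()
    sigma = level * (peak if peak > 0 else 1.0)  # black image: unit peak
    rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, image.shape)
    g2 = rng.normal(0.0, sigma, image.shape)
    return np.hypot(image + g1, g2)
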