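"""Local patch sampling, 4-tap least-squares weight estimation, edge rule.

Every pixel in an image owns a square region (default 9x9) from which a
linear system is sampled: each interior patch contributes one row relating
a center intensity ``y_i`` to its four lattice neighbors ``x_{i,1..4}``.
The minimal-norm least-squares solution of that system is the local weight
vector ``b``; the same four neighbors drive the edge-pixel decision via a
variance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "RegionSampleSet",
    "WeightVector",
    "EdgeMask",
    "lattice_offsets",
    "extract_region_samples",
    "estimate_weights",
    "solve_weights_batch",
    "edge_mask",
    "sum_of_weights",
]

#: Relative singular-value cutoff for the minimal-norm pseudo-solution.
SV_CUTOFF = 1e-10

#: Default local-variance threshold for the edge-pixel rule (intensities
#: normalized to [0, 1]).
EDGE_THRESHOLD = 1e-4

# Neighbor column order is a package-wide convention: estimation and
# application must agree on it, nothing else depends on the choice.
_DIAGONAL = ((-1, -1), (-1, 1), (1, -1), (1, 1))  # UL, UR, LL, LR
_AXIAL = ((-1, 0), (0, 1), (1, 0), (0, -1))  # up, right, down, left


def lattice_offsets(lattice: str, spacing: int = 1) -> Tuple[Tuple[int, int], ...]:
    """Return the 4 neighbor offsets ``(drow, dcol)`` for a lattice.

    ``diagonal`` orders columns upper-left, upper-right, lower-left,
    lower-right; ``axial`` orders up, right, down, left.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if lattice == "diagonal":
        base = _DIAGONAL
    elif lattice == "axial":
        base = _AXIAL
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    return tuple((dr * spacing, dc * spacing) for dr, dc in base)


@dataclass(frozen=True)
class RegionSampleSet:
    """The sampled linear system of one local region.

    ``y`` holds the ``(region - 2)**2`` patch-center intensities in raster
    order; row ``i`` of ``X`` holds the 4 lattice neighbors of the pixel
    contributing ``y[i]``.
    """

    y: np.ndarray
    X: np.ndarray
    center: Tuple[int, int]
    lattice: str
    spacing: int
    region: int = 9

    def __post_init__(self) -> None:
        n = (self.region - 2) ** 2
        if self.y.shape != (n,) or self.X.shape != (n, 4):
            raise ValueError(
                f"inconsistent sample shapes {self.y.shape}, {self.X.shape} "
                f"for region {self.region}"
            )


@dataclass(frozen=True)
class WeightVector:
    """4 regression weights with estimation metadata."""

    b: np.ndarray
    residual_norm: float
    rank: int
    source: str = ""

    def __post_init__(self) -> None:
        if np.asarray(self.b).shape != (4,):
            raise ValueError("b must have exactly 4 entries")


@dataclass(frozen=True)
class EdgeMask:
    """Boolean edge map plus the rule parameters that produced it."""

    mask: np.ndarray
    threshold: float
    neighborhood: str = "diagonal, spacing 1"

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def _patch_center_offsets(region: int) -> Tuple[np.ndarray, np.ndarray]:
    # patch centers are the interior (region-2)x(region-2) pixels, raster order
    half = region // 2
    rel = np.arange(-half + 1, half)
    rr, cc = np.meshgrid(rel, rel, indexing="ij")
    return rr.ravel(), cc.ravel()


def extract_region_samples(
    image: np.ndarray,
    center: Tuple[int, int],
    lattice: str = "diagonal",
    spacing: int = 1,
    region: int = 9,
) -> RegionSampleSet:
    """Sample the local linear system of the region centered at ``center``.

    The image is replicate-padded so regions near (or beyond reach of) the
    border are always well defined; sampling is deterministic.

    Parameters
    ----------
    image:
        2D intensity array.
    center:
        ``(row, col)`` of the region center in image coordinates.
    lattice:
        ``diagonal`` or ``axial`` neighbor geometry.
    spacing:
        Neighbor distance in pixels (>= 1).
    region:
        Odd region size >= 5; a 9x9 region yields the canonical 49 rows.
    """
    region = int(region)
    if region < 5 or region % 2 == 0:
        raise ValueError("region size must be an odd integer >= 5")
    offsets = lattice_offsets(lattice, spacing)

    image = np.asarray(image, dtype=np.float64)
    margin = region // 2 + spacing
    padded = np.pad(image, margin, mode="edge")
    r0 = center[0] + margin
    c0 = center[1] + margin

    pr, pc = _patch_center_offsets(region)
    y = padded[r0 + pr, c0 + pc]
    X = np.empty((y.size, 4), dtype=np.float64)
    for j, (dr, dc) in enumerate(offsets):
        X[:, j] = padded[r0 + pr + dr, c0 + pc + dc]
    return RegionSampleSet(
        y=y, X=X, center=tuple(center), lattice=lattice, spacing=spacing,
        region=region,
    )


def solve_weights_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimal-norm least-squares weights for a stack of systems.

    ``X`` has shape ``(..., n, 4)`` and ``y`` shape ``(..., n)``; returns
    ``(..., 4)``.  Uses the SVD pseudoinverse with relative singular-value
    cutoff ``SV_CUTOFF`` so rank-deficient systems get the minimal-norm
    solution instead of failing.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pinv = np.linalg.pinv(X, rcond=SV_CUTOFF)
    return np.matmul(pinv, y[..., None])[..., 0]


def estimate_weights(samples: RegionSampleSet, source: str = "") -> WeightVector:
    """Estimate the 4 regression weights of a sampled region.

    Solves ``min_b ||y - X b||_2``; for full-column-rank ``X`` this equals
    the normal-equation solution ``(X^T X)^{-1} X^T y``, and on
    rank-deficient systems the minimal-norm solution is returned (singular
    values below ``SV_CUTOFF * sigma_max`` are treated as zero).
    """
    y, X = samples.y, samples.X
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("samples contain non-finite entries")
    b, _, rank, _ = np.linalg.lstsq(X, y, rcond=SV_CUTOFF)
    residual = float(np.linalg.norm(y - X @ b))
    return WeightVector(b=b, residual_norm=residual, rank=int(rank), source=source)


def neighbor_stack(
    image: np.ndarray, lattice: str = "diagonal", spacing: int = 1
) -> np.ndarray:
    """Per-pixel stack of the 4 lattice neighbors, shape ``(H, W, 4)``.

    Borders use replicate padding.
    """
    image = np.asarray(image, dtype=np.float64)
    offsets = lattice_offsets(lattice, spacing)
    padded = np.pad(image, spacing, mode="edge")
    h, w = image.shape
    out = np.empty((h, w, 4), dtype=np.float64)
    for j, (dr, dc) in enumerate(offsets):
        out[:, :, j] = padded[
            spacing + dr : spacing + dr + h, spacing + dc : spacing + dc + w
        ]
    return out


def edge_mask(
    image: np.ndarray,
    lattice: str = "diagonal",
    spacing: int = 1,
    threshold: float = EDGE_THRESHOLD,
) -> EdgeMask:
    """Flag edge pixels: population variance of the 4 lattice neighbors
    exceeds ``threshold``.

    The image must be normalized to ``[0, 1]`` — the default threshold is
    only meaningful on that scale.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.max() > 1.0 + 1e-9 or image.min() < -1e-9:
        raise ValueError("edge_mask expects intensities normalized to [0, 1]")
    nbrs = neighbor_stack(image, lattice, spacing)
    variance = nbrs.var(axis=2)  # population divisor (/4)
    return EdgeMask(
        mask=variance > threshold,
        threshold=float(threshold),
        neighborhood=f"{lattice}, spacing {spacing}",
    )


def sum_of_weights(w: WeightVector | Sequence[float]) -> float:
    """Sum of the 4 regression weights (approximately 1 on natural images)."""
    b = w.b if isinstance(w, WeightVector) else np.asarray(w, dtype=np.float64)
    return float(np.sum(b))
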