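"""Numerical diagnostics for the two weight-invariance properties.

Two empirical facts underpin borrowing weights across contrasts:

1. the four weights of an edge region sum to approximately 1 (the column
   sums of the sampled system nearly equal the center-pixel sum);
2. weights estimated from two registered images of different contrast are
   close, with the gap controlled by a residual term plus a perturbation
   term (a pseudoinverse perturbation bound).

This module measures both on whole images and on individual region pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from mcnedi.weight_regression import (
    EDGE_THRESHOLD,
    SV_CUTOFF,
    RegionSampleSet,
    _patch_center_offsets,
    edge_mask,
    estimate_weights,
    lattice_offsets,
    solve_weights_batch,
)

__all__ = [
    "BoundDecomposition",
    "FractionReport",
    "neighbor_sum_balance",
    "sum_of_weights_survey",
    "bound_decomposition",
    "weight_similarity_survey",
]


@dataclass(frozen=True)
class BoundDecomposition:
    """The three terms of the cross-contrast weight-error bound.

    ``lhs <= term_residual + term_perturb`` whenever the second system's
    matrix has full column rank.
    """

    lhs: float
    term_residual: float
    term_perturb: float

    @property
    def rhs(self) -> float:
        return self.term_residual + self.term_perturb

    def holds(self, tol: float = 1e-9) -> bool:
        scale = max(self.lhs, self.rhs, 1.0)
        return self.lhs <= self.rhs + tol * scale


@dataclass(frozen=True)
class FractionReport:
    """Histogram of a per-region statistic over surveyed edge regions."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    n_regions: int
    values: np.ndarray
    centers: np.ndarray  # (n_regions, 2) surveyed (row, col) centers

    def fraction_within(self, lo: float, hi: float) -> float:
        """Fraction of surveyed regions whose statistic lies in [lo, hi]."""
        if self.n_regions == 0:
            return float("nan")
        return float(np.mean((self.values >= lo) & (self.values <= hi)))


def neighbor_sum_balance(
    samples: RegionSampleSet,
) -> Tuple[np.ndarray, float, float]:
    """Column sums vs center sum of one sampled region.

    Returns ``(column_sums, y_sum, max_rel_discrepancy)``.  When the four
    column sums all match the center sum, the weight sum is forced toward 1.
    """
    column_sums = samples.X.sum(axis=0)
    y_sum = float(samples.y.sum())
    denom = max(abs(y_sum), 1e-12)
    max_rel = float(np.max(np.abs(column_sums - y_sum)) / denom)
    return column_sums, y_sum, max_rel


def _default_stride(shape: Tuple[int, int]) -> int:
    return 1 if max(shape) <= 128 else 4


def _survey_centers(image: np.ndarray, stride: int) -> Tuple[np.ndarray, np.ndarray]:
    h, w = image.shape
    rr, cc = np.meshgrid(
        np.arange(0, h, stride), np.arange(0, w, stride), indexing="ij"
    )
    return rr.ravel(), cc.ravel()


def _batched_region_weights(
    image: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    lattice: str,
    spacing: int,
    region: int,
) -> np.ndarray:
    """Weights for many region centers of one image, shape (N, 4)."""
    offsets = lattice_offsets(lattice, spacing)
    margin = region // 2 + spacing
    padded = np.pad(np.asarray(image, dtype=np.float64), margin, mode="edge")
    pr, pc = _patch_center_offsets(region)
    r0 = rows[:, None] + margin + pr[None, :]
    c0 = cols[:, None] + margin + pc[None, :]
    y = padded[r0, c0]
    X = np.empty(y.shape + (4,), dtype=np.float64)
    for j, (dr, dc) in enumerate(offsets):
        X[:, :, j] = padded[r0 + dr, c0 + dc]
    return solve_weights_batch(X, y)


def _histogram_report(values: np.ndarray, centers: np.ndarray,
                      bins: int = 20) -> FractionReport:
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return FractionReport(
            bin_edges=np.array([]), fractions=np.array([]),
            n_regions=0, values=values, centers=np.empty((0, 2), dtype=int),
        )
    # effectively-constant data cannot support many finite-width bins
    if np.ptp(values) < 1e-9 * max(1.0, float(np.abs(values).max())):
        v = values[0]
        counts, edges = np.histogram(values, bins=1,
                                     range=(v - 0.5, v + 0.5))
    else:
        counts, edges = np.histogram(values, bins=bins)
    return FractionReport(
        bin_edges=edges,
        fractions=counts / values.size,
        n_regions=int(values.size),
        values=values,
        centers=np.asarray(centers),
    )


def sum_of_weights_survey(
    image: np.ndarray,
    stride: Optional[int] = None,
    lattice: str = "diagonal",
    spacing: int = 1,
    region: int = 9,
    threshold: float = EDGE_THRESHOLD,
) -> FractionReport:
    """Survey the weight sum over every edge-region center on a stride grid.

    Only edge pixels (local neighbor variance above ``threshold``) are
    surveyed — that is the operating domain of the interpolation engines.
    ``report.fraction_within(0.95, 1.05)`` gives the headline coverage.
    """
    image = np.asarray(image, dtype=np.float64)
    if stride is None:
        stride = _default_stride(image.shape)
    rows, cols = _survey_centers(image, stride)
    mask = edge_mask(image, lattice, spacing, threshold).mask
    keep = mask[rows, cols]
    rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        warnings.warn("no edge regions found; empty survey", stacklevel=2)
        return _histogram_report(np.array([]), np.empty((0, 2), dtype=int))
    b = _batched_region_weights(image, rows, cols, lattice, spacing, region)
    return _histogram_report(b.sum(axis=1), np.column_stack([rows, cols]))


def bound_decomposition(
    samples_a: RegionSampleSet, samples_b: RegionSampleSet
) -> BoundDecomposition:
    """Evaluate the weight-error bound for one pair of sampled regions.

    Weights ``b`` come from ``samples_a`` and ``b~`` from ``samples_b``;
    the two terms use the minimal-norm pseudoinverse of the second
    system's matrix.
    """
    geo_a = (samples_a.center, samples_a.lattice, samples_a.spacing,
             samples_a.region)
    geo_b = (samples_b.center, samples_b.lattice, samples_b.spacing,
             samples_b.region)
    if geo_a != geo_b:
        raise ValueError(f"region geometry mismatch: {geo_a} vs {geo_b}")

    b = estimate_weights(samples_a).b
    b_tilde = estimate_weights(samples_b).b
    X, y = samples_a.X, samples_a.y
    Xt, yt = samples_b.X, samples_b.y
    pinv = np.linalg.pinv(Xt, rcond=SV_CUTOFF)
    d = yt - y
    C = Xt - X
    return BoundDecomposition(
        lhs=float(np.linalg.norm(b_tilde - b)),
        term_residual=float(np.linalg.norm(pinv @ (y - X @ b))),
        term_perturb=float(np.linalg.norm(pinv @ (d - C @ b))),
    )


def weight_similarity_survey(
    image_a: np.ndarray,
    image_b: np.ndarray,
    stride: Optional[int] = None,
    lattice: str = "diagonal",
    spacing: int = 1,
    region: int = 9,
    threshold: float = EDGE_THRESHOLD,
    edge_from: str = "both",
) -> FractionReport:
    """Survey ``||b~ - b||_2`` between two registered contrasts.

    Weights are estimated independently from each image at the same region
    centers; centers are taken on a stride grid where the edge rule fires
    (``edge_from``: ``a``, ``b``, ``both`` = intersection, ``either`` =
    union).  ``report.fraction_within(0, 0.25)`` gives the headline
    similarity coverage.
    """
    image_a = np.asarray(image_a, dtype=np.float64)
    image_b = np.asarray(image_b, dtype=np.float64)
    if image_a.shape != image_b.shape:
        raise ValueError(
            f"shape mismatch: {image_a.shape} vs {image_b.shape}"
        )
    if stride is None:
        stride = _default_stride(image_a.shape)
    mask_a = edge_mask(image_a, lattice, spacing, threshold).mask
    mask_b = edge_mask(image_b, lattice, spacing, threshold).mask
    if edge_from == "a":
        mask = mask_a
    elif edge_from == "b":
        mask = mask_b
    elif edge_from == "both":
        mask = mask_a & mask_b
    elif edge_from == "either":
        mask = mask_a | mask_b
    else:
        raise ValueError(f"unknown edge_from {edge_from!r}")

    rows, cols = _survey_centers(image_a, stride)
    keep = mask[rows, cols]
    rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        warnings.warn("no edge regions found; empty survey", stacklevel=2)
        return _histogram_report(np.array([]), np.empty((0, 2), dtype=int))
    wa = _batched_region_weights(image_a, rows, cols, lattice, spacing, region)
    wb = _batched_region_weights(image_b, rows, cols, lattice, spacing, region)
    return _histogram_report(np.linalg.norm(wb - wa, axis=1),
                             np.column_stack([rows, cols]))
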