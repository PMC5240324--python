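"""x2 super-resolution engines: classic NEDI and its multi-contrast variant.

Both engines expand the low-resolution (LR) image so that LR pixel ``(i, j)``
lands at high-resolution (HR) position ``(2i, 2j)`` and then fill the three
interpolated parities in two passes:

- pass 1: odd-odd HR pixels from their 4 diagonal neighbors (which are LR
  pixels);
- pass 2: the remaining odd-parity pixels from their 4 axial neighbors on
  the 45-degree rotated lattice of already-known pixels.

For every interpolated pixel flagged as an edge (variance of its 4 neighbors
above a threshold) the 4-tap weights are estimated by local least squares —
from the LR image itself (NEDI) or from a registered HR image of another
contrast (multi-contrast mode) — and the new value is the weighted sum of
the neighbors.  Non-edge pixels fall back to bicubic.  Even-even pixels
always keep their LR values (data consistency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np


from mcnedi.weight_regression import (
    EDGE_THRESHOLD,
    WeightVector,
    _patch_center_offsets,
    lattice_offsets,
    solve_weights_batch,
)

__all__ = [
    "UpscaleResult",
    "expand_nearest",
    "interpolate_pixel",
    "nedi_upscale",
    "multicontrast_upscale",
    "bicubic_baseline",
]

logger = logging.getLogger(__name__)

#: Pixels whose estimated weights have l1 norm above this are treated as
#: unstable and sent to the bicubic fallback.
WEIGHT_L1_GUARD = 4.0


@dataclass(frozen=True)
class UpscaleResult:
    """A x2 upscaled image plus bookkeeping about the interpolation."""

    image: np.ndarray
    edge_fraction: float
    fallback_fraction: float
    method: str = ""


def expand_nearest(lr: np.ndarray, factor: int = 2) -> np.ndarray:
    """Replicate every LR pixel into a ``factor x factor`` block.

    Only ``factor=2`` is supported; LR pixel ``(i, j)`` lands at HR
    ``(2i, 2j)``.
    """
    if factor != 2:
        raise ValueError("only x2 expansion is supported")
    lr = np.asarray(lr, dtype=np.float64)
    return np.repeat(np.repeat(lr, 2, axis=0), 2, axis=1)


def interpolate_pixel(weights: WeightVector | np.ndarray, neighbors) -> float:
    """Weighted sum ``b . s`` of 4 neighbor intensities, clipped to [0, 1]."""
    b = weights.b if isinstance(weights, WeightVector) else np.asarray(weights)
    s = np.asarray(neighbors, dtype=np.float64)
    if b.shape != (4,) or s.shape != (4,):
        raise ValueError("weights and neighbors must both have 4 entries")
    return float(np.clip(b @ s, 0.0, 1.0))


# Catmull-Rom (a = -0.5) taps at the half-pixel position.
_CUBIC_TAPS = (-0.0625, 0.5625, 0.5625, -0.0625)


def _cubic_double(x: np.ndarray) -> np.ndarray:
    """Double the first axis: even rows copy, odd rows cubic half-samples."""
    p = np.pad(x, ((1, 2), (0, 0)), mode="edge")
    odd = (_CUBIC_TAPS[0] * p[:-3] + _CUBIC_TAPS[1] * p[1:-2]
           + _CUBIC_TAPS[2] * p[2:-1] + _CUBIC_TAPS[3] * p[3:])
    out = np.empty((2 * x.shape[0], x.shape[1]), dtype=np.float64)
    out[::2] = x
    out[1::2] = odd
    return out


def bicubic_baseline(lr: np.ndarray, factor: int = 2) -> np.ndarray:
    """Standard bicubic (Catmull-Rom) x2 resampling, even-even anchored.

    HR coordinate ``(r, c)`` samples LR coordinate ``(r/2, c/2)``, so
    ``HR(2i, 2j) = LR(i, j)`` exactly and polynomial ramps are reproduced
    away from the replicated border.
    """
    if factor != 2:
        raise ValueError("only x2 upscaling is supported")
    lr = np.asarray(lr, dtype=np.float64)
    hr = _cubic_double(_cubic_double(lr).T).T
    return np.clip(hr, 0.0, 1.0)


def _neighbor_values(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                     offsets) -> np.ndarray:
    """Gather the 4 lattice neighbors of each (row, col), edge-replicated."""
    padded = np.pad(canvas, 1, mode="edge")
    s = np.empty((rows.size, 4), dtype=np.float64)
    for j, (dr, dc) in enumerate(offsets):
        s[:, j] = padded[rows + 1 + dr, cols + 1 + dc]
    return s


def _batched_weights(est_padded: np.ndarray, margin: int, rows: np.ndarray,
                     cols: np.ndarray, offsets, region: int) -> np.ndarray:
    """Estimate weights for many region centers of one estimation image."""
    pr, pc = _patch_center_offsets(region)
    r0 = rows[:, None] + margin + pr[None, :]
    c0 = cols[:, None] + margin + pc[None, :]
    y = est_padded[r0, c0]
    X = np.empty(y.shape + (4,), dtype=np.float64)
    for j, (dr, dc) in enumerate(offsets):
        X[:, :, j] = est_padded[r0 + dr, c0 + dc]
    return solve_weights_batch(X, y)


def _fill_pass(
    canvas: np.ndarray,
    fallback: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    lattice: str,
    est_padded: np.ndarray,
    est_rows: np.ndarray,
    est_cols: np.ndarray,
    margin: int,
    region: int,
    threshold: float,
) -> tuple[int, int]:
    """Fill one parity class of interpolated pixels in place.

    Returns ``(n_edge, n_fallback)`` — how many of the pixels were treated
    as edges and how many ended up on the fallback interpolator (non-edge
    plus unstable-weight pixels).
    """
    offsets = lattice_offsets(lattice, 1)
    s = _neighbor_values(canvas, rows, cols, offsets)
    is_edge = s.var(axis=1) > threshold  # variance of the taps themselves

    values = fallback[rows, cols].copy()
    n_guard = 0
    if is_edge.any():
        er, ec = rows[is_edge], cols[is_edge]
        b = _batched_weights(
            est_padded, margin, est_rows[is_edge], est_cols[is_edge],
            offsets, region,
        )
        raw = np.einsum("ij,ij->i", b, s[is_edge])
        unstable = np.abs(b).sum(axis=1) > WEIGHT_L1_GUARD
        n_guard = int(unstable.sum())
        overshoot = int(((raw < 0) | (raw > 1)).sum())
        if overshoot:
            logger.debug("%d interpolated values clipped to [0, 1]", overshoot)
        est = np.where(unstable, values[is_edge], np.clip(raw, 0.0, 1.0))
        values[is_edge] = est
    canvas[rows, cols] = values
    n_edge = int(is_edge.sum())
    return n_edge, (rows.size - n_edge) + n_guard


def _parity_targets(h: int, w: int):
    """HR index arrays for the two passes: odd-odd, then mixed parity."""
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    odd_odd = (rr % 2 == 1) & (cc % 2 == 1)
    mixed = (rr + cc) % 2 == 1
    return (rr[odd_odd], cc[odd_odd]), (rr[mixed], cc[mixed])


def _run_engine(
    lr: np.ndarray,
    est_image: np.ndarray,
    est_scale: int,
    region: int,
    threshold: float,
    method: str,
) -> UpscaleResult:
    """Shared two-pass engine; ``est_image`` supplies the weights.

    ``est_scale`` maps HR pixel coordinates to estimation-image coordinates
    (2 when weights come from the LR image itself, 1 when they come from an
    HR reference).
    """
    lr = np.asarray(lr, dtype=np.float64)
    if min(lr.shape) < 9:
        raise ValueError("LR image must be at least 9x9")
    if lr.min() < -1e-9 or lr.max() > 1.0 + 1e-9:
        raise ValueError("LR image must be normalized to [0, 1]")
    if region < 5 or region % 2 == 0:
        raise ValueError("region size must be an odd integer >= 5")

    canvas = expand_nearest(lr)
    h, w = canvas.shape
    fallback = bicubic_baseline(lr)

    margin = region // 2 + 1
    est_padded = np.pad(np.asarray(est_image, dtype=np.float64), margin,
                        mode="edge")

    (r1, c1), (r2, c2) = _parity_targets(h, w)
    stats = []
    for rows, cols, lattice in ((r1, c1, "diagonal"), (r2, c2, "axial")):
        stats.append(
            _fill_pass(
                canvas, fallback, rows, cols, lattice,
                est_padded, rows // est_scale, cols // est_scale,
                margin, region, threshold,
            )
        )

    canvas[::2, ::2] = lr  # data consistency, exact
    total = r1.size + r2.size
    n_edge = sum(s[0] for s in stats)
    n_fb = sum(s[1] for s in stats)
    return UpscaleResult(
        image=canvas,
        edge_fraction=n_edge / total,
        fallback_fraction=n_fb / total,
        method=method,
    )


def nedi_upscale(
    lr: np.ndarray,
    region: int = 9,
    threshold: float = EDGE_THRESHOLD,
) -> UpscaleResult:
    """Classic single-image NEDI x2 upscaling.

    Weights for each edge pixel are estimated from the LR image itself, in
    the region around the corresponding LR location, exploiting the
    geometric duality between the LR and HR lattices.
    """
    return _run_engine(lr, lr, est_scale=2, region=region,
                       threshold=threshold, method="nedi")


def multicontrast_upscale(
    lr_target: np.ndarray,
    hr_reference: np.ndarray,
    region: int = 9,
    threshold: float = EDGE_THRESHOLD,
) -> UpscaleResult:
    """x2 upscaling of ``lr_target`` with weights borrowed from a registered
    HR image of another contrast.

    ``hr_reference`` must already have the target HR shape (2x the LR
    shape) and be co-registered with the target; registration is the
    caller's responsibility.  Weights are estimated in the reference region
    centered at the same HR coordinates as each interpolated pixel and
    applied to the target's own neighbors, so the output keeps the target's
    contrast.  Globally rescaling the reference does not change the result
    (least-squares weights are scale invariant; the edge decision is made
    on the target).
    """
    lr_target = np.asarray(lr_target, dtype=np.float64)
    hr_reference = np.asarray(hr_reference, dtype=np.float64)
    expected = (2 * lr_target.shape[0], 2 * lr_target.shape[1])
    if hr_reference.shape != expected:
        raise ValueError(
            f"reference shape {hr_reference.shape} does not match the "
            f"target HR shape {expected}"
        )
    if not np.all(np.isfinite(hr_reference)):
        raise ValueError("reference contains non-finite values")
    return _run_engine(lr_target, hr_reference, est_scale=1, region=region,
                       threshold=threshold, method="mcnedi")
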