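"""Stick directionality by dynamic time warping.

A matched density stick still has two possible N→C readings.  Both the model
SSE's Cα trace and the stick's axis points are ordered 3-D sequences, so the
cheaper of the two warping alignments — stick as given versus stick reversed —
decides the direction flag: +1 (forward) when the forward cost is strictly
smaller, −1 otherwise.  The same orientation-free cost, min(forward,
backward), also serves as the arbiter when several sticks compete for one
model SSE during conflict resolution.

The DTW recurrence is the textbook one on squared Euclidean point distances:
D(0,0)=0, the rest of row/column 0 is +∞, and
D(i,j) = cost(i,j) + min{D(i−1,j), D(i,j−1), D(i−1,j−1)}.  The returned cost
is the raw accumulated sum D(m,n); an optional length-normalized variant
(divide by m+n) exists for comparing sticks of very different lengths, and is
off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["DTWResult", "dtw_cost", "dtw_cost_with_matrix", "detect_direction",
           "orientation_free_cost"]


@dataclass
class DTWResult:
    """Forward/backward DTW costs and the resulting direction flag."""

    cost_forward: float
    cost_backward: float
    direction: int
    accumulation: np.ndarray | None = None


def _as_seq(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 3:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (n, 3) point sequence, got shape {pts.shape}")
    if len(pts) == 0:
        raise InputError("empty sequence")
    return pts


def _accumulate(seq_a: np.ndarray, seq_b: np.ndarray) -> np.ndarray:
    m, n = len(seq_a), len(seq_b)
    local = cdist(seq_a, seq_b, "sqeuclidean")
    D = np.full((m + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        row = D[i]
        prev = D[i - 1]
        cost = local[i - 1]
        for j in range(1, n + 1):
            row[j] = cost[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return D


def dtw_cost(seq_a, seq_b, normalized: bool = False) -> float:
    """Accumulated DTW cost between two ordered 3-D point sequences."""
    a = _as_seq(seq_a)
    b = _as_seq(seq_b)
    total = float(_accumulate(a, b)[len(a), len(b)])
    if normalized:
        total /= len(a) + len(b)
    return total


def dtw_cost_with_matrix(seq_a, seq_b):
    """DTW cost plus the full (m+1)×(n+1) accumulation matrix."""
    a = _as_seq(seq_a)
    b = _as_seq(seq_b)
    D = _accumulate(a, b)
    return float(D[len(a), len(b)]), D


def orientation_free_cost(seq_a, seq_b, normalized: bool = False) -> float:
    """min(forward, backward) DTW cost — invariant to point-order reversal of
    either sequence; used to arbitrate competing matches."""
    b = _as_seq(seq_b)
    return min(
        dtw_cost(seq_a, b, normalized=normalized),
        dtw_cost(seq_a, b[::-1], normalized=normalized),
    )


def detect_direction(model_trace, stick_points) -> DTWResult:
    """Assign the N→C reading of a stick matched to a model SSE.

    Forward cost aligns the stick as stored; backward cost aligns the
    reversed stick.  Direction is +1 only on a strict forward win; an exact
    tie yields −1 (ties normally indicate palindromic or degenerate input
    and are logged).
    """
    trace = _as_seq(model_trace)
    pts = _as_seq(stick_points)
    cost_f = dtw_cost(trace, pts)
    cost_b = dtw_cost(trace, pts[::-1])
    if cost_f == cost_b:
        logger.warning(
            "DTW forward/backward tie (%.6g): palindromic or degenerate stick",
            cost_f,
        )
    direction = +1 if cost_f < cost_b else -1
    return DTWResult(cost_forward=cost_f, cost_backward=cost_b, direction=direction)
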