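"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, exact integer
arithmetic) kept free of any code from the package's computational paths.
"""

from __future__ import annotations

from math import comb

import numpy as np


def com_bruteforce(data: np.ndarray) -> tuple[float, float, float]:
    """Centroid of positive voxels by explicit accumulation."""
    total = 0
    acc = [0.0, 0.0, 0.0]
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                if data[z, y, x]:
                    total += 1
                    acc[0] += z
                    acc[1] += y
                    acc[2] += x
    return acc[0] / total, acc[1] / total, acc[2] / total


def projection_bruteforce(data: np.ndarray, axis: int) -> np.ndarray:
    shape = [s for i, s in enumerate(data.shape) if i != axis]
    out = np.zeros(shape, dtype=int)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                if data[z, y, x]:
                    idx = [z, y, x]
                    del idx[axis]
                    out[tuple(idx)] += 1
    return out


def spans_bruteforce(
    data: np.ndarray, voxel: tuple[float, float, float], k_span: float = 1.0
) -> dict[str, float]:
    """Spans from mean+k·SD-thresholded projections, double-loop style."""

    def thresholded(proj: np.ndarray) -> list[tuple[int, int]]:
        flat = proj.astype(float).ravel()
        thr = flat.mean() + k_span * flat.std()
        return [
            (r, c)
            for r in range(proj.shape[0])
            for c in range(proj.shape[1])
            if proj[r, c] > thr
        ]

    dv = projection_bruteforce(data, 0)  # rows RC, cols ML
    keep = thresholded(dv)
    if keep:
        rows = [r for r, _ in keep]
        cols = [c for _, c in keep]
        span_rc = (max(rows) - min(rows) + 1) * voxel[1]
        span_ml = (max(cols) - min(cols) + 1) * voxel[2]
    else:
        span_rc = span_ml = 0.0
    rc = projection_bruteforce(data, 1)  # rows DV, cols ML
    keep = thresholded(rc)
    if keep:
        zrows = [r for r, _ in keep]
        span_dv = (max(zrows) - min(zrows) + 1) * voxel[0]
    else:
        span_dv = 0.0
    return {"ML": span_ml, "RC": span_rc, "DV": span_dv}


def density_bruteforce(
    data: np.ndarray, voxel: tuple[float, float, float], axis: int
) -> float:
    proj = projection_bruteforce(data, axis)
    occupied = sum(
        1 for r in range(proj.shape[0]) for c in range(proj.shape[1]) if proj[r, c] > 0
    )
    remaining = [v for i, v in enumerate(voxel) if i != axis]
    return int(data.sum()) / (occupied * remaining[0] * remaining[1])


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration.

    Sums hypergeometric point probabilities no larger than the observed
    one (same 1e-7 relative slack as the implementation, applied in
    integer arithmetic so there is no floating-point pmf in the oracle).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    n_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        n_k = comb(r1, k) * comb(r2, c1 - k)
        if n_k * 10**7 <= n_obs * (10**7 + 1):
            total += n_k
    return total / denom
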