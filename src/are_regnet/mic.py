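"""Maximal information coefficient (MIC) between two real-valued vectors.

MIC quantifies arbitrary (not just linear) statistical dependence by searching
over two-dimensional grids: for each grid resolution (nx columns by ny rows)
with ``nx * ny <= B(n)``, the mutual information of the induced discrete joint
distribution is maximised over grid-line placements and normalised by
``log(min(nx, ny))``, so that a noiseless functional relationship scores 1 and
statistical independence scores ~0.  MIC is the maximum entry of this
*characteristic matrix*.

Two estimators are provided:

``compute_mic(..., MicParams(exhaustive_mode=False))``
    The MINE heuristic: equipartition one axis into ny equal-frequency rows,
    then find the dynamic-programming-optimal column partition with boundaries
    restricted to superclump edges; repeat with axes swapped and take the
    elementwise maximum of the two characteristic matrices.  Every grid it
    evaluates is a genuine grid, so its score is a lower bound of the true MIC.

``compute_mic(..., MicParams(exhaustive_mode=True))``
    Brute-force enumeration of *all* grid-line placements for every admissible
    (nx, ny).  Exponential in n; intended as the ground-truth oracle for
    n <= ~15.

Both estimators operate on ranks only, which makes MIC invariant under
strictly monotone transforms of either variable.  Ties in values are broken
by the stable order of sample index when forming partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MicParams", "compute_mic", "grid_budget"]

_EXHAUSTIVE_MAX_N = 16


@dataclass(frozen=True)
class MicParams:
    """MIC search parameters.

    alpha : grid-budget exponent, B(n) = n**alpha (0 < alpha <= 1).
    clump_factor : superclump multiplier c; the DP may place column boundaries
        at up to c * nx_max approximately equal-frequency positions.
    exhaustive_mode : enumerate every grid placement instead of the heuristic.
    """

    alpha: float = 0.6
    clump_factor: int = 15
    exhaustive_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.clump_factor < 1:
            raise ValueError(f"clump_factor must be >= 1, got {self.clump_factor}")


def grid_budget(n: int, alpha: float) -> int:
    """Maximal grid size B(n) = floor(n**alpha), floored at 4 so the minimal
    2x2 grid is always admissible."""
    return max(4, int(math.floor(n**alpha)))


def _stable_ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(v.size, dtype=np.int64)
    return ranks


@njit(cache=True)
def _char_max_one_orientation(
    ryx: np.ndarray, B: int, c: int, L: np.ndarray
) -> float:
    """Max normalised-MI over the characteristic matrix for one orientation.

    ryx: y-ranks (a permutation of 0..n-1) of the points sorted by x.
    The y axis is equipartitioned into ny rows; the x axis is optimised by
    dynamic programming over superclump boundaries.  L[m] = m*log(m) is a
    precomputed table: a column of m points with per-row cell counts c_r
    contributes (sum_r L[c_r] - L[m]) / n to H(P) - H(P,Q) (the log-n terms
    cancel because sum_r c_r = m), so the hot loops need no log calls.
    """
    n = ryx.shape[0]
    best = 0.0
    for ny in range(2, B // 2 + 1):
        nx_max = B // ny
        if nx_max < 2:
            break
        # equal-frequency row of each point (in x order)
        rows = np.empty(n, np.int64)
        rowcnt = np.zeros(ny, np.int64)
        for i in range(n):
            r = ryx[i] * ny // n
            rows[i] = r
            rowcnt[r] += 1
        hq = math.log(n)
        for r in range(ny):
            hq -= L[rowcnt[r]] / n
        # superclump boundaries: k approximately equal-frequency cut points
        k = c * nx_max
        if k > n:
            k = n
        ends = np.empty(k + 1, np.int64)
        for t in range(k + 1):
            ends[t] = t * n // k
        # cumulative row counts at clump ends
        cum = np.zeros((k + 1, ny), np.int64)
        pos = 0
        for t in range(1, k + 1):
            for r in range(ny):
                cum[t, r] = cum[t - 1, r]
            while pos < ends[t]:
                cum[t, rows[pos]] += 1
                pos += 1
        # g[i, j] (j < i): contribution of a column spanning clumps (j, i] to
        # H(P) - H(P,Q); additive over columns, so I = H(Q) + sum over columns.
        g = np.zeros((k + 1, k + 1), np.float64)
        for i in range(1, k + 1):
            for j in range(i):
                val = -L[ends[i] - ends[j]]
                for r in range(ny):
                    val += L[cum[i, r] - cum[j, r]]
                g[i, j] = val / n
        # DP over number of columns; f_prev[i] = best sum of column
        # contributions for the first i clumps split into (nx-1) columns.
        f_prev = np.empty(k + 1, np.float64)
        f_new = np.empty(k + 1, np.float64)
        f_prev[0] = 0.0
        for i in range(1, k + 1):
            f_prev[i] = g[i, 0]
        for nx in range(2, nx_max + 1):
            for i in range(k + 1):
                if i < nx:
                    f_new[i] = -np.inf
                    continue
                m_best = -np.inf
                for j in range(nx - 1, i):
                    v = f_prev[j] + g[i, j]
                    if v > m_best:
                        m_best = v
                f_new[i] = m_best
            for i in range(k + 1):
                f_prev[i] = f_new[i]
            mi = hq + f_prev[k]
            norm = math.log(min(nx, ny))
            val = mi / norm
            if val > best:
                best = val
    return best


def _xlogx_table(n: int) -> np.ndarray:
    m = np.arange(n + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = m * np.log(m)
    L[0] = 0.0
    return L


@njit(cache=True)
def _next_combination(b: np.ndarray, maxval: int) -> bool:
    """Advance strictly-increasing boundary tuple b (values in 1..maxval)."""
    k = b.shape[0]
    i = k - 1
    while i >= 0 and b[i] == maxval - (k - 1 - i):
        i -= 1
    if i < 0:
        return False
    b[i] += 1
    for j in range(i + 1, k):
        b[j] = b[j - 1] + 1
    return True


@njit(cache=True)
def _exhaustive_best(ryx: np.ndarray, B: int) -> float:
    """True MIC by enumerating every grid with nx*ny <= B (exponential)."""
    n = ryx.shape[0]
    best = 0.0
    col = np.empty(n, np.int64)
    for nx in range(2, B // 2 + 1):
        for ny in range(2, B // nx + 1):
            if nx > n or ny > n:
                continue
            norm = math.log(min(nx, ny))
            bx = np.empty(nx - 1, np.int64)
            for t in range(nx - 1):
                bx[t] = t + 1
            while True:
                # column of each point position (points sorted by x)
                ci = 0
                for i in range(n):
                    while ci < nx - 1 and i >= bx[ci]:
                        ci += 1
                    col[i] = ci
                by = np.empty(ny - 1, np.int64)
                for t in range(ny - 1):
                    by[t] = t + 1
                while True:
                    counts = np.zeros((nx, ny), np.float64)
                    for i in range(n):
                        yr = ryx[i]
                        r = 0
                        while r < ny - 1 and yr >= by[r]:
                            r += 1
                        counts[col[i], r] += 1.0
                    # plug-in mutual information of the induced partition
                    hx = 0.0
                    hy = 0.0
                    hxy = 0.0
                    for a in range(nx):
                        s = 0.0
                        for b in range(ny):
                            cell = counts[a, b]
                            s += cell
                            if cell > 0.0:
                                p = cell / n
                                hxy -= p * math.log(p)
                        if s > 0.0:
                            p = s / n
                            hx -= p * math.log(p)
                    for b in range(ny):
                        s = 0.0
                        for a in range(nx):
                            s += counts[a, b]
                        if s > 0.0:
                            p = s / n
                            hy -= p * math.log(p)
                    val = (hx + hy - hxy) / norm
                    if val > best:
                        best = val
                    if not _next_combination(by, n - 1):
                        break
                if not _next_combination(bx, n - 1):
                    break
    return best


def _validate_pair(x, y, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: len(x)={x.size}, len(y)={y.size}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite with no missing values")
    return x, y


def compute_mic(x, y, params: MicParams | None = None) -> float:
    """MIC score in [0, 1] between vectors x and y.

    A constant vector carries no information about the other, so either input
    being constant yields 0.0 (not an error).
    """
    params = params or MicParams()
    x, y = _validate_pair(x, y)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0
    n = x.size
    B = grid_budget(n, params.alpha)
    rx = _stable_ranks(x)
    ry = _stable_ranks(y)
    ry_in_x_order = ry[np.argsort(x, kind="stable")]
    if params.exhaustive_mode:
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive grid enumeration is limited to n <= {_EXHAUSTIVE_MAX_N}"
            )
        # grids are enumerated over both axes, so one orientation suffices
        score = _exhaustive_best(ry_in_x_order, B)
    else:
        rx_in_y_order = rx[np.argsort(y, kind="stable")]
        L = _xlogx_table(n)
        score = max(
            _char_max_one_orientation(ry_in_x_order, B, params.clump_factor, L),
            _char_max_one_orientation(rx_in_y_order, B, params.clump_factor, L),
        )
    return float(min(max(score, 0.0), 1.0))
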