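"""Dynamic Time Warping, written out as the textbook dynamic program.

Local cost is the absolute difference; accumulation uses the symmetric
step pattern with diagonal weight 2,

    D(i,j) = min(D(i-1,j-1) + 2*d(i,j), D(i-1,j) + d(i,j), D(i,j-1) + d(i,j)),

which makes the total cost symmetric in its arguments and normalizable by
``n + m``.  The optimal warping path is recovered by backtracking, with
ties resolved deterministically (diagonal first, then the i-decrement).
A near-diagonal path — quantified here by the coefficient of determination
of the path against the straight corner-to-corner line — indicates that
the two series share temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WarpPath", "DTWResult", "dtw_align", "path_linearity", "downsample"]

#: refuse to allocate cost matrices above this many cells
DEFAULT_CELL_CAP = 200_000_000


@dataclass(frozen=True)
class WarpPath:
    """Monotone alignment path: 0-based (i, j) index pairs."""

    pairs: np.ndarray  # shape (L, 2), int

    def __post_init__(self) -> None:
        p = np.asarray(self.pairs, dtype=int)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise ValueError("path must be a non-empty (L, 2) index array")
        steps = np.diff(p, axis=0)
        if p.shape[0] > 1:
            ok = np.all((steps >= 0) & (steps <= 1)) and np.all(steps.sum(axis=1) >= 1)
            if not ok:
                raise ValueError("path steps must be in {(1,0), (0,1), (1,1)}")
        if tuple(p[0]) != (0, 0):
            raise ValueError("path must start at (0, 0)")
        object.__setattr__(self, "pairs", p)

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class DTWResult:
    total_cost: float
    normalized_cost: float
    path: WarpPath
    linearity_r2: float


def dtw_align(
    x: np.ndarray, y: np.ndarray, cell_cap: int = DEFAULT_CELL_CAP
) -> DTWResult:
    """Align two series and return cost, path and the linearity diagnostic.

    ``total_cost`` is zero exactly when the series are identical.  Matrices
    larger than ``cell_cap`` cells are refused; downsample first (see
    :func:`downsample`).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("DTW inputs must be non-empty")
    if n * m > cell_cap:
        raise MemoryError(
            f"cost matrix would need {n*m:,} cells (cap {cell_cap:,}); "
            f"downsample the inputs (e.g. block-mean by a factor of "
            f"{int(np.ceil(np.sqrt(n * m / cell_cap)))})"
        )
    d = np.abs(x[:, None] - y[None, :])
    D = np.empty((n, m))
    D[0, 0] = d[0, 0]
    np.cumsum(d[0, :], out=D[0, :])
    np.cumsum(d[:, 0], out=D[:, 0])
    for i in range(1, n):
        Di, Dp, di = D[i], D[i - 1], d[i]
        for j in range(1, m):
            Di[j] = di[j] + min(Dp[j - 1] + di[j], Dp[j], Di[j - 1])
    path = _backtrack(D, d)
    total = float(D[-1, -1])
    return DTWResult(
        total_cost=total,
        normalized_cost=total / (n + m),
        path=path,
        linearity_r2=path_linearity(path),
    )


def _backtrack(D: np.ndarray, d: np.ndarray) -> WarpPath:
    # lowest-cost predecessor; diagonal preferred, then the i-decrement
    i, j = D.shape[0] - 1, D.shape[1] - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            dij = d[i, j]
            cands = (
                (D[i - 1, j - 1] + 2.0 * dij, i - 1, j - 1),
                (D[i - 1, j] + dij, i - 1, j),
                (D[i, j - 1] + dij, i, j - 1),
            )
            best = min(c[0] for c in cands)
            for cost, pi, pj in cands:
                if cost <= best:
                    i, j = pi, pj
                    break
        rev.append((i, j))
    return WarpPath(np.array(rev[::-1], dtype=int))


def path_linearity(path: WarpPath) -> float:
    """R-squared of the path against the straight corner-to-corner line.

    The j-coordinates of the path points are compared with the line from
    (0, 0) to (n-1, m-1) evaluated at the path's i-coordinates; the result
    is clamped to [0, 1].  A perfect diagonal gives 1; an L-shaped path
    (all of one series first) scores low.  Single-point or zero-variance
    paths return 1 by convention.
    """
    p = path.pairs
    if len(path) < 2:
        return 1.0
    i = p[:, 0].astype(float)
    j = p[:, 1].astype(float)
    n1, m1 = float(p[-1, 0]), float(p[-1, 1])
    pred = j * 0.0 if n1 == 0 else i * (m1 / n1) if n1 > 0 else j
    ss_res = float(np.sum((j - pred) ** 2))
    ss_tot = float(np.sum((j - j.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean decimation; the trailing partial block is averaged as-is."""
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    x = np.asarray(x, dtype=float).ravel()
    if factor == 1:
        return x.copy()
    n_full = x.size // factor
    out = []
    if n_full:
        out.append(x[: n_full * factor].reshape(n_full, factor).mean(axis=1))
    if x.size % factor:
        out.append([x[n_full * factor :].mean()])
    return np.concatenate(out) if len(out) > 1 else out[0]
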