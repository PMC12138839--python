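"""Dynamic time warping for short univariate series.

Two alignment families are provided:

* :func:`dtw_undirected` -- the classic symmetric alignment with the
  "symmetric2" step pattern (diagonal steps weighted 2, horizontal and
  vertical steps weighted 1) restricted to a Sakoe-Chiba band
  ``|i - j| <= window`` around the diagonal.  The cumulative cost is
  normalised by ``N + M`` so that a perfectly diagonal alignment of
  equal-length series equals the mean absolute difference.

* :func:`dtw_directed` -- a forward-only alignment in which every point
  ``i`` of ``x`` is matched to exactly one point ``j(i)`` of ``y`` with
  ``j(i) in {i, ..., i + max_lag}`` (lag-0 or lag-1 for the default
  ``max_lag=1``), ``j`` non-decreasing and advancing at most two target
  points per step.  A small distance means changes in ``x`` align with
  same-time or *later* values of ``y``, i.e. ``x`` temporally leads ``y``.
  Normalised by ``N``.

:func:`oracle_min_cost` recomputes either distance by exhaustive
enumeration of every admissible path/mapping; it exists purely as an
independent reference for the dynamic programs and is guarded to short
series.

Missing values are a hard error at this layer: alignment is only ever run
on complete (imputed) replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WarpResult",
    "local_cost_matrix",
    "dtw_undirected",
    "dtw_directed",
    "dtw_undirected_batch",
    "dtw_directed_batch",
    "oracle_min_cost",
]

_ORACLE_MAX_LEN = 8


@dataclass(frozen=True)
class WarpResult:
    """Outcome of a single pairwise alignment.

    Attributes
    ----------
    distance : float
        Normalised cumulative cost (raw cost / ``normalization_constant``).
    path : tuple[tuple[int, int], ...]
        Alignment as 0-based ``(i, j)`` index pairs, non-decreasing in both
        coordinates.
    normalization_constant : float
        ``N + M`` for the undirected pattern, ``N`` for the directed one.
    """

    distance: float
    path: tuple[tuple[int, int], ...]
    normalization_constant: float


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


def local_cost_matrix(x, y) -> np.ndarray:
    """Pointwise cost ``c[i, j] = |x[i] - y[j]|`` for complete series."""
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    return np.abs(xa[:, None] - ya[None, :])


def dtw_undirected(x, y, window: int = 1) -> WarpResult:
    """Banded DTW distance with the symmetric2 step pattern.

    The recursion is ``g(0,0) = 2 c(0,0)``;
    ``g(i,j) = min(g(i-1,j-1) + 2 c(i,j), g(i-1,j) + c(i,j),
    g(i,j-1) + c(i,j))`` over cells with ``|i - j| <= window``, and the
    distance is ``g(N-1, M-1) / (N + M)``.

    Parameters
    ----------
    x, y : array-like
        Complete univariate series, lengths ``N, M >= 2``.
    window : int
        Sakoe-Chiba band half-width; requires ``|N - M| <= window`` or no
        monotone path reaches the terminal cell.
    """
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    n, m = xa.size, ya.size
    if n < 2 or m < 2:
        raise ValueError("series must have at least 2 points")
    if window < 0:
        raise ValueError("window must be nonnegative")
    if abs(n - m) > window:
        raise ValueError(
            f"no admissible path: |N - M| = {abs(n - m)} exceeds window {window}"
        )
    c = np.abs(xa[:, None] - ya[None, :])
    g = np.full((n, m), np.inf)
    # step id for backtracking: 0 = diagonal, 1 = vertical (i-1), 2 = horizontal (j-1)
    step = np.full((n, m), -1, dtype=np.int8)
    g[0, 0] = 2.0 * c[0, 0]
    for i in range(n):
        jlo = max(0, i - window)
        jhi = min(m - 1, i + window)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            cand = (
                (g[i - 1, j - 1] + 2.0 * c[i, j]) if i > 0 and j > 0 else np.inf,
                (g[i - 1, j] + c[i, j]) if i > 0 else np.inf,
                (g[i, j - 1] + c[i, j]) if j > 0 else np.inf,
            )
            # ties broken toward the diagonal step (affects the path only)
            best = int(np.argmin(cand))
            g[i, j] = cand[best]
            step[i, j] = best
    total = g[n - 1, m - 1]
    if not np.isfinite(total):
        raise ValueError("no admissible path under the band constraint")
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        s = step[i, j]
        if s == 0:
            i, j = i - 1, j - 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    norm = float(n + m)
    return WarpResult(float(total) / norm, tuple(reversed(path)), norm)


def dtw_directed(x, y, max_lag: int = 1) -> WarpResult:
    """Forward-only DTW distance (temporal-lead alignment of ``x`` into ``y``).

    Every index ``i`` of ``x`` is matched to one index ``j(i)`` of ``y``
    with ``j(i)`` in ``{i, ..., i + max_lag}`` clipped to the series,
    ``j`` non-decreasing and ``j(i) - j(i-1) <= 2``.  The distance is the
    minimal ``sum_i c(i, j(i)) / N`` over admissible mappings.
    """
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    if xa.size != ya.size:
        raise ValueError("directed DTW requires equal-length series")
    n = xa.size
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if max_lag < 1:
        raise ValueError("max_lag must be a positive integer")
    c = np.abs(xa[:, None] - ya[None, :])
    g = np.full((n, n), np.inf)
    prev = np.full((n, n), -1, dtype=np.int64)
    for j in range(0, min(max_lag, n - 1) + 1):
        g[0, j] = c[0, j]
    for i in range(1, n):
        for j in range(i, min(i + max_lag, n - 1) + 1):
            lo = max(i - 1, j - 2)
            hi = min(j, (i - 1) + max_lag, n - 1)
            if lo > hi:
                continue
            # prefer the smallest admissible predecessor advance on ties
            # (keeps the mapping as diagonal as possible)
            best_jp, best_val = -1, np.inf
            for jp in range(hi, lo - 1, -1):
                if g[i - 1, jp] <= best_val:
                    best_val = g[i - 1, jp]
                    best_jp = jp
            g[i, j] = best_val + c[i, j]
            prev[i, j] = best_jp
    total = g[n - 1, n - 1]
    if not np.isfinite(total):
        raise ValueError("no admissible mapping")
    mapping = [n - 1]
    for i in range(n - 1, 0, -1):
        mapping.append(int(prev[i, mapping[-1]]))
    mapping.reverse()
    path = tuple((i, j) for i, j in enumerate(mapping))
    return WarpResult(float(total) / n, path, float(n))


def dtw_undirected_batch(x: np.ndarray, y: np.ndarray, window: int = 1) -> np.ndarray:
    """Vectorised :func:`dtw_undirected` distances for stacked series.

    ``x`` has shape ``(S, N)`` and ``y`` shape ``(S, M)``; returns the
    ``(S,)`` array of distances.  Row ``s`` of ``x`` is aligned with row
    ``s`` of ``y``.  Identical recursion and normalisation as the scalar
    routine (paths are not materialised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("expected (S, N) and (S, M) arrays with matching S")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values")
    s, n = x.shape
    m = y.shape[1]
    if n < 2 or m < 2:
        raise ValueError("series must have at least 2 points")
    if abs(n - m) > window:
        raise ValueError("no admissible path: |N - M| exceeds window")
    c = np.abs(x[:, :, None] - y[:, None, :])
    g = np.full((s, n, m), np.inf)
    g[:, 0, 0] = 2.0 * c[:, 0, 0]
    for i in range(n):
        jlo = max(0, i - window)
        jhi = min(m - 1, i + window)
        for j in range(jlo, jhi + 1):
            if i == 0 and j == 0:
                continue
            best = np.full(s, np.inf)
            if i > 0 and j > 0:
                best = g[:, i - 1, j - 1] + 2.0 * c[:, i, j]
            if i > 0:
                best = np.minimum(best, g[:, i - 1, j] + c[:, i, j])
            if j > 0:
                best = np.minimum(best, g[:, i, j - 1] + c[:, i, j])
            g[:, i, j] = best
    return g[:, n - 1, m - 1] / (n + m)


def dtw_directed_batch(x: np.ndarray, y: np.ndarray, max_lag: int = 1) -> np.ndarray:
    """Vectorised :func:`dtw_directed` distances for stacked equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("expected two (S, N) arrays of identical shape")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values")
    s, n = x.shape
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if max_lag < 1:
        raise ValueError("max_lag must be a positive integer")
    c = np.abs(x[:, :, None] - y[:, None, :])
    g = np.full((s, n, n), np.inf)
    for j in range(0, min(max_lag, n - 1) + 1):
        g[:, 0, j] = c[:, 0, j]
    for i in range(1, n):
        for j in range(i, min(i + max_lag, n - 1) + 1):
            lo = max(i - 1, j - 2)
            hi = min(j, (i - 1) + max_lag, n - 1)
            if lo > hi:
                continue
            g[:, i, j] = g[:, i - 1, lo:hi + 1].min(axis=1) + c[:, i, j]
    return g[:, n - 1, n - 1] / n


def oracle_min_cost(x, y, pattern: str, window: int = 1, max_lag: int = 1) -> float:
    """Brute-force minimal normalised cost over every admissible alignment.

    Exhaustively enumerates all banded monotone paths (``pattern
    = "undirected"``) or all forward-only mappings (``pattern =
    "directed"``); intended only as a test reference for the dynamic
    programs, hence the hard length guard.
    """
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    n, m = xa.size, ya.size
    if n > _ORACLE_MAX_LEN or m > _ORACLE_MAX_LEN:
        raise ValueError(f"oracle limited to series of length <= {_ORACLE_MAX_LEN}")
    c = np.abs(xa[:, None] - ya[None, :])

    if pattern == "undirected":
        if abs(n - m) > window:
            raise ValueError("no admissible path: |N - M| exceeds window")
        best = np.inf

        def walk(i: int, j: int, acc: float) -> None:
            nonlocal best
            if acc >= best:
                return
            if i == n - 1 and j == m - 1:
                best = acc
                return
            for di, dj, w in ((1, 1, 2.0), (1, 0, 1.0), (0, 1, 1.0)):
                ni, nj = i + di, j + dj
                if ni < n and nj < m and abs(ni - nj) <= window:
                    walk(ni, nj, acc + w * c[ni, nj])

        walk(0, 0, 2.0 * c[0, 0])
        if not np.isfinite(best):
            raise ValueError("no admissible path under the band constraint")
        return float(best) / (n + m)

    if pattern == "directed":
        if n != m:
            raise ValueError("directed pattern requires equal lengths")
        if max_lag < 1:
            raise ValueError("max_lag must be a positive integer")
        best = np.inf

        def extend(i: int, j_prev: int, acc: float) -> None:
            nonlocal best
            if acc >= best:
                return
            if i == n:
                best = acc
                return
            for j in range(i, min(i + max_lag, n - 1) + 1):
                if j_prev <= j <= j_prev + 2:
                    extend(i + 1, j, acc + c[i, j])

        for j0 in range(0, min(max_lag, n - 1) + 1):
            extend(1, j0, c[0, j0])
        if not np.isfinite(best):
            raise ValueError("no admissible mapping")
        return float(best) / n

    raise ValueError(f"unknown pattern {pattern!r}")
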