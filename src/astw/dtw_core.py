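"""Banded dynamic time warping between equal-length sequences.

DTW is used here as a *similarity feature*: for each analysis window, the
DTW distance (with a squared-difference local cost, accumulated as a plain
sum along the optimal path) is computed between every unordered pair of
channels, separately within each derivative order (raw signal, first
difference, second difference).  With ``Nc`` channels this yields a feature
vector of length ``3 * Nc * (Nc - 1) / 2`` per window.

The warping path starts at (1,1), ends at (l,l), advances each index by 0
or 1 per step (never both by 0), and is confined to a Sakoe-Chiba band
``|e_i - f_i| <= w * l`` where ``w`` is a fraction of the sequence length.
The diagonal is always inside the band, so a valid path always exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ContractError

_BAND_EPS = 1e-9


@dataclass(frozen=True)
class DtwConfig:
    """Band fraction ``band`` in (0, 1]: maximum |e - f| as a fraction of l.

    The local cost is fixed to the squared difference.  ``band=1.0`` leaves
    the path unconstrained within the equal-length cost matrix; ``band=0``
    degenerates to the diagonal (squared Euclidean) path.
    """

    band: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.band <= 1.0):
            raise ContractError("band fraction must lie in [0, 1]")


def distance_matrix(s: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Local-cost matrix ``D[i, j] = (s_i - u_j)**2`` for equal-length s, u."""
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.ndim != 1 or u.ndim != 1:
        raise ContractError("sequences must be 1-D")
    if s.shape != u.shape:
        raise ContractError("sequences must have equal length")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(u))):
        raise ContractError("sequences must be finite")
    return (s[:, None] - u[None, :]) ** 2


@njit(cache=False)
def _dtw_kernel(s, u, band_abs):  # pragma: no cover - exercised via dtw_distance
    l = s.shape[0]
    INF = np.inf
    dp = np.full((l, l), INF)
    for i in range(l):
        lo = i - band_abs
        hi = i + band_abs
        for j in range(l):
            if j < lo - _BAND_EPS or j > hi + _BAND_EPS:
                continue
            c = (s[i] - u[j]) ** 2
            if i == 0 and j == 0:
                dp[0, 0] = c
                continue
            best = INF
            if i > 0 and dp[i - 1, j] < best:
                best = dp[i - 1, j]
            if j > 0 and dp[i, j - 1] < best:
                best = dp[i, j - 1]
            if i > 0 and j > 0 and dp[i - 1, j - 1] < best:
                best = dp[i - 1, j - 1]
            dp[i, j] = c + best
    return dp[l - 1, l - 1]


def _check_pair(s, u):
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.ndim != 1 or u.ndim != 1 or s.shape != u.shape:
        raise ContractError("DTW requires two 1-D sequences of equal length")
    if s.size < 1:
        raise ContractError("sequences must contain at least one sample")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(u))):
        raise ContractError("sequences must be finite")
    return s, u


def dtw_distance(
    s: np.ndarray,
    u: np.ndarray,
    config: DtwConfig | None = None,
    return_path: bool = False,
):
    """Minimum banded warping cost between two equal-length sequences.

    Returns the accumulated squared-difference cost along the optimal path;
    with ``return_path=True`` also returns the path as an array of 1-based
    ``(e, f)`` index pairs.
    """
    config = config or DtwConfig()
    s, u = _check_pair(s, u)
    band_abs = config.band * s.size
    if not return_path:
        return float(_dtw_kernel(s, u, band_abs))
    dist, path = _dtw_with_path(s, u, band_abs)
    return dist, path


def _dtw_with_path(s, u, band_abs):
    l = s.size
    D = (s[:, None] - u[None, :]) ** 2
    valid = np.abs(np.subtract.outer(np.arange(l), np.arange(l))) <= band_abs + _BAND_EPS
    dp = np.full((l, l), np.inf)
    dp[0, 0] = D[0, 0]
    for i in range(l):
        for j in range(l):
            if (i == 0 and j == 0) or not valid[i, j]:
                continue
            best = np.inf
            if i > 0:
                best = min(best, dp[i - 1, j])
            if j > 0:
                best = min(best, dp[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, dp[i - 1, j - 1])
            dp[i, j] = D[i, j] + best
    # backtrack from (l-1, l-1) preferring the diagonal predecessor
    path = [(l, l)]
    i = j = l - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((dp[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((dp[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((dp[i, j - 1], i, j - 1))
        _, i, j = min(cands, key=lambda c: c[0])
        path.append((i + 1, j + 1))
    path.reverse()
    return float(dp[l - 1, l - 1]), np.array(path, dtype=int)


def is_valid_path(path: np.ndarray, l: int, band: float) -> bool:
    """Check the warping-path conditions for 1-based index pairs."""
    path = np.asarray(path, dtype=int)
    if path.ndim != 2 or path.shape[1] != 2:
        return False
    if tuple(path[0]) != (1, 1) or tuple(path[-1]) != (l, l):
        return False
    de = np.diff(path[:, 0])
    df = np.diff(path[:, 1])
    if np.any((de < 0) | (de > 1) | (df < 0) | (df > 1)):
        return False
    if np.any((de == 0) & (df == 0)):
        return False
    return bool(np.all(np.abs(path[:, 0] - path[:, 1]) <= band * l + _BAND_EPS))


def feature_length(nc: int) -> int:
    """Spatial feature dimension ``3 * C(nc, 2)`` for ``nc`` channels."""
    return 3 * nc * (nc - 1) // 2


def pairwise_dtw_features(stack, config: DtwConfig | None = None) -> np.ndarray:
    """DTW similarity features for every channel pair within each derivative order.

    ``stack`` is a :class:`~astw.io_preprocess.ChannelStack`.  The output is
    ordered as three blocks (raw, first difference, second difference); within
    each block, channel pairs (i, j), i < j, in lexicographic index order.
    All entries are nonnegative.
    """
    config = config or DtwConfig()
    nc = stack.nc
    if nc < 2:
        raise ContractError("pairwise DTW features need at least 2 channels")
    out = np.empty(feature_length(nc))
    pos = 0
    for X in stack.orders():
        X = np.ascontiguousarray(X, dtype=float)
        l = X.shape[0]
        band_abs = config.band * l
        for i in range(nc):
            si = X[:, i].copy()
            for j in range(i + 1, nc):
                out[pos] = _dtw_kernel(si, X[:, j].copy(), band_abs)
                pos += 1
    return out
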