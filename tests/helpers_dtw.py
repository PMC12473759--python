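"""Independent brute-force oracle for banded DTW: explicit path enumeration.

Enumerates every valid warping path (DFS over the 0/1-increment step
pattern within the band) and takes the minimum summed squared-difference
cost.  Exponential, usable only for short sequences; deliberately shares no
code with the dynamic-programming implementation it checks.
"""

from functools import lru_cache

import numpy as np

_EPS = 1e-9


@lru_cache(maxsize=None)
def enumerate_paths(l: int, band_fraction: float):
    """All valid 0-based warping paths for length ``l`` within the band."""
    limit = band_fraction * l + _EPS
    paths = []

    def dfs(i, j, acc):
        if abs(i - j) > limit:
            return
        if i == l - 1 and j == l - 1:
            paths.append(acc + [(i, j)])
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < l and nj < l:
                dfs(ni, nj, acc + [(i, j)])

    dfs(0, 0, [])
    return [np.array(p, dtype=int) for p in paths]


def oracle_dtw(s, u, band_fraction: float) -> float:
    """Minimum path cost by exhaustive enumeration."""
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    l = s.size
    if l == 1:
        return float((s[0] - u[0]) ** 2)
    D = (s[:, None] - u[None, :]) ** 2
    best = np.inf
    for p in enumerate_paths(l, band_fraction):
        cost = D[p[:, 0], p[:, 1]].sum()
        if cost < best:
            best = cost
    return float(best)
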