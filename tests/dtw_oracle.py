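"""Independent DTW oracle: exhaustive enumeration of all warping paths.

Enumerates every monotone alignment path from (0, 0) to (n-1, m-1) using the
unit step pattern {(1,0), (0,1), (1,1)} and takes the minimum summed
absolute-difference cost.  Exponential in sequence length, so only usable
for short sequences -- which is the point: it shares no code path with the
dynamic-programming implementation it checks.

Paths depend only on the (n, m) shape, so they are enumerated once per shape
(as flat indices into the cost matrix, padded with a zero-cost sentinel) and
the per-pair evaluation is a vectorised gather + sum + min.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def _paths_for_shape(n: int, m: int) -> np.ndarray:
    """(n_paths, max_len) flat indices into an (n*m + 1)-element cost vector;
    the final element is the zero-cost padding sentinel."""
    sentinel = n * m
    paths: list[list[int]] = []

    def walk(i: int, j: int, trail: list[int]) -> None:
        trail = trail + [i * m + j]
        if i == n - 1 and j == m - 1:
            paths.append(trail)
            return
        if i + 1 < n:
            walk(i + 1, j, trail)
        if j + 1 < m:
            walk(i, j + 1, trail)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, trail)

    walk(0, 0, [])
    max_len = max(len(p) for p in paths)
    out = np.full((len(paths), max_len), sentinel, dtype=np.int64)
    for k, p in enumerate(paths):
        out[k, : len(p)] = p
    return out


def dtw_bruteforce(x, y) -> float:
    """Minimum warping cost by exhaustive path enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cost = np.abs(x[:, None] - y[None, :])
    flat = np.append(cost.ravel(), 0.0)  # sentinel pad
    paths = _paths_for_shape(len(x), len(y))
    return float(flat[paths].sum(axis=1).min())
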