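"""Independent test oracles, kept free of any gaitdtw internals."""

from __future__ import annotations

import math


def brute_force_dtw(x, y, kind: str = "squared") -> float:
    """Minimum accumulated cost over an exhaustive enumeration of all
    monotone warp paths from (0, 0) to (m-1, n-1).

    Exponential in m + n; only usable for tiny sequences. Deliberately
    recursive and cache-free so it shares nothing with the dynamic-programming
    implementation it checks.
    """
    m, n = len(x), len(y)

    def cost(i: int, j: int) -> float:
        d = x[i] - y[j]
        return d * d if kind == "squared" else abs(d)

    best = math.inf

    def walk(i: int, j: int, acc: float) -> None:
        nonlocal best
        if i == m - 1 and j == n - 1:
            best = min(best, acc)
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, acc + cost(i + 1, j + 1))
        if i + 1 < m:
            walk(i + 1, j, acc + cost(i + 1, j))
        if j + 1 < n:
            walk(i, j + 1, acc + cost(i, j + 1))

    walk(0, 0, cost(0, 0))
    return best
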