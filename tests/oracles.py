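"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid every code path of the package's own distance and
search engines: plain full-matrix dynamic programming, and exhaustive scans.
"""

from __future__ import annotations


def dp_levenshtein(a: str, b: str) -> int:
    """Naive full-matrix unit-cost Levenshtein distance."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[n][m]


def brute_force_min_candidates(query: str, names: list[str], allowed: int):
    """All names achieving the minimal distance to query, among those within
    the allowance. Returns (min_distance, set_of_names); (None, empty) when
    nothing is within the allowance."""
    dists = {name: dp_levenshtein(query, name) for name in names}
    within = {n: d for n, d in dists.items() if d <= allowed}
    if not within:
        return None, set()
    dmin = min(within.values())
    return dmin, {n for n, d in within.items() if d == dmin}
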