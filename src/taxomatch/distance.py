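"""Edit-distance kernels and the fractional distance bound used to gate fuzzy matches.

Two kernels are provided:

``levenshtein``
    The classic unit-cost edit distance: single-character substitutions,
    insertions, and deletions each contribute 1. This is the distance that
    gates fuzzy candidate search and that is reported as ``Fuzzy.dist``.

``modified_dl``
    A Damerau–Levenshtein variant in the spirit of Taxamatch in which
    transposing two adjacent blocks of characters is a single weighted
    operation costing half the total block length. Swapping ``"cusi"`` and
    ``"sicu"`` inside *vecusilosus* / *vesiculosus* therefore costs 2 where
    plain character substitution would cost 4, and an adjacent
    single-character swap (``"ab"`` -> ``"ba"``) costs 1.

Distances operate on Unicode code points and are case-sensitive; any case
folding happens upstream during name cleaning. The hybrid sign ``×`` is an
ordinary character.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

__all__ = [
    "levenshtein",
    "bounded_levenshtein",
    "modified_dl",
    "DistanceBound",
    "within_bound",
]

# edlib refuses inputs whose joint alphabet exceeds 256 distinct symbols; taxon
# names never get close, but the pure-Python DP below keeps us total anyway.
_EDLIB_ALPHABET_LIMIT = 256


def _dp_levenshtein(a: str, b: str, k: int | None = None) -> int | None:
    """Two-row dynamic-programming Levenshtein; returns None if > k."""
    if len(a) < len(b):
        a, b = b, a
    if k is not None and len(a) - len(b) > k:
        return None
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
        if k is not None and min(prev) > k:
            return None
    return prev[-1] if (k is None or prev[-1] <= k) else None


def _alphabet_ok(a: str, b: str) -> bool:
    return len(set(a) | set(b)) <= _EDLIB_ALPHABET_LIMIT


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two strings.

    Symmetric; ``levenshtein(a, "") == len(a)``. Computed with edlib when the
    joint alphabet allows it, otherwise with a plain DP.
    """
    if a == b:
        return 0
    if _alphabet_ok(a, b):
        return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return _dp_levenshtein(a, b)  # type: ignore[return-value]


def bounded_levenshtein(a: str, b: str, k: int) -> int | None:
    """Levenshtein distance if it is <= k, else None.

    The bound lets the search engine abandon hopeless candidates early, which
    is what makes scanning a whole backbone per query affordable.
    """
    if abs(len(a) - len(b)) > k:
        return None
    if a == b:
        return 0
    if _alphabet_ok(a, b):
        d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
        return None if d < 0 else d
    return _dp_levenshtein(a, b, k=k)


def modified_dl(a: str, b: str) -> float:
    """Modified Damerau–Levenshtein distance with half-weight block transpositions.

    Extends the unit-cost edit operations with one extra move: if a prefix of
    ``a`` ends in blocks ``X Y`` and the corresponding prefix of ``b`` ends in
    ``Y X``, the exchange is a single operation costing ``(|X| + |Y|) / 2``.
    Hence ``modified_dl(a, b) <= levenshtein(a, b)`` always, with equality
    whenever no transposition helps, and an adjacent character swap costs 1.

    Costs are half-integral; the return value is a float.
    """
    n, m = len(a), len(b)
    if a == b:
        return 0.0
    # suffix[i][j] = length of the longest common suffix of a[:i] and b[:j];
    # it bounds the block lengths that can participate in a transposition
    # ending at (i, j), so the quadratic block search only fires where
    # characters actually repeat.
    suffix = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = suffix[i]
        prev = suffix[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                row[j] = prev[j - 1] + 1
    # DP over doubled costs to stay in integers (transposition cost p+q).
    INF = 10 ** 9
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = 2 * i
    for j in range(m + 1):
        d[0][j] = 2 * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(
                d[i - 1][j] + 2,
                d[i][j - 1] + 2,
                d[i - 1][j - 1] + (0 if a[i - 1] == b[j - 1] else 2),
            )
            # transposition: a[:i] ends with X+Y, b[:j] ends with Y+X,
            # |X| = p, |Y| = q; validity reduces to suffix-table lookups:
            #   Y = a[i-q:i] == b[j-p-q:j-p]  <=>  q <= suffix[i][j-p]
            #   X = a[i-p-q:i-q] == b[j-p:j]  <=>  p <= suffix[i-q][j]
            for p in range(1, j):
                qmax = suffix[i][j - p]
                if qmax == 0:
                    continue
                for q in range(1, qmax + 1):
                    if p <= suffix[i - q][j]:
                        cand = d[i - p - q][j - p - q] + p + q
                        if cand < best:
                            best = cand
            d[i][j] = best
    return d[n][m] / 2.0


@dataclass(frozen=True)
class DistanceBound:
    """Maximum edit distance allowed for a fuzzy candidate.

    With ``interpretation="fraction"`` the allowance scales with the pattern:
    ``ceiling(max_distance * len(pattern))`` edits, mirroring agrep's
    fraction-of-pattern-length semantics (default 0.1). With ``"absolute"``
    the allowance is the integer ``max_distance`` itself.
    """

    max_distance: float = 0.1
    interpretation: str = "fraction"

    def __post_init__(self) -> None:
        if self.interpretation not in ("fraction", "absolute"):
            raise ValueError(f"unknown interpretation: {self.interpretation!r}")
        if self.interpretation == "fraction":
            if not (0 <= self.max_distance < 1):
                raise ValueError("fractional max_distance must be in [0, 1)")
        else:
            if self.max_distance < 0 or self.max_distance != int(self.max_distance):
                raise ValueError("absolute max_distance must be a non-negative integer")

    def allowed(self, pattern: str) -> int:
        """Integer edit allowance for this pattern."""
        if self.interpretation == "absolute":
            return int(self.max_distance)
        # Guard against binary-float artifacts: 0.1 * 20 == 2.0000000000000004,
        # which must allow 2 edits, not 3.
        return max(0, math.ceil(self.max_distance * len(pattern) - 1e-9))


def within_bound(pattern: str, candidate: str, bound: DistanceBound) -> bool:
    """True if candidate lies within the edit allowance derived from pattern."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    return bounded_levenshtein(pattern, candidate, bound.allowed(pattern)) is not None
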