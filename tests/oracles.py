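"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's dynamic-programming formulation:
the edit-distance oracle is a top-down exhaustive search over edit
scripts on aligned suffixes (memoized — memoization does not change which
scripts are considered), and the gram oracle counts shared gram
instances by literal list matching.
"""

from __future__ import annotations


def script_search_distance(a: str, b: str, block_limit: int) -> int:
    """Minimum edit-script cost from ``a`` to ``b`` by exhaustive search.

    Operations: delete, insert, substitute (cost 1) and swap of two
    adjacent equal-length blocks of up to ``block_limit`` characters
    (cost = block length).
    """
    memo: dict[tuple[int, int], int] = {}
    la, lb = len(a), len(b)

    def go(i: int, j: int) -> int:
        if i == la:
            return lb - j
        if j == lb:
            return la - i
        key = (i, j)
        hit = memo.get(key)
        if hit is not None:
            return hit
        best = min(
            go(i + 1, j) + 1,
            go(i, j + 1) + 1,
            go(i + 1, j + 1) + (a[i] != b[j]),
        )
        for blk in range(1, block_limit + 1):
            if i + 2 * blk <= la and j + 2 * blk <= lb:
                if (
                    a[i : i + blk] == b[j + blk : j + 2 * blk]
                    and a[i + blk : i + 2 * blk] == b[j : j + blk]
                ):
                    best = min(best, go(i + 2 * blk, j + 2 * blk) + blk)
        memo[key] = best
        return best

    return go(0, 0)


def literal_grams(s: str, n: int, padded: bool) -> list[str]:
    text = s.upper()
    if padded:
        text = " " * (n - 1) + text + " " * (n - 1)
    return [text[i : i + n] for i in range(len(text) - n + 1)]


def shared_gram_count(a: str, b: str, n: int, padded: bool) -> int:
    """Count shared gram instances by literal cross-off matching."""
    ga = literal_grams(a, n, padded)
    gb = literal_grams(b, n, padded)
    shared = 0
    for g in ga:
        if g in gb:
            gb.remove(g)
            shared += 1
    return shared


def oracle_ngram_similarity(a: str, b: str, n: int, padded: bool) -> float:
    ga = literal_grams(a, n, padded)
    gb = literal_grams(b, n, padded)
    if not ga and not gb:
        return 1.0
    return shared_gram_count(a, b, n, padded) / ((len(ga) + len(gb)) / 2)
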