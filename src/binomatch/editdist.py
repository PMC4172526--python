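"""Edit distances with multi-character block transpositions.

``edit_distance`` computes, depending on ``block_limit``:

* 0 — plain Levenshtein distance (insert/delete/substitute, unit cost);
* 1 — optimal-string-alignment Damerau-Levenshtein (adds adjacent
  single-character transposition at cost 1);
* k >= 2 — the block-transposition extension: two adjacent equal-length
  blocks of up to k characters swapped between the strings cost the block
  length instead of twice that.

An optional ``max_distance`` allows early abandon: when every cell of a
dynamic-programming row exceeds it, the distinct sentinel :data:`EXCEEDS`
is returned instead of a (clamped) number.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parse import NormalizedWord

__all__ = [
    "EditParams",
    "EXCEEDS",
    "edit_distance",
    "ed1_operation_count",
    "ed1_neighborhood",
]


class _Exceeds:
    """Sentinel: distance is unknown but greater than ``max_distance``."""

    __slots__ = ()

    def __repr__(self) -> str:
        return "EXCEEDS"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("EXCEEDS has no truth value; test identity instead")


EXCEEDS = _Exceeds()

GENUS_BLOCK_LIMIT = 2
SPECIES_BLOCK_LIMIT = 4


@dataclass(frozen=True)
class EditParams:
    block_limit: int = 1
    max_distance: int | None = None

    def __post_init__(self) -> None:
        if self.block_limit < 0:
            raise ValueError("block_limit must be >= 0")
        if self.max_distance is not None and self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")


def _text(w: str | NormalizedWord) -> str:
    return w.text if isinstance(w, NormalizedWord) else w


def edit_distance(
    a: str | NormalizedWord,
    b: str | NormalizedWord,
    params: EditParams | None = None,
    *,
    block_limit: int | None = None,
    max_distance: int | None = None,
) -> int | _Exceeds:
    """Minimum-cost transformation of ``a`` into ``b``.

    Accepts either an :class:`EditParams` or the two keyword shortcuts.
    """
    if params is None:
        params = EditParams(
            block_limit=1 if block_limit is None else block_limit,
            max_distance=max_distance,
        )
    s, t = _text(a), _text(b)
    if s == t:
        return 0
    la, lb = len(s), len(t)
    limit = params.max_distance
    if limit is not None and abs(la - lb) > limit:
        return EXCEEDS

    bl = params.block_limit
    prev_rows: list[list[int]] = [list(range(lb + 1))]
    for i in range(1, la + 1):
        row = [i] + [0] * lb
        ca = s[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == t[j - 1] else 1
            best = min(
                prev_rows[-1][j] + 1,       # deletion
                row[j - 1] + 1,             # insertion
                prev_rows[-1][j - 1] + cost,  # substitution / match
            )
            for blk in range(1, bl + 1):
                if i < 2 * blk or j < 2 * blk:
                    break
                if (
                    s[i - 2 * blk : i - blk] == t[j - blk : j]
                    and s[i - blk : i] == t[j - 2 * blk : j - blk]
                ):
                    cand = prev_rows[-2 * blk][j - 2 * blk] + blk
                    if cand < best:
                        best = cand
            row[j] = best
        prev_rows.append(row)
        # keep only the rows still reachable by the largest block move
        if len(prev_rows) > 2 * bl + 1:
            prev_rows.pop(0)
        if limit is not None and min(row) > limit:
            return EXCEEDS
    d = prev_rows[-1][lb]
    if limit is not None and d > limit:
        return EXCEEDS
    return d


def ed1_operation_count(length: int, alphabet_size: int = 26) -> int:
    """Number of single-edit operations available on a word of ``length``.

    Counts (length+1)*A insertions, length deletions, length*(A-1)
    substitutions and length-1 adjacent transpositions.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return (
        (length + 1) * alphabet_size
        + length
        + length * (alphabet_size - 1)
        + (length - 1)
    )


def ed1_neighborhood(word: str | NormalizedWord, alphabet: str | None = None) -> set[str]:
    """Distinct strings producible from ``word`` by exactly one edit.

    Edits are insertion, deletion, substitution to a *different* letter,
    or adjacent transposition.
    """
    w = _text(word)
    if not w:
        raise ValueError("word must be non-empty")
    letters = alphabet if alphabet is not None else "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out: set[str] = set()
    n = len(w)
    for i in range(n + 1):
        for c in letters:
            out.add(w[:i] + c + w[i:])
    for i in range(n):
        out.add(w[:i] + w[i + 1 :])
        for c in letters:
            if c != w[i]:
                out.add(w[:i] + c + w[i + 1 :])
    for i in range(n - 1):
        out.add(w[:i] + w[i + 1] + w[i] + w[i + 2 :])
    return out
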