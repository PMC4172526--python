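"""Padded/unpadded n-gram multiset similarity.

Similarity is the number of shared gram *instances* (multiset
intersection) divided by the arithmetic mean of the two gram counts.
Padding appends n-1 space characters at each end of a string before
windowing, which evens out the weight of terminal characters.  Strings
are case-folded but punctuation and internal spaces are retained, which
is what authority comparison requires.
"""

from __future__ import annotations

from collections import Counter

__all__ = ["NgramProfile", "ngram_profile", "ngram_similarity", "blended_similarity"]


class NgramProfile:
    """The gram multiset of one string."""

    __slots__ = ("grams", "n", "padded")

    def __init__(self, grams: Counter, n: int, padded: bool):
        self.grams = grams
        self.n = n
        self.padded = padded

    @property
    def size(self) -> int:
        return sum(self.grams.values())


def ngram_profile(s: str, n: int, padded: bool) -> NgramProfile:
    if n < 2:
        raise ValueError("n must be >= 2")
    if not s:
        raise ValueError("cannot profile an empty string")
    text = s.upper()
    if padded:
        pad = " " * (n - 1)
        text = pad + text + pad
    grams = Counter(text[i : i + n] for i in range(len(text) - n + 1))
    return NgramProfile(grams, n, padded)


def ngram_similarity(a: str, b: str, n: int, padded: bool) -> float:
    """Shared gram instances over the mean gram count, in [0, 1]."""
    pa = ngram_profile(a, n, padded)
    pb = ngram_profile(b, n, padded)
    shared = sum((pa.grams & pb.grams).values())
    mean = (pa.size + pb.size) / 2
    if mean == 0:
        # both strings shorter than n without padding: equal (empty) multisets
        return 1.0
    return shared / mean


def blended_similarity(a: str, b: str) -> float:
    """Two-thirds padded bigram plus one-third padded trigram similarity.

    The bigram part is insensitive to token order; the trigram part
    restores some order sensitivity.
    """
    return (2 / 3) * ngram_similarity(a, b, 2, padded=True) + (1 / 3) * ngram_similarity(
        a, b, 3, padded=True
    )
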