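"""Phonetic key encoders for latinized name words.

Two encoder generations are provided.  The older (2001) variant keeps the
initial character untouched and applies soundalike substitutions to the
remainder; the newer (2007) variant additionally rewrites selected leading
character groups *before* quarantining the initial character and, for
species epithets, normalizes latin gender endings so that -us/-a/-um
variants of the same stem collapse to one key.

Substitutions run in a single left-to-right pass, longest pattern first at
each cursor position, followed by one pass collapsing adjacent duplicate
letters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parse import NormalizedWord

__all__ = ["PhoneticKey", "rees2001_key", "rees2007_key", "phonetic_match"]

# Remainder substitutions (applied after the initial character), ordered
# longest-first so multi-character patterns win at each position.
_REMAINDER_SUBS = [
    ("AE", "I"),
    ("OE", "I"),
    ("IA", "A"),
    ("MC", "MAC"),
    ("SC", "S"),
    ("E", "I"),
    ("U", "I"),
    ("Y", "I"),
    ("O", "A"),
    ("K", "C"),
    ("Z", "S"),
    ("H", ""),
]

# Whole-word leading patterns for the 2007 variant; at most one applies.
_LEADING_SUBS = [
    ("AE", "E"), ("EA", "E"), ("OE", "E"),
    ("CN", "N"), ("GN", "N"), ("KN", "N"), ("MN", "N"),
    ("CT", "T"), ("PT", "T"),
    ("CZ", "C"),
    ("DJ", "J"),
    ("EU", "U"),
    ("PH", "F"),
    ("PS", "S"), ("TS", "S"),
    ("QU", "Q"),
    ("X", "Z"),
]

# Gender endings: a transformed epithet ending in one of these has its
# last two characters replaced by A.  (-IS covers original -is/-us/-ys/-es,
# -IM covers -um, -AS covers -as/-os, all via the remainder substitutions.)
_GENDER_ENDINGS = ("IS", "IM", "AS")


@dataclass(frozen=True)
class PhoneticKey:
    key: str
    source_version: int
    gender_normalized: bool = False


def _as_text(word: str | NormalizedWord) -> str:
    text = word.text if isinstance(word, NormalizedWord) else word
    if not text:
        raise ValueError("cannot encode an empty word")
    return text.upper()


def _substitute_remainder(remainder: str) -> str:
    out: list[str] = []
    i = 0
    n = len(remainder)
    while i < n:
        for pat, rep in _REMAINDER_SUBS:
            if remainder.startswith(pat, i):
                out.append(rep)
                i += len(pat)
                break
        else:
            out.append(remainder[i])
            i += 1
    return "".join(out)


def _collapse_doubles(s: str) -> str:
    out: list[str] = []
    for ch in s:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def rees2001_key(word: str | NormalizedWord) -> PhoneticKey:
    """Encode a word with the 2001 scheme (initial character untouched)."""
    text = _as_text(word)
    key = _collapse_doubles(text[0] + _substitute_remainder(text[1:]))
    return PhoneticKey(key=key, source_version=2001)


def rees2007_key(word: str | NormalizedWord, is_epithet: bool = False) -> PhoneticKey:
    """Encode a word with the 2007 scheme.

    Leading patterns rewrite the word start before the (possibly new)
    initial character is retained; the remainder then follows the 2001
    substitutions.  For epithets the gender rule replaces a trailing
    IS/IM/AS by A, skipped when the transformed word is shorter than 4
    characters so the stem is never emptied.
    """
    text = _as_text(word)
    for pat, rep in _LEADING_SUBS:
        if text.startswith(pat):
            text = rep + text[len(pat):]
            break
    key = _collapse_doubles(text[0] + _substitute_remainder(text[1:]))
    gender_applied = False
    if is_epithet and len(key) >= 4 and key.endswith(_GENDER_ENDINGS):
        key = _collapse_doubles(key[:-2] + "A")
        gender_applied = True
    return PhoneticKey(key=key, source_version=2007, gender_normalized=gender_applied)


def phonetic_match(a: str | NormalizedWord, b: str | NormalizedWord, is_epithet: bool = False) -> bool:
    """True iff the 2007 keys of the two words are equal."""
    return rees2007_key(a, is_epithet).key == rees2007_key(b, is_epithet).key
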