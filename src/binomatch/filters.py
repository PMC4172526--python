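"""Heuristic gatekeepers around the edit-distance tests.

The pre-filters are cheap blocking rules that decide which reference
names are worth the dynamic-programming distance computation; the
post-filters discard measured candidates that are too distant for their
word length or mismatch on leading characters.  All functions here are
pure functions of their arguments; rule constants are frozen defaults.

Genus pre-filter rules (any one suffices):
  1a  genus phonetic keys equal;
  1b  query epithet key occurs under the target genus and the genus
      length difference is at most 3;
  1c  genus length difference at most 2 and leading/trailing substrings
      match on a schedule depending on the shorter length.

Genus post-filter: distance below 4, phonetic matches auto-accepted,
otherwise at least 50% good characters and a leading-character match at
distance 2+.  Species rules mirror these with a combined-distance cap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parse import NormalizedWord
from .phonetics import PhoneticKey

__all__ = [
    "QueryContext",
    "genus_prefilter",
    "genus_postfilter",
    "species_prefilter",
    "species_postfilter",
]

GENUS_PREFILTER_MAX_LEN_DIFF = 2
GENUS_PREFILTER_EPITHET_LEN_DIFF = 3
SPECIES_PREFILTER_MAX_LEN_DIFF = 4
GENUS_MAX_ED = 3           # distance 4+ always discarded
SPECIES_MAX_COMBINED_ED = 4


@dataclass(frozen=True)
class QueryContext:
    """The normalized query words and their phonetic keys."""

    genus: NormalizedWord
    genus_key_2007: PhoneticKey
    epithet: NormalizedWord | None = None
    epithet_key_2007: PhoneticKey | None = None


def genus_prefilter(q: QueryContext, g) -> tuple[bool, str | None]:
    """Decide whether a reference genus is worth the distance test.

    ``g`` needs attributes ``name_norm`` (NormalizedWord), ``key_2007``
    (PhoneticKey) and ``epithet_key_set`` (set of key strings).  Returns
    (passed, rule_tag); the "1a" tag doubles as the genus phonetic flag
    downstream.
    """
    if q.genus_key_2007.key == g.key_2007.key:
        return True, "1a"
    len_diff = abs(q.genus.length - g.name_norm.length)
    if (
        q.epithet_key_2007 is not None
        and len_diff <= GENUS_PREFILTER_EPITHET_LEN_DIFF
        and q.epithet_key_2007.key in g.epithet_key_set
    ):
        return True, "1b"
    if len_diff <= GENUS_PREFILTER_MAX_LEN_DIFF:
        a, b = q.genus.text, g.name_norm.text
        m = min(len(a), len(b))
        if m < 5:
            ok = a[:1] == b[:1] or a[-1:] == b[-1:]
        elif m == 5:
            ok = a[:2] == b[:2] or a[-3:] == b[-3:]
        else:
            ok = a[:3] == b[:3] or a[-3:] == b[-3:]
        if ok:
            return True, "1c"
    return False, None


def genus_postfilter(
    ed: int,
    phonetic: bool,
    q_len: int,
    g_len: int,
    first_chars_equal: bool,
) -> bool:
    """Accept or discard a genus candidate with measured distance ``ed``."""
    if ed > GENUS_MAX_ED:                      # rule 3a
        return False
    if phonetic:                               # rule 3b
        return True
    m = min(q_len, g_len)                      # rule 3c: >=50% good characters
    max_ed = 1 if m <= 3 else (2 if m <= 5 else 3)
    if ed > max_ed:
        return False
    if ed >= 2 and not first_chars_equal:
        return False
    return True


def species_prefilter(q_epithet_len: int, target_epithet_len: int, parent_passed: bool) -> bool:
    """Rule 4a (child of a surviving genus) and 4b (length window)."""
    return parent_passed and abs(q_epithet_len - target_epithet_len) <= SPECIES_PREFILTER_MAX_LEN_DIFF


def species_postfilter(
    genus_ed: int,
    epithet_ed: int,
    epithet_phonetic: bool,
    m: int,
    first_char_equal: bool,
    first3_equal: bool,
) -> bool:
    """Accept or discard a species candidate.

    ``m`` is the shorter of the two epithet lengths.
    """
    if genus_ed + epithet_ed > SPECIES_MAX_COMBINED_ED:   # rule 6a
        return False
    if epithet_phonetic:                                  # rule 6b
        return True
    # rule 6c
    max_ed = 1 if m <= 3 else (2 if m <= 5 else (3 if m <= 7 else 4))
    if epithet_ed > max_ed:
        return False
    if epithet_ed in (2, 3) and not first_char_equal:
        return False
    if epithet_ed == 4 and not first3_equal:
        return False
    return True
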