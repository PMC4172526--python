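"""Parsing of raw scientific-name strings and word normalization.

A raw query string may carry markup residue, hybrid signs, rank markers,
uncertainty qualifiers, a parenthesized subgenus and an authority.  This
module atomizes such strings into a :class:`ParsedName` and normalizes
individual name words to plain uppercase ASCII for all downstream
comparisons.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ParsedName",
    "NormalizedWord",
    "ParseError",
    "parse_name",
    "split_hybrid_formula",
    "strip_markup",
    "normalize_word",
]

# Infraspecific rank markers recognized between epithet and infraspecific
# epithet.  Anything in QUALIFIERS is stripped and recorded instead.
RANK_MARKERS = {"subsp.", "ssp.", "var.", "subvar.", "f.", "forma", "subf."}
QUALIFIERS = {"cf.", "aff.", "?", "sp.", "spp.", "sp", "spp", "indet.", "indet"}

HYBRID_SIGNS = ("×", "x")

# Explicit diacritic/ligature folding table (Latin-1/Latin-2 letters).
# Unknown non-ASCII letters are dropped with a warning.
_FOLD = {
    "æ": "ae", "Æ": "AE", "œ": "oe", "Œ": "OE",
    "ß": "ss",
    "à": "a", "á": "a", "â": "a", "ã": "a", "ä": "a", "å": "a",
    "è": "e", "é": "e", "ê": "e", "ë": "e",
    "ì": "i", "í": "i", "î": "i", "ï": "i",
    "ò": "o", "ó": "o", "ô": "o", "õ": "o", "ö": "o", "ø": "o",
    "ù": "u", "ú": "u", "û": "u", "ü": "u",
    "ý": "y", "ÿ": "y",
    "ç": "c", "ñ": "n",
    "À": "A", "Á": "A", "Â": "A", "Ã": "A", "Ä": "A", "Å": "A",
    "È": "E", "É": "E", "Ê": "E", "Ë": "E",
    "Ì": "I", "Í": "I", "Î": "I", "Ï": "I",
    "Ò": "O", "Ó": "O", "Ô": "O", "Õ": "O", "Ö": "O", "Ø": "O",
    "Ù": "U", "Ú": "U", "Û": "U", "Ü": "U",
    "Ý": "Y",
    "Ç": "C", "Ñ": "N",
    # Latin-2 / Latin Extended-A letters seen in author and place names
    "ā": "a", "ă": "a", "ą": "a",
    "ć": "c", "ĉ": "c", "č": "c",
    "ď": "d", "đ": "d",
    "ē": "e", "ė": "e", "ę": "e", "ě": "e",
    "ğ": "g", "ģ": "g",
    "ī": "i", "į": "i",
    "ł": "l", "ľ": "l",
    "ń": "n", "ň": "n",
    "ō": "o", "ő": "o",
    "ŕ": "r", "ř": "r",
    "ś": "s", "ş": "s", "š": "s",
    "ţ": "t", "ť": "t",
    "ū": "u", "ů": "u", "ű": "u",
    "ź": "z", "ż": "z", "ž": "z",
    "Ā": "A", "Ą": "A", "Ć": "C", "Č": "C",
    "Đ": "D", "Ę": "E", "Ě": "E",
    "Ł": "L", "Ń": "N", "Ň": "N",
    "Ő": "O", "Ř": "R", "Ś": "S", "Š": "S",
    "Ź": "Z", "Ż": "Z", "Ž": "Z",
}

_TAG_RE = re.compile(r"<[^<>]*>")
_WS_RE = re.compile(r"\s+")


class ParseError(ValueError):
    """Raised when a raw string cannot be parsed into name components.

    Carries the offending raw string so callers can report it.
    """

    def __init__(self, raw: str, reason: str = "unparseable name"):
        self.raw = raw
        self.reason = reason
        super().__init__(f"{reason}: {raw!r}")


@dataclass(frozen=True)
class NormalizedWord:
    """A name word reduced to uppercase A-Z characters only."""

    text: str
    length: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass
class ParsedName:
    """Atomized components of one scientific-name string."""

    genus_raw: str
    subgenus_raw: str | None = None
    epithet_raw: str | None = None
    infra_rank_marker: str | None = None
    infra_epithet_raw: str | None = None
    authority_raw: str | None = None
    hybrid_genus: bool = False
    hybrid_epithet: bool = False
    qualifiers: list[str] = field(default_factory=list)
    residue: str = ""

    @property
    def is_binomial(self) -> bool:
        return self.epithet_raw is not None

    def reassemble(self) -> str:
        """Rebuild ``genus [epithet] [authority]`` (markup/qualifiers lost)."""
        parts = [self.genus_raw]
        if self.epithet_raw:
            parts.append(self.epithet_raw)
        if self.infra_rank_marker and self.infra_epithet_raw:
            parts.extend([self.infra_rank_marker, self.infra_epithet_raw])
        if self.authority_raw:
            parts.append(self.authority_raw)
        return " ".join(parts)


def strip_markup(raw: str) -> str:
    """Remove stray HTML tags and entities, collapse whitespace."""
    s = _TAG_RE.sub(" ", raw)
    s = s.replace("&amp;", "&").replace("&nbsp;", " ")
    return _WS_RE.sub(" ", s).strip()


def normalize_word(word: str) -> NormalizedWord:
    """Uppercase a word and fold it to the A-Z alphabet.

    Hyphens, whitespace and apostrophes are removed; diacritics and
    ligatures fold to plain ASCII.  Any other non-ASCII letter is dropped
    with a warning.  A word that reduces to nothing is an error.
    """
    if not word:
        raise ValueError("cannot normalize an empty word")
    out: list[str] = []
    for ch in word:
        if ch in _FOLD:
            out.append(_FOLD[ch].upper())
        elif ch.isascii() and ch.isalpha():
            out.append(ch.upper())
        elif ch in "-'’" or ch.isspace() or (ch.isascii() and ch.isdigit()):
            continue
        else:
            warnings.warn(f"dropping unmappable character {ch!r} in {word!r}", stacklevel=2)
    text = "".join(out)
    if not text:
        raise ValueError(f"word {word!r} reduced to empty after normalization")
    return NormalizedWord(text=text, length=len(text))


def split_hybrid_formula(raw: str) -> list[str]:
    """Split a hybrid formula ``A b x C d`` into its parent name strings.

    A hybrid *sign* attached to (or directly preceding) a single word is
    not a formula separator; only a standalone sign *between* two name
    parts splits.  Returns a single-element list for non-formula input.
    """
    s = strip_markup(raw)
    tokens = s.split(" ")
    parts: list[list[str]] = [[]]
    for i, tok in enumerate(tokens):
        if tok in HYBRID_SIGNS and parts[-1] and i + 1 < len(tokens):
            nxt = tokens[i + 1]
            # a sign directly before a lowercase epithet marks a hybrid
            # epithet, not a formula boundary
            if nxt[:1].isupper() or nxt[:1] == "×":
                parts.append([])
                continue
            if tok == "×":
                parts[-1].append(tok)
                continue
        parts[-1].append(tok)
    return [" ".join(p) for p in parts if p]


def _is_latinate(tok: str) -> bool:
    return bool(tok) and all(c.isalpha() or c in "-'" for c in tok)


def _looks_like_authority_start(tok: str) -> bool:
    if not tok:
        return False
    if tok.startswith("("):
        return True
    if tok[0].isupper():
        return True
    return not _is_latinate(tok)


def parse_name(raw: str) -> ParsedName:
    """Atomize a raw name string into its components.

    Components are assigned positionally: the first capitalized latinate
    word is the genus, an optional parenthesized word after it the
    subgenus, a following lowercase word the epithet, a recognized rank
    marker plus word the infraspecific pair and any trailing text the
    authority.  Hybrid signs are removed (with flags set) and qualifier
    tokens removed and recorded.  A string containing a hybrid formula is
    parsed to its first parent, the rest going to ``residue``.
    """
    stripped = strip_markup(raw)
    if not stripped:
        raise ParseError(raw, "empty after markup stripping")

    parents = split_hybrid_formula(stripped)
    residue = ""
    if len(parents) > 1:
        stripped = parents[0]
        residue = " × ".join(parents[1:])

    hybrid_genus = False
    hybrid_epithet = False
    qualifiers: list[str] = []
    tokens: list[str] = []
    pending_hybrid = False
    for tok in stripped.split(" "):
        low = tok.lower()
        if low in QUALIFIERS:
            qualifiers.append(tok)
            continue
        if tok in HYBRID_SIGNS and not tokens:
            hybrid_genus = True
            continue
        if tok in HYBRID_SIGNS:
            pending_hybrid = True
            continue
        if tok.startswith("×") and len(tok) > 1:
            tok = tok[1:]
            if not tokens:
                hybrid_genus = True
            else:
                pending_hybrid = True
        if pending_hybrid:
            if tok[:1].islower():
                hybrid_epithet = True
            pending_hybrid = False
        tokens.append(tok)

    if not tokens:
        raise ParseError(raw, "no name tokens found")

    genus = tokens[0]
    if not (genus[:1].isupper() and _is_latinate(genus)):
        raise ParseError(raw, "no leading capitalized genus word")

    name = ParsedName(
        genus_raw=genus,
        hybrid_genus=hybrid_genus,
        hybrid_epithet=hybrid_epithet,
        qualifiers=qualifiers,
        residue=residue,
    )

    i = 1
    # optional parenthesized subgenus between genus and epithet
    if i < len(tokens) and tokens[i].startswith("(") and tokens[i].endswith(")"):
        inner = tokens[i][1:-1]
        if _is_latinate(inner) and inner[:1].isupper():
            name.subgenus_raw = inner
            i += 1

    if i < len(tokens) and tokens[i][:1].islower() and _is_latinate(tokens[i]):
        name.epithet_raw = tokens[i]
        i += 1
        if (
            i + 1 < len(tokens)
            and tokens[i].lower() in RANK_MARKERS
            and tokens[i + 1][:1].islower()
            and _is_latinate(tokens[i + 1])
        ):
            name.infra_rank_marker = tokens[i]
            name.infra_epithet_raw = tokens[i + 1]
            i += 2

    if i < len(tokens):
        name.authority_raw = " ".join(tokens[i:])

    return name
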