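"""Authority-string normalization and similarity.

Authorities ("L.", "Röding, 1798", "(Lipsky) Greuter") differ between
sources in ways edit distance handles poorly — abbreviated surnames,
missing years, reordered author teams, diacritics.  The comparison here
normalizes both strings, applies two asymmetric pre-adjustments (year
truncation, leading-bracket removal), then averages a blended bigram/
trigram similarity computed on a diacritic-retaining and a plain-ASCII
form of each string.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .ngrams import blended_similarity
from .parse import _FOLD

__all__ = [
    "AuthorityForms",
    "AbbrevTable",
    "DEFAULT_ABBREVIATIONS",
    "normalize_authority",
    "pair_adjust",
    "authority_similarity",
]

# Small default author-abbreviation dictionary; user-replaceable.
DEFAULT_ABBREVIATIONS = {
    "l.": "Linnaeus",
    "dc.": "de Candolle",
    "lam.": "Lamarck",
    "ag.": "Agardh",
    "benth.": "Bentham",
    "hook.": "Hooker",
    "kuetz.": "Kuetzing",
    "mont.": "Montagne",
}

_YEAR_RE = re.compile(r"(1[5-9]\d{2}|20\d{2})(\))?$")
_INITIAL_GAP_RE = re.compile(r"\b([A-Za-z])\.\s+(?=[A-Za-z]\.)")
_ET_AND_RE = re.compile(r"\s+(et|and)\s+(?!al\b)", flags=re.IGNORECASE)
_TRAILING_YEAR_NO_COMMA_RE = re.compile(r"([^\s,])\s+((1[5-9]\d{2}|20\d{2})\)?)$")


@dataclass(frozen=True)
class AuthorityForms:
    """Normalized authority in diacritic-retaining and plain-ASCII form."""

    original_norm: str
    plain_norm: str


@dataclass
class AbbrevTable:
    """Mapping from abbreviated author surname (with dot) to expansion."""

    entries: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ABBREVIATIONS))

    def __post_init__(self) -> None:
        self.entries = {k.lower(): v for k, v in self.entries.items()}

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str | None = None) -> "AbbrevTable":
        """Load a two-column (abbreviation, expansion) delimited text file."""
        path = Path(path)
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        entries: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter=delimiter):
                if len(row) >= 2 and row[0].strip():
                    entries[row[0].strip().lower()] = row[1].strip()
        return cls(entries=entries)


def fold_diacritics(s: str) -> str:
    """Replace accented characters and ligatures by ASCII equivalents."""
    out = []
    for ch in s:
        out.append(_FOLD.get(ch, ch).upper() if ch in _FOLD else ch)
    return "".join(out)


def normalize_authority(s: str, abbrevs: AbbrevTable | None = None) -> AuthorityForms:
    """Normalize an authority string into its two comparison forms.

    'et'/'and' become '&' (but 'et al.' is kept), initials lose internal
    spacing, a comma is inserted before a trailing year if absent,
    abbreviated surnames are expanded, and the result is uppercased.
    """
    if not s or not s.strip():
        raise ValueError("cannot normalize an empty authority")
    if abbrevs is None:
        abbrevs = AbbrevTable()
    t = s.replace("&amp;", "&").strip()
    t = re.sub(r"\s+", " ", t)
    t = _ET_AND_RE.sub(" & ", t)
    # "F. J. R. Taylor" -> "F.J.R. Taylor": join initial-to-initial only
    while _INITIAL_GAP_RE.search(t):
        t = _INITIAL_GAP_RE.sub(r"\1.", t)
    t = _TRAILING_YEAR_NO_COMMA_RE.sub(r"\1, \2", t)
    # expand whole tokens ending in "." against the abbreviation table
    tokens = t.split(" ")
    for i, tok in enumerate(tokens):
        if tok.endswith(".") and tok.lower() in abbrevs.entries:
            tokens[i] = abbrevs.entries[tok.lower()]
    t = " ".join(tokens).upper()
    return AuthorityForms(original_norm=t, plain_norm=fold_diacritics(t))


def pair_adjust(a: str, b: str) -> tuple[str, str]:
    """Apply the two asymmetric pre-adjustments to a normalized pair.

    If exactly one string ends with a year (optional closing bracket)
    the year's last three digits are removed; if exactly one starts with
    '(' that bracket is removed.  The rules fire independently.
    """
    ya, yb = _YEAR_RE.search(a), _YEAR_RE.search(b)
    if ya and not yb:
        a = a[: ya.start() + 1] + (ya.group(2) or "")
    elif yb and not ya:
        b = b[: yb.start() + 1] + (yb.group(2) or "")
    ba, bb = a.startswith("("), b.startswith("(")
    if ba and not bb:
        a = a[1:]
    elif bb and not ba:
        b = b[1:]
    return a, b


def authority_similarity(a: str | None, b: str | None, abbrevs: AbbrevTable | None = None) -> float | None:
    """Mean blended n-gram similarity of the two authority forms.

    Returns ``None`` (undefined, *not* zero) when either side is missing,
    so callers can distinguish "no authority supplied" from "dissimilar".
    """
    if not a or not a.strip() or not b or not b.strip():
        return None
    fa = normalize_authority(a, abbrevs)
    fb = normalize_authority(b, abbrevs)
    orig_a, orig_b = pair_adjust(fa.original_norm, fb.original_norm)
    sim_orig = blended_similarity(orig_a, orig_b)
    if fa.original_norm == fa.plain_norm and fb.original_norm == fb.plain_norm:
        return sim_orig
    plain_a, plain_b = pair_adjust(fa.plain_norm, fb.plain_norm)
    return (sim_orig + blended_similarity(plain_a, plain_b)) / 2
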