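"""Synthetic checklists, seeded misspellings and the evaluation harness.

Misspellings are generated and classified by a six-way error taxonomy:

* ``1a`` — single non-initial character insertion/deletion/substitution;
* ``1b`` — single non-initial adjacent transposition;
* ``1c`` — error at word start (initial character inserted, deleted,
  substituted or transposed);
* ``2``  — two-character insertion/deletion/substitution in one word;
* ``3``  — two-character block transposition, or three or more character
  transformations, in one word;
* ``4``  — (binomials) at least one transformation in both genus and
  epithet.

Independently of the label, an error is *phonetic* when every changed
word still matches the original under the 2007 phonetic test
(gender-tolerant for epithets).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .editdist import edit_distance
from .engine import EngineConfig, ReferenceIndex, match_name
from .parse import normalize_word
from .phonetics import phonetic_match

__all__ = [
    "ErrorType",
    "SyntheticCase",
    "EvaluationResult",
    "ERROR_LABELS",
    "generate_reference",
    "generate_misspelling",
    "classify_error",
    "evaluate",
]

ERROR_LABELS = ("1a", "1b", "1c", "2", "3", "4")

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"
_EPITHET_ENDINGS = ("us", "a", "um", "is")
_GENUS_ENDINGS = ("us", "a", "um", "ia", "odon", "ella")
_AUTHORS = ("Smith", "Jones", "Garcia", "Tanaka", "Olsen", "Petrov", "Dubois", "Rossi")
_GROUPS = ("animalia", "plantae")
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class ErrorType:
    label: str
    phonetic: bool

    def __post_init__(self) -> None:
        if self.label not in ERROR_LABELS:
            raise ValueError(f"unknown error label {self.label!r}")


@dataclass(frozen=True)
class SyntheticCase:
    correct: str
    misspelled: str
    error_type: ErrorType
    seed: int


@dataclass(frozen=True)
class EvaluationResult:
    recall: float
    precision: float
    f1: float
    by_error_type: dict
    n_cases: int
    n_hits: int
    n_true_hits: int


# ---------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------


def _syllable_word(rng: random.Random, min_len: int, max_len: int, endings) -> str:
    ending = rng.choice(endings)
    target = rng.randint(min_len, max_len)
    stem_len = max(2, target - len(ending))
    stem = ""
    while len(stem) < stem_len:
        stem += rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
    return (stem[:stem_len] + ending)[:max_len]


def generate_reference(n_genera: int, species_per_genus: int, seed: int) -> list[dict]:
    """Deterministic latinate-looking synthetic checklist rows."""
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = random.Random(seed)
    rows: list[dict] = []
    genera: set[str] = set()
    while len(genera) < n_genera:
        genus = _syllable_word(rng, 4, 16, _GENUS_ENDINGS).capitalize()
        if genus in genera:
            continue
        genera.add(genus)
        group = rng.choice(_GROUPS)
        epithets: set[str] = set()
        while len(epithets) < species_per_genus:
            epithet = _syllable_word(rng, 4, 14, _EPITHET_ENDINGS)
            if epithet in epithets:
                continue
            epithets.add(epithet)
            authority = f"{rng.choice(_AUTHORS)}, {rng.randint(1758, 2010)}"
            rows.append(
                {
                    "genus": genus,
                    "epithet": epithet,
                    "authority": authority,
                    "status": "accepted",
                    "group": group,
                }
            )
        if species_per_genus == 0:
            rows.append(
                {"genus": genus, "epithet": "", "authority": "", "status": "accepted", "group": group}
            )
    return rows


# ---------------------------------------------------------------------
# single-word edit primitives (operate on lowercase text)
# ---------------------------------------------------------------------


def _insert(rng, w, pos):
    return w[:pos] + rng.choice(_ALPHABET) + w[pos:]


def _delete(w, pos):
    return w[:pos] + w[pos + 1 :]


def _substitute(rng, w, pos):
    c = rng.choice([x for x in _ALPHABET if x != w[pos]])
    return w[:pos] + c + w[pos + 1 :]


def _transpose(w, pos):
    return w[:pos] + w[pos + 1] + w[pos] + w[pos + 2 :]


def _edit_word(rng: random.Random, word: str, label: str) -> str:
    """One attempt at applying an error of the requested type to a word."""
    w = word.lower()
    n = len(w)
    if label == "1a":
        op = rng.choice(("ins", "del", "sub"))
        if op == "ins":
            return _insert(rng, w, rng.randint(1, n))
        if op == "del":
            return _delete(w, rng.randint(1, n - 1))
        return _substitute(rng, w, rng.randint(1, n - 1))
    if label == "1b":
        positions = [i for i in range(1, n - 1) if w[i] != w[i + 1]]
        if not positions:
            raise ValueError(f"no non-initial transposition possible in {word!r}")
        return _transpose(w, rng.choice(positions))
    if label == "1c":
        ops = ["ins", "sub"]
        if n >= 2:
            ops.append("del")
        if n >= 2 and w[0] != w[1]:
            ops.append("tr")
        op = rng.choice(ops)
        if op == "ins":
            return _insert(rng, w, 0)
        if op == "del":
            return _delete(w, 0)
        if op == "sub":
            return _substitute(rng, w, 0)
        return _transpose(w, 0)
    if label == "2":
        out = w
        for _ in range(2):
            op = rng.choice(("ins", "del", "sub"))
            m = len(out)
            if op == "ins":
                out = _insert(rng, out, rng.randint(1, m))
            elif op == "del" and m >= 3:
                out = _delete(out, rng.randint(1, m - 1))
            else:
                out = _substitute(rng, out, rng.randint(1, m - 1))
        return out
    if label == "3":
        if rng.random() < 0.5 and n >= 5:
            # adjacent two-character block swap, e.g. panulirus -> palinurus
            pos = rng.randint(1, n - 4)
            blocks = [
                i for i in range(1, n - 3) if w[i : i + 2] != w[i + 2 : i + 4]
            ]
            if blocks:
                pos = rng.choice(blocks)
                return w[:pos] + w[pos + 2 : pos + 4] + w[pos : pos + 2] + w[pos + 4 :]
        out = w
        for _ in range(3):
            op = rng.choice(("ins", "del", "sub"))
            m = len(out)
            if op == "ins":
                out = _insert(rng, out, rng.randint(1, m))
            elif op == "del" and m >= 3:
                out = _delete(out, rng.randint(1, m - 1))
            else:
                out = _substitute(rng, out, rng.randint(1, m - 1))
        return out
    raise ValueError(f"unknown error label {label!r}")


def generate_misspelling(name: str, error_type: str, seed: int) -> SyntheticCase:
    """Produce a seeded misspelling of ``name`` with the requested label.

    The returned case round-trips: ``classify_error(misspelled, name)``
    reproduces the label.  Raises when the request is infeasible for the
    given name (e.g. a transposition in a word of repeated letters).
    """
    rng = random.Random(seed)
    words = name.split()
    if error_type == "4" and len(words) != 2:
        raise ValueError("type 4 errors require a binomial")
    for _ in range(200):
        new_words = list(words)
        if error_type == "4":
            idxs = [0, 1]
            labels = [rng.choice(("1a", "1b", "1c")) for _ in idxs]
        else:
            idxs = [rng.randrange(len(words))] if len(words) > 1 else [0]
            labels = [error_type]
        try:
            for idx, lab in zip(idxs, labels):
                edited = _edit_word(rng, words[idx], lab)
                new_words[idx] = edited.capitalize() if idx == 0 else edited
        except (ValueError, IndexError):
            continue
        misspelled = " ".join(new_words)
        if misspelled == name or any(not w for w in new_words):
            continue
        try:
            got = classify_error(misspelled, name)
        except ValueError:
            continue
        if got.label == error_type:
            return SyntheticCase(
                correct=name, misspelled=misspelled, error_type=got, seed=seed
            )
    raise ValueError(f"could not generate a type-{error_type} error for {name!r} (seed {seed})")


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------


def _is_block_swap(a: str, b: str) -> bool:
    """True when b is a single adjacent 2-character block swap of a."""
    if len(a) != len(b) or len(a) < 4:
        return False
    for i in range(len(a) - 3):
        if (
            a[:i] == b[:i]
            and a[i : i + 2] == b[i + 2 : i + 4]
            and a[i + 2 : i + 4] == b[i : i + 2]
            and a[i + 4 :] == b[i + 4 :]
            and a[i : i + 2] != a[i + 2 : i + 4]
        ):
            return True
    return False


def _is_adjacent_transposition(a: str, b: str) -> int | None:
    """Position of a single adjacent swap turning a into b, else None."""
    if len(a) != len(b):
        return None
    diffs = [i for i in range(len(a)) if a[i] != b[i]]
    if (
        len(diffs) == 2
        and diffs[1] == diffs[0] + 1
        and a[diffs[0]] == b[diffs[1]]
        and a[diffs[1]] == b[diffs[0]]
    ):
        return diffs[0]
    return None


def classify_error(misspelled: str, correct: str) -> ErrorType:
    """Assign an error-type label and phonetic flag to a misspelling."""
    mw = misspelled.split()
    cw = correct.split()
    if len(mw) != len(cw) or len(mw) not in (1, 2):
        raise ValueError("names must share uninomial/binomial structure")
    m_norm = [normalize_word(w).text for w in mw]
    c_norm = [normalize_word(w).text for w in cw]
    changed = [i for i in range(len(mw)) if m_norm[i] != c_norm[i]]
    if not changed:
        raise ValueError("names are identical; no error to classify")

    phonetic = all(
        phonetic_match(m_norm[i], c_norm[i], is_epithet=(i == 1)) for i in changed
    )

    if len(changed) == 2:
        return ErrorType(label="4", phonetic=phonetic)

    a, b = m_norm[changed[0]], c_norm[changed[0]]
    if _is_block_swap(a, b):
        return ErrorType(label="3", phonetic=phonetic)
    d1 = edit_distance(a, b, block_limit=1)
    if d1 == 1:
        pos = _is_adjacent_transposition(a, b)
        if pos is not None:
            label = "1c" if pos == 0 else "1b"
        else:
            label = "1c" if a[:1] != b[:1] else "1a"
        return ErrorType(label=label, phonetic=phonetic)
    if d1 == 2:
        return ErrorType(label="2", phonetic=phonetic)
    return ErrorType(label="3", phonetic=phonetic)


# ---------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------


def evaluate(
    cases: list[SyntheticCase],
    index: ReferenceIndex,
    config: EngineConfig | None = None,
) -> EvaluationResult:
    """Recall / precision / F1 of the matcher over synthetic cases.

    Recall is the fraction of cases whose correct target appears anywhere
    in the returned candidates; precision pools hits over the whole set.
    """
    if not cases:
        raise ValueError("no cases to evaluate")
    config = config or EngineConfig()
    n_hits = 0
    n_true = 0
    found = 0
    per_type: dict[str, list[int]] = {}
    for case in cases:
        report = match_name(case.misspelled, index, config)
        hits = report.target_names()
        hit = case.correct in hits
        found += hit
        n_hits += len(hits)
        n_true += sum(1 for h in hits if h == case.correct)
        per_type.setdefault(case.error_type.label, []).append(int(hit))
    recall = found / len(cases)
    precision = n_true / n_hits if n_hits else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    by_type = {lab: sum(v) / len(v) for lab, v in sorted(per_type.items())}
    return EvaluationResult(
        recall=recall,
        precision=precision,
        f1=f1,
        by_error_type=by_type,
        n_cases=len(cases),
        n_hits=n_hits,
        n_true_hits=n_true,
    )
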