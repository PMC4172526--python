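"""Reference-index construction and match orchestration.

``build_index`` precomputes normalized names, lengths and phonetic keys
for a reference checklist and indexes genera by phonetic key, by the
phonetic keys of their child epithets and by length, so that the genus
pre-filter can be answered with dictionary lookups instead of a full
scan.  ``match_name`` runs the full pipeline: parse, genus pre-filter,
genus distance + post-filter, species pre-filter, species distance +
post-filter, authority similarity, result shaping and ranking.

``brute_force_match`` applies exactly the same rules by scanning every
record naively; the two must return identical reports (the index is an
optimization, never a semantics change).
"""

from __future__ import annotations

import time
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from .authority import AbbrevTable, authority_similarity
from .editdist import EXCEEDS, edit_distance
from .filters import (
    GENUS_MAX_ED,
    GENUS_PREFILTER_EPITHET_LEN_DIFF,
    GENUS_PREFILTER_MAX_LEN_DIFF,
    SPECIES_MAX_COMBINED_ED,
    QueryContext,
    genus_postfilter,
    genus_prefilter,
    species_postfilter,
    species_prefilter,
)
from .parse import NormalizedWord, ParsedName, ParseError, normalize_word, parse_name
from .phonetics import PhoneticKey, rees2007_key

__all__ = [
    "GenusRecord",
    "SpeciesRecord",
    "CandidateGenus",
    "CandidateSpecies",
    "MatchReport",
    "EngineConfig",
    "ReferenceIndex",
    "build_index",
    "match_name",
    "brute_force_match",
    "shape_results",
    "rank_results",
]

MASKED_STATUSES = {"misspelling", "nomen nudum", "nomen_nudum", "later usage", "later_usage"}


@dataclass
class GenusRecord:
    id: int
    name_raw: str
    name_norm: NormalizedWord
    key_2007: PhoneticKey
    epithet_key_set: set[str] = field(default_factory=set)
    group_labels: set[str] = field(default_factory=set)
    masked: bool = True
    authority_raw: str | None = None
    species_ids: list[int] = field(default_factory=list)


@dataclass
class SpeciesRecord:
    id: int
    genus_id: int
    epithet_raw: str
    epithet_norm: NormalizedWord
    key_2007: PhoneticKey
    masked: bool = False
    authority_raw: str | None = None


@dataclass(frozen=True)
class CandidateGenus:
    genus_id: int
    name: str
    ed: int
    phonetic: bool
    authority: str | None = None
    authority_similarity: float | None = None

    @property
    def combined_ed(self) -> int:
        return self.ed

    @property
    def is_phonetic(self) -> bool:
        return self.phonetic

    @property
    def full_name(self) -> str:
        return self.name


@dataclass(frozen=True)
class CandidateSpecies:
    species_id: int
    genus_name: str
    epithet: str
    genus_ed: int
    epithet_ed: int
    genus_phonetic: bool
    epithet_phonetic: bool
    authority: str | None = None
    authority_similarity: float | None = None

    @property
    def combined_ed(self) -> int:
        return self.genus_ed + self.epithet_ed

    @property
    def is_phonetic(self) -> bool:
        # both words must sound alike for the binomial to count phonetic
        return self.genus_phonetic and self.epithet_phonetic

    @property
    def full_name(self) -> str:
        return f"{self.genus_name} {self.epithet}"


@dataclass
class MatchReport:
    raw: str
    mode: str
    level: str                      # "genus" or "species"
    query: ParsedName | None
    exact: list = field(default_factory=list)
    nearest: list = field(default_factory=list)
    other: list = field(default_factory=list)
    n_genera_prefiltered: int = 0
    n_epithets_tested: int = 0
    elapsed: float = field(default=0.0, compare=False)
    error: str | None = None

    @property
    def candidates(self) -> list:
        return self.exact + self.nearest + self.other

    def target_names(self) -> set[str]:
        return {c.full_name for c in self.candidates}


@dataclass
class EngineConfig:
    mode: str = "normal"            # normal | no_shaping | rapid
    group: str | None = None
    genus_block_limit: int = 2
    species_block_limit: int = 4
    abbrevs: AbbrevTable | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"normal", "no_shaping", "rapid"}:
            raise ValueError(f"unknown mode {self.mode!r}")


class ReferenceIndex:
    """Precomputed reference checklist with lookup structures."""

    def __init__(self) -> None:
        self.genera: list[GenusRecord] = []
        self.species: list[SpeciesRecord] = []
        self._genus_id_by_norm: dict[str, int] = {}
        self._genus_ids_by_key: dict[str, list[int]] = defaultdict(list)
        self._genus_ids_by_epithet_key: dict[str, set[int]] = defaultdict(set)
        self._genus_ids_by_length: dict[int, list[int]] = defaultdict(list)
        self._species_by_genus_epithet: dict[tuple[int, str], int] = {}

    # -- construction -------------------------------------------------

    def _get_or_add_genus(self, name_raw: str, norm: NormalizedWord) -> GenusRecord:
        gid = self._genus_id_by_norm.get(norm.text)
        if gid is not None:
            return self.genera[gid]
        rec = GenusRecord(
            id=len(self.genera),
            name_raw=name_raw,
            name_norm=norm,
            key_2007=rees2007_key(norm, is_epithet=False),
        )
        self.genera.append(rec)
        self._genus_id_by_norm[norm.text] = rec.id
        return rec

    def _finalize(self) -> None:
        for g in self.genera:
            self._genus_ids_by_key[g.key_2007.key].append(g.id)
            self._genus_ids_by_length[g.name_norm.length].append(g.id)
            for key in g.epithet_key_set:
                self._genus_ids_by_epithet_key[key].add(g.id)

    # -- stats ---------------------------------------------------------

    @property
    def n_genera(self) -> int:
        return sum(1 for g in self.genera if not g.masked)

    @property
    def n_species(self) -> int:
        return sum(1 for s in self.species if not s.masked)

    def unmasked_genera(self, group: str | None = None):
        for g in self.genera:
            if g.masked:
                continue
            if group is not None and group not in g.group_labels:
                continue
            yield g

    # -- pre-filter candidate generation (index path) ------------------

    def prefilter_candidate_ids(self, q: QueryContext, config: EngineConfig) -> list[int]:
        """Genus ids that could pass the pre-filter, via index lookups."""
        ids: set[int] = set(self._genus_ids_by_key.get(q.genus_key_2007.key, ()))
        if q.epithet_key_2007 is not None:
            for gid in self._genus_ids_by_epithet_key.get(q.epithet_key_2007.key, ()):
                if (
                    abs(self.genera[gid].name_norm.length - q.genus.length)
                    <= GENUS_PREFILTER_EPITHET_LEN_DIFF
                ):
                    ids.add(gid)
        if config.mode != "rapid":
            qlen = q.genus.length
            for length in range(
                qlen - GENUS_PREFILTER_MAX_LEN_DIFF, qlen + GENUS_PREFILTER_MAX_LEN_DIFF + 1
            ):
                ids.update(self._genus_ids_by_length.get(length, ()))
        return sorted(ids)


def build_index(records) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from an iterable of reference rows.

    Each row is a mapping with keys ``genus``/``epithet`` (or a full
    ``scientific_name``), and optionally ``authority``, ``status`` and
    ``group``.  Rows whose status flags them as misspellings, nomina nuda
    or later usages are masked: stored but never returned by matching.
    Duplicate (genus, epithet) rows collapse with a warning; unparseable
    rows are reported and skipped, never fatal.
    """
    index = ReferenceIndex()
    genus_mask_votes: dict[int, bool] = {}
    for rownum, row in enumerate(records):
        if not isinstance(row, dict):
            row = vars(row)
        genus_raw = (row.get("genus") or "").strip()
        epithet_raw = (row.get("epithet") or "").strip()
        authority = (row.get("authority") or "").strip() or None
        status = (row.get("status") or "").strip().lower()
        group = (row.get("group") or "").strip()
        masked = status in MASKED_STATUSES

        if not genus_raw:
            sci = (row.get("scientific_name") or "").strip()
            if not sci:
                warnings.warn(f"row {rownum}: no genus or scientific name; skipped")
                continue
            try:
                parsed = parse_name(sci)
            except ParseError as exc:
                warnings.warn(f"row {rownum}: {exc}; skipped")
                continue
            genus_raw = parsed.genus_raw
            epithet_raw = parsed.epithet_raw or ""
            if authority is None:
                authority = parsed.authority_raw

        try:
            genus_norm = normalize_word(genus_raw)
        except ValueError as exc:
            warnings.warn(f"row {rownum}: {exc}; skipped")
            continue
        genus = index._get_or_add_genus(genus_raw, genus_norm)
        prev = genus_mask_votes.get(genus.id, True)
        genus_mask_votes[genus.id] = prev and masked
        if group:
            genus.group_labels.add(group)
        if not epithet_raw:
            if authority and genus.authority_raw is None:
                genus.authority_raw = authority
            continue

        try:
            epithet_norm = normalize_word(epithet_raw)
        except ValueError as exc:
            warnings.warn(f"row {rownum}: {exc}; skipped")
            continue
        dup = index._species_by_genus_epithet.get((genus.id, epithet_norm.text))
        if dup is not None:
            warnings.warn(
                f"row {rownum}: duplicate species {genus_raw} {epithet_raw}; collapsed"
            )
            if not masked:
                index.species[dup].masked = False
            continue
        sp = SpeciesRecord(
            id=len(index.species),
            genus_id=genus.id,
            epithet_raw=epithet_raw,
            epithet_norm=epithet_norm,
            key_2007=rees2007_key(epithet_norm, is_epithet=True),
            masked=masked,
            authority_raw=authority,
        )
        index.species.append(sp)
        index._species_by_genus_epithet[(genus.id, epithet_norm.text)] = sp.id
        genus.species_ids.append(sp.id)

    for gid, all_masked in genus_mask_votes.items():
        index.genera[gid].masked = all_masked
    for sp in index.species:
        genus = index.genera[sp.genus_id]
        if not sp.masked:
            genus.masked = False
            genus.epithet_key_set.add(sp.key_2007.key)
    index._finalize()
    return index


# ---------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------


def _query_context(parsed: ParsedName) -> QueryContext:
    genus_norm = normalize_word(parsed.genus_raw)
    epithet_norm = normalize_word(parsed.epithet_raw) if parsed.epithet_raw else None
    return QueryContext(
        genus=genus_norm,
        genus_key_2007=rees2007_key(genus_norm, is_epithet=False),
        epithet=epithet_norm,
        epithet_key_2007=(
            rees2007_key(epithet_norm, is_epithet=True) if epithet_norm is not None else None
        ),
    )


def shape_results(cands: list, level: str) -> list:
    """Suppress distant candidates when closer ones exist.

    Near matches at the closest distances (plus phonetic matches) are
    always kept; each wider distance band is kept only when every closer
    band is empty.  Exact (distance 0) candidates are handled separately
    and must not be passed in.
    """
    if level == "species":
        always_max, bands = 2, (3, 4)
    else:
        always_max, bands = 1, (2, 3)
    kept = [c for c in cands if c.is_phonetic or c.combined_ed <= always_max]
    if kept:
        return kept
    for band in bands:
        at_band = [c for c in cands if c.combined_ed == band]
        if at_band:
            return at_band
    return []


def rank_results(cands: list) -> tuple[list, list]:
    """Split shaped candidates into nearest (ED 1 + phonetic) and other."""
    key = lambda c: (c.full_name, getattr(c, "authority", None) or "")
    nearest = sorted((c for c in cands if c.combined_ed == 1 or c.is_phonetic), key=key)
    other = sorted((c for c in cands if not (c.combined_ed == 1 or c.is_phonetic)), key=key)
    return nearest, other


def _run_match(
    raw: str,
    index: ReferenceIndex,
    config: EngineConfig,
    candidate_genus_ids,
    parsed: ParsedName | None = None,
) -> MatchReport:
    t0 = time.perf_counter()
    if parsed is None:
        try:
            parsed = parse_name(raw)
        except ParseError as exc:
            return MatchReport(
                raw=raw, mode=config.mode, level="genus", query=None,
                error=exc.reason, elapsed=time.perf_counter() - t0,
            )
    q = _query_context(parsed)
    level = "species" if q.epithet is not None else "genus"
    report = MatchReport(raw=raw, mode=config.mode, level=level, query=parsed)

    query_auth = parsed.authority_raw

    # genus pre-filter + distance + post-filter
    surviving: list[tuple[GenusRecord, int, bool]] = []
    n_prefiltered = 0
    for g in candidate_genus_ids:
        passed, tag = genus_prefilter(q, g)
        if not passed:
            continue
        if config.mode == "rapid" and tag not in ("1a", "1b"):
            continue
        n_prefiltered += 1
        ed = edit_distance(
            q.genus, g.name_norm,
            block_limit=config.genus_block_limit, max_distance=GENUS_MAX_ED,
        )
        if ed is EXCEEDS:
            continue
        phonetic = tag == "1a"
        if not genus_postfilter(
            ed, phonetic, q.genus.length, g.name_norm.length,
            q.genus.text[:1] == g.name_norm.text[:1],
        ):
            continue
        surviving.append((g, ed, phonetic))
    report.n_genera_prefiltered = n_prefiltered

    if level == "genus":
        cands = []
        for g, ed, phonetic in surviving:
            sim = authority_similarity(query_auth, g.authority_raw, config.abbrevs)
            cands.append(
                CandidateGenus(
                    genus_id=g.id, name=g.name_raw, ed=ed, phonetic=phonetic,
                    authority=g.authority_raw, authority_similarity=sim,
                )
            )
        exact = [c for c in cands if c.ed == 0]
        near = [c for c in cands if c.ed > 0]
        if config.mode != "no_shaping":
            near = shape_results(near, "genus")
        report.exact = sorted(exact, key=lambda c: c.full_name)
        report.nearest, report.other = rank_results(near)
    else:
        cands = []
        n_epithets = 0
        for g, genus_ed, genus_phonetic in surviving:
            for sid in g.species_ids:
                sp = index.species[sid]
                if sp.masked:
                    continue
                if not species_prefilter(q.epithet.length, sp.epithet_norm.length, True):
                    continue
                n_epithets += 1
                epithet_ed = edit_distance(
                    q.epithet, sp.epithet_norm,
                    block_limit=config.species_block_limit,
                    max_distance=SPECIES_MAX_COMBINED_ED,
                )
                if epithet_ed is EXCEEDS:
                    continue
                epithet_phonetic = q.epithet_key_2007.key == sp.key_2007.key
                m = min(q.epithet.length, sp.epithet_norm.length)
                if not species_postfilter(
                    genus_ed, epithet_ed, epithet_phonetic, m,
                    q.epithet.text[:1] == sp.epithet_norm.text[:1],
                    q.epithet.text[:3] == sp.epithet_norm.text[:3],
                ):
                    continue
                sim = authority_similarity(query_auth, sp.authority_raw, config.abbrevs)
                cands.append(
                    CandidateSpecies(
                        species_id=sp.id, genus_name=g.name_raw, epithet=sp.epithet_raw,
                        genus_ed=genus_ed, epithet_ed=epithet_ed,
                        genus_phonetic=genus_phonetic, epithet_phonetic=epithet_phonetic,
                        authority=sp.authority_raw, authority_similarity=sim,
                    )
                )
        report.n_epithets_tested = n_epithets
        exact = [c for c in cands if c.combined_ed == 0]
        near = [c for c in cands if c.combined_ed > 0]
        if config.mode != "no_shaping":
            near = shape_results(near, "species")
        report.exact = sorted(exact, key=lambda c: c.full_name)
        report.nearest, report.other = rank_results(near)

    report.elapsed = time.perf_counter() - t0
    return report


def match_name(raw: str, index: ReferenceIndex, config: EngineConfig | None = None) -> MatchReport:
    """Match one raw name string against the index (optimized path)."""
    config = config or EngineConfig()
    try:
        parsed = parse_name(raw)
    except ParseError as exc:
        return MatchReport(raw=raw, mode=config.mode, level="genus", query=None, error=exc.reason)
    q = _query_context(parsed)
    ids = index.prefilter_candidate_ids(q, config)
    genera = [
        index.genera[i]
        for i in ids
        if not index.genera[i].masked
        and (config.group is None or config.group in index.genera[i].group_labels)
    ]
    return _run_match(raw, index, config, genera, parsed=parsed)


def brute_force_match(raw: str, index: ReferenceIndex, config: EngineConfig | None = None) -> MatchReport:
    """Match by scanning every reference genus naively (test oracle)."""
    config = config or EngineConfig()
    genera = list(index.unmasked_genera(config.group))
    return _run_match(raw, index, config, genera)
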