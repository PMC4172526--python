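import random

import pytest

from binomatch.editdist import edit_distance
from binomatch.engine import (
    CandidateSpecies,
    EngineConfig,
    brute_force_match,
    build_index,
    match_name,
    rank_results,
    shape_results,
)
from binomatch.synthetic import generate_misspelling, generate_reference


def _report_key(rep):
    return (rep.query, rep.exact, rep.nearest, rep.other,
            rep.n_genera_prefiltered, rep.n_epithets_tested, rep.error)


class TestBuildIndex:
    def test_epithet_key_set_per_genus(self, small_index):
        g = next(g for g in small_index.genera if g.name_raw == "Halymenia")
        assert 1 <= len(g.epithet_key_set) <= 3
        assert len(g.species_ids) == 3

    def test_masked_row_never_returned(self, small_index):
        rep = match_name("Fagus silvatica", small_index)
        assert all(c.epithet != "silvatica" for c in rep.candidates)
        # the accepted sibling is still found
        assert "Fagus sylvatica" in rep.target_names()

    def test_genus_with_zero_species_matchable(self, small_index):
        rep = match_name("Catharocta", small_index)
        assert rep.level == "genus"
        assert "Catharacta" in rep.target_names()

    def test_duplicate_rows_collapse_with_warning(self):
        rows = [
            {"genus": "Homo", "epithet": "sapiens"},
            {"genus": "Homo", "epithet": "sapiens"},
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            index = build_index(rows)
        assert index.n_species == 1

    def test_unparseable_row_skipped_not_fatal(self):
        with pytest.warns(UserWarning):
            index = build_index([{"scientific_name": "123 456"}, {"genus": "Homo"}])
        assert index.n_genera == 1

    def test_full_scientific_name_rows(self):
        index = build_index([{"scientific_name": "Fagus sylvatica L."}])
        assert index.n_genera == 1 and index.n_species == 1
        assert index.species[0].authority_raw == "L."


class TestMatchName:
    def test_fig_style_two_hits_at_same_distance(self, small_index):
        rep = match_name("Halymenia dilitata Zanardini", small_index)
        hits = {c.full_name: c for c in rep.candidates}
        assert set(hits) == {"Halymenia dilatata", "Halymenia digitata"}
        for c in hits.values():
            assert (c.genus_ed, c.epithet_ed) == (0, 1)
            assert c.authority_similarity is not None
        assert hits["Halymenia dilatata"].authority_similarity > hits[
            "Halymenia digitata"
        ].authority_similarity

    def test_exact_match_distinct(self, small_index):
        rep = match_name("Fagus sylvatica", small_index)
        assert [c.full_name for c in rep.exact] == ["Fagus sylvatica"]
        assert rep.nearest == [] and rep.other == []

    def test_parse_failure_reported(self, small_index):
        rep = match_name("123 nonsense", small_index)
        assert rep.error is not None
        assert rep.candidates == []

    def test_selectivity_counts(self, small_index):
        rep = match_name("Halymenia dilitata", small_index)
        assert 1 <= rep.n_genera_prefiltered <= len(small_index.genera)
        assert rep.n_epithets_tested >= 2

    def test_group_restriction(self, small_index):
        rep = match_name("Siganus canaliculatus", small_index, EngineConfig(group="plantae"))
        assert rep.candidates == []
        rep2 = match_name("Siganus canaliculatus", small_index, EngineConfig(group="animalia"))
        assert [c.full_name for c in rep2.exact] == ["Siganus canaliculatus"]

    def test_shaping_suppresses_distant_target(self):
        # designated target at combined ED 4 masked by a closer false hit
        index = build_index([
            {"genus": "Aleuron", "epithet": "scriptor"},
            {"genus": "Asura", "epithet": "scripta"},
        ])
        normal = match_name("Aleura scripta", index)
        assert normal.target_names() == {"Asura scripta"}
        unshaped = match_name("Aleura scripta", index, EngineConfig(mode="no_shaping"))
        assert unshaped.target_names() == {"Asura scripta", "Aleuron scriptor"}

    def test_authority_similarity_requires_both_sides(self, small_index):
        rep = match_name("Halymenia dilitata", small_index)  # no query authority
        assert all(c.authority_similarity is None for c in rep.candidates)


def _mk(genus_ed, epithet_ed, genus_phonetic=False, epithet_phonetic=False, name="Aa aa"):
    g, e = name.split()
    return CandidateSpecies(
        species_id=0, genus_name=g, epithet=e,
        genus_ed=genus_ed, epithet_ed=epithet_ed,
        genus_phonetic=genus_phonetic, epithet_phonetic=epithet_phonetic,
    )


class TestShaping:
    def test_ed3_dropped_when_ed2_present(self):
        keep = _mk(0, 2)
        drop = _mk(0, 3, name="Bb bb")
        assert shape_results([keep, drop], "species") == [keep]

    def test_lone_ed4_survives(self):
        only = _mk(2, 2, name="Cc cc")
        assert shape_results([only], "species") == [only]
        lone4 = _mk(0, 4, name="Dd dd")
        assert shape_results([lone4], "species") == [lone4]

    def test_empty(self):
        assert shape_results([], "species") == []
        assert shape_results([], "genus") == []

    def test_phonetic_always_kept(self):
        close = _mk(0, 1)
        phon = _mk(2, 2, genus_phonetic=True, epithet_phonetic=True, name="Bb bb")
        kept = shape_results([close, phon], "species")
        assert phon in kept and close in kept

    def test_ed4_dropped_when_ed3_present(self):
        ed3 = _mk(0, 3)
        ed4 = _mk(0, 4, name="Bb bb")
        assert shape_results([ed3, ed4], "species") == [ed3]


class TestRanking:
    def test_phonetic_grouped_with_ed1(self):
        a = _mk(0, 1, name="Aa aa")
        b = _mk(0, 2, genus_phonetic=True, epithet_phonetic=True, name="Bb bb")
        nearest, other = rank_results([a, b])
        assert nearest == [a, b] and other == []

    def test_combined_ed3_goes_to_other(self):
        c = _mk(2, 1, name="Cc cc")
        nearest, other = rank_results([c])
        assert nearest == [] and other == [c]

    def test_alphabetical_order(self):
        xs = [_mk(0, 1, name=n) for n in ("Cc cc", "Aa aa", "Bb bb")]
        nearest, _ = rank_results(xs)
        assert [c.full_name for c in nearest] == ["Aa aa", "Bb bb", "Cc cc"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["normal", "no_shaping", "rapid"])
    def test_equivalence_on_synthetic_queries(self, synthetic_index, synthetic_rows, mode):
        rng = random.Random(99)
        names = [f"{r['genus']} {r['epithet']}" for r in synthetic_rows]
        config = EngineConfig(mode=mode)
        queries = []
        for _ in range(60):
            name = rng.choice(names)
            label = rng.choice(("1a", "1b", "1c", "2", "3", "4"))
            try:
                queries.append(generate_misspelling(name, label, rng.randrange(2**31)).misspelled)
            except ValueError:
                queries.append(name)
        queries += [rng.choice(names).split()[0] for _ in range(10)]  # uninomials
        queries += ["Zzygomat incognita", "Homo"]
        for q in queries:
            fast = match_name(q, synthetic_index, config)
            slow = brute_force_match(q, synthetic_index, config)
            assert _report_key(fast) == _report_key(slow), q

    def test_equivalence_with_group_restriction(self, synthetic_index, synthetic_rows):
        config = EngineConfig(group="plantae")
        for r in synthetic_rows[:20]:
            q = f"{r['genus']} {r['epithet']}"
            assert _report_key(match_name(q, synthetic_index, config)) == _report_key(
                brute_force_match(q, synthetic_index, config)
            )


class TestEngineProperties:
    def test_ed1_guarantee(self, synthetic_index, synthetic_rows):
        rng = random.Random(5)
        names = [f"{r['genus']} {r['epithet']}" for r in synthetic_rows]
        for _ in range(80):
            name = rng.choice(names)
            label = rng.choice(("1a", "1b", "1c"))
            case = generate_misspelling(name, label, rng.randrange(2**31))
            rep = match_name(case.misspelled, synthetic_index)
            assert name in rep.target_names(), (case.misspelled, name)

    def test_rapid_candidates_subset_of_normal(self, synthetic_index, synthetic_rows):
        rng = random.Random(11)
        names = [f"{r['genus']} {r['epithet']}" for r in synthetic_rows]
        for _ in range(40):
            case = generate_misspelling(
                rng.choice(names), rng.choice(("1a", "1b", "1c", "2")), rng.randrange(2**31)
            )
            rapid = match_name(case.misspelled, synthetic_index, EngineConfig(mode="rapid"))
            normal = match_name(case.misspelled, synthetic_index, EngineConfig(mode="no_shaping"))
            assert rapid.target_names() <= normal.target_names()

    def test_shaping_never_drops_close_or_phonetic(self, synthetic_index, synthetic_rows):
        rng = random.Random(17)
        names = [f"{r['genus']} {r['epithet']}" for r in synthetic_rows]
        for _ in range(40):
            case = generate_misspelling(
                rng.choice(names), rng.choice(("1a", "2", "3", "4")), rng.randrange(2**31)
            )
            normal = match_name(case.misspelled, synthetic_index)
            unshaped = match_name(case.misspelled, synthetic_index, EngineConfig(mode="no_shaping"))
            kept = normal.target_names()
            for c in unshaped.candidates:
                if c.combined_ed <= 2 or c.is_phonetic:
                    assert c.full_name in kept

    def test_uninomial_runs_genus_flow_only(self, small_index):
        rep = match_name("Fagus", small_index)
        assert rep.level == "genus"
        assert rep.n_epithets_tested == 0
        assert "Fagus" in {c.full_name for c in rep.exact}

    def test_exact_query_identical_in_both_modes(self, small_index):
        a = match_name("Homo sapiens", small_index)
        b = brute_force_match("Homo sapiens", small_index)
        assert _report_key(a) == _report_key(b)
        assert [c.full_name for c in a.exact] == ["Homo sapiens"]


class TestBlockLimitsConfigurable:
    def test_species_block_limit_enables_block_swap_match(self):
        index = build_index([{"genus": "Palinurus", "epithet": "elephas"}])
        # genus block swap: panulirus <-> palinurus at distance 2
        rep = match_name("Panulirus elephas", index, EngineConfig(genus_block_limit=2))
        assert "Palinurus elephas" in rep.target_names()
        rep_ld = match_name("Panulirus elephas", index, EngineConfig(genus_block_limit=0))
        assert "Palinurus elephas" not in rep_ld.target_names()

    def test_default_limits(self):
        cfg = EngineConfig()
        assert cfg.genus_block_limit == 2 and cfg.species_block_limit == 4
        assert edit_distance("PANULIRUS", "PALINURUS", block_limit=cfg.genus_block_limit) == 2
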