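# binomatch

Near ("fuzzy") matching of organism scientific names against a reference
checklist.

Misspelled genus and species names are matched with a composite pipeline:

1. **Parsing / normalization** — raw strings are atomized into genus,
   subgenus, epithet, infraspecific parts and authority; hybrid signs and
   qualifier tokens (`cf.`, `aff.`, `sp.`, …) are removed and recorded;
   words are folded to uppercase A–Z (`binomatch.parse`).
2. **Phonetic keys** — two custom soundalike encoders, the newer of which
   rewrites leading character groups (PH→F, GN→N, …) and collapses latin
   gender endings (-us/-a/-um) of epithets (`binomatch.phonetics`).
3. **Edit distance** — Levenshtein / Damerau-Levenshtein plus a
   block-transposition extension that charges a transposed 2–4 character
   block its length instead of double (so *Panulirus* ↔ *Palinurus* is
   distance 2, not 4) (`binomatch.editdist`).
4. **Heuristic filters** — cheap pre-filters ("blocking") decide which
   reference names deserve the dynamic-programming test; post-filters
   discard distant candidates by word length and leading characters
   (`binomatch.filters`).
5. **Engine** — index construction, candidate generation, result shaping
   (wider distance bands only shown when closer ones are empty), ranking
   into nearest/other, plus a naive brute-force twin used as a test
   oracle (`binomatch.engine`).
6. **Authority similarity** — padded bigram/trigram blend over normalized
   authority strings, with abbreviation expansion and diacritic-tolerant
   dual forms (`binomatch.authority`, `binomatch.ngrams`).
7. **Synthetic benchmark** — seeded checklist generation, misspelling
   generation/classification by a six-way error taxonomy, and a
   recall/precision/F1 harness (`binomatch.synthetic`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including an
exhaustive comparison of the edit distance against a brute-force
edit-script oracle over all string pairs up to length 6 on a 3-letter
alphabet (~1.5 min).

## Command line

```sh
# validate a checklist (TSV/CSV; Darwin-Core column names accepted)
binomatch build-index reference.tsv

# match one or more names (or --input-list file.txt)
binomatch match "Sigonus caraliculatus" -r reference.tsv
binomatch match --input-list queries.txt -r reference.tsv --format json -o out.json

# modes: normal (default), no-shaping (report every near match), rapid
binomatch match "Peronella lesueri" -r reference.tsv --mode no-shaping

# restrict to a group label, tune block limits, supply author abbreviations
binomatch match "Fucus sp." -r reference.tsv --group plantae \
    --genus-block-limit 2 --species-block-limit 4 --abbrev-file abbrevs.tsv

# all-against-all deduplication of one file
binomatch dedupe -r reference.tsv -o duplicates.tsv

# synthetic recall/precision benchmark by error type
binomatch evaluate --n-genera 200 --species-per-genus 5 --cases-per-type 50 --seed 1
```

Reports carry one row per candidate with the edit distance in `x,y`
(genus,epithet) form, phonetic flags, authority similarity (blank when
either side lacks an authority), the nearest/other/exact bucket and
per-query pre-filter selectivity counts. Run with `-v` to log
selectivity percentages per query.

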