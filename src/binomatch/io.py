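"""Reading reference checklists and writing match reports.

Reference checklists are delimited text (TSV or CSV) with a header row.
Darwin-Core-style column names (``scientificName``, ``genus``,
``specificEpithet``, ``scientificNameAuthorship``, ``taxonomicStatus``)
are recognized as aliases for the native short names.  Reports are
written as TSV or JSON, one row per candidate, with edit distances in
the "x,y" genus,epithet format.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .engine import CandidateSpecies, MatchReport

__all__ = ["read_reference", "write_report", "COLUMN_ALIASES"]

log = logging.getLogger(__name__)

COLUMN_ALIASES = {
    "scientificname": "scientific_name",
    "scientific_name": "scientific_name",
    "genus": "genus",
    "specificepithet": "epithet",
    "specific_epithet": "epithet",
    "epithet": "epithet",
    "species": "epithet",
    "scientificnameauthorship": "authority",
    "authorship": "authority",
    "authority": "authority",
    "taxonomicstatus": "status",
    "status": "status",
    "group": "group",
    "taxon_group": "group",
    "taxongroup": "group",
}

_MANDATORY_ANY = ("genus", "scientific_name")


def read_reference(path: str | Path, delimiter: str | None = None) -> list[dict]:
    """Read a reference checklist into a list of row dicts.

    The delimiter is inferred from the file extension unless given.
    A file providing neither a genus nor a full-name column is fatal;
    rows with an empty name field are logged and skipped.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    renames = {}
    for col in df.columns:
        alias = COLUMN_ALIASES.get(col.strip().lower())
        if alias and alias not in renames.values():
            renames[col] = alias
    df = df.rename(columns=renames)
    if not any(c in df.columns for c in _MANDATORY_ANY):
        raise ValueError(
            f"{path}: no usable name column; need one of {_MANDATORY_ANY}, "
            f"got {list(df.columns)}"
        )
    rows: list[dict] = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = {k: rec.get(k, "") for k in ("scientific_name", "genus", "epithet", "authority", "status", "group")}
        if not row["genus"].strip() and not row["scientific_name"].strip():
            log.warning("%s line %d: empty name fields; skipped", path, i + 2)
            continue
        rows.append(row)
    return rows


def _candidate_row(report: MatchReport, cand, bucket: str) -> dict:
    if isinstance(cand, CandidateSpecies):
        ed = f"{cand.genus_ed},{cand.epithet_ed}"
        phonetic = cand.is_phonetic
    else:
        ed = str(cand.ed)
        phonetic = cand.phonetic
    sim = cand.authority_similarity
    return {
        "query": report.raw,
        "match": cand.full_name,
        "authority": cand.authority or "",
        "edit_distance": ed,
        "phonetic": phonetic,
        "authority_similarity": "" if sim is None else round(sim, 4),
        "group": bucket,
        "n_genera_prefiltered": report.n_genera_prefiltered,
        "n_epithets_tested": report.n_epithets_tested,
        "elapsed_s": round(report.elapsed, 6),
        "error": report.error or "",
    }


def report_rows(reports: list[MatchReport]) -> list[dict]:
    rows = []
    for rep in reports:
        emitted = False
        for bucket, cands in (("exact", rep.exact), ("nearest", rep.nearest), ("other", rep.other)):
            for cand in cands:
                rows.append(_candidate_row(rep, cand, bucket))
                emitted = True
        if not emitted:
            rows.append(
                {
                    "query": rep.raw, "match": "", "authority": "", "edit_distance": "",
                    "phonetic": "", "authority_similarity": "", "group": "",
                    "n_genera_prefiltered": rep.n_genera_prefiltered,
                    "n_epithets_tested": rep.n_epithets_tested,
                    "elapsed_s": round(rep.elapsed, 6),
                    "error": rep.error or "",
                }
            )
    return rows


def write_report(reports: list[MatchReport], path: str | Path, format: str = "tsv") -> None:
    """Write match reports as TSV or JSON (same schema either way)."""
    rows = report_rows(reports)
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1, default=str)
    elif format == "tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
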