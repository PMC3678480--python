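"""Reading and writing species records, match logs and taxon stores.

CSV reading is deliberately flexible: real biodiversity spreadsheets either
combine the binomial and author citation into one field or keep them apart,
and carry arbitrary extra columns (trait values). A ColumnMap says which
column is which; everything else becomes the record's data mapping. Reading
is total — a row whose name cannot be parsed becomes an explicit skip
record, never a silent drop, so row counts are conserved.

Taxon sets persist to a small versioned JSON document (JSON holds nested
lists and mappings far more comfortably than tabular CSV).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Union

from .nomenclature import Name, NameParseError, Rank, parse_authority, parse_name
from .resolver import MatchResult
from .taxa import Taxon, TaxonSet

__all__ = [
    "ColumnMap",
    "Record",
    "SkippedRecord",
    "SchemaError",
    "read_records_csv",
    "write_match_log_csv",
    "read_match_log_csv",
    "save_taxa_json",
    "load_taxa_json",
]

JSON_FORMAT = "taxonmatch-taxa"
JSON_VERSION = 1

MATCH_LOG_COLUMNS = [
    "original_name",
    "original_authority",
    "matched_accepted_name",
    "matched_authority",
    "step",
    "score",
    "outcome",
    "alternatives",
    "notes",
]


class SchemaError(ValueError):
    """A required column or a JSON schema element is missing or wrong."""


@dataclass(frozen=True)
class ColumnMap:
    """Which CSV columns hold the name, the authority, and the data.

    ``authority_field=None`` means the citation is embedded in the name
    field. ``data_fields``: ``"keep_all"`` keeps every remaining column,
    or pass an explicit list.
    """

    name_field: str
    authority_field: str | None = None
    synonym_fields: tuple[str, ...] = ()
    data_fields: Union[str, tuple[str, ...]] = "keep_all"


@dataclass
class Record:
    """One successfully parsed CSV row."""

    name: Name
    data: dict[str, Any] = field(default_factory=dict)
    synonyms: list[Name] = field(default_factory=list)
    row: int = 0


@dataclass
class SkippedRecord:
    """One row whose name could not be parsed (kept, not dropped)."""

    row: int
    raw: str
    reason: str


def read_records_csv(
    path: str | Path,
    colmap: ColumnMap,
    style: str = "botanical",
    delimiter: str = ",",
) -> list[Record | SkippedRecord]:
    """Read species records from a CSV file with a header row.

    Returns one :class:`Record` or :class:`SkippedRecord` per data row, in
    file order. Raises :class:`SchemaError` when the name column is absent.
    """
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        if colmap.name_field not in header:
            raise SchemaError(
                f"name column {colmap.name_field!r} not in header {header}"
            )
        if colmap.authority_field and colmap.authority_field not in header:
            raise SchemaError(
                f"authority column {colmap.authority_field!r} not in header"
            )
        reserved = {colmap.name_field, colmap.authority_field, *colmap.synonym_fields}
        if colmap.data_fields == "keep_all":
            data_cols = [c for c in header if c not in reserved]
        else:
            data_cols = [c for c in colmap.data_fields if c in header]

        out: list[Record | SkippedRecord] = []
        for rownum, row in enumerate(reader, start=2):
            raw_name = (row.get(colmap.name_field) or "").strip()
            try:
                name = parse_name(raw_name, style=style)
            except NameParseError as exc:
                out.append(SkippedRecord(row=rownum, raw=raw_name, reason=str(exc)))
                continue
            if colmap.authority_field:
                raw_auth = (row.get(colmap.authority_field) or "").strip()
                if raw_auth:
                    name = replace(name, authority=parse_authority(raw_auth))
            synonyms = []
            for col in colmap.synonym_fields:
                raw_syn = (row.get(col) or "").strip()
                if raw_syn:
                    try:
                        synonyms.append(parse_name(raw_syn, style=style))
                    except NameParseError:
                        pass
            data = {c: row.get(c, "") for c in data_cols}
            out.append(Record(name=name, data=data, synonyms=synonyms, row=rownum))
        return out


def write_match_log_csv(results: Iterable[MatchResult], path: str | Path) -> None:
    """Write one audit row per query: what matched, at which step, and why."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MATCH_LOG_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.query.binomial,
                    str(r.query.authority),
                    r.accepted_name.binomial if r.accepted_name else "",
                    str(r.accepted_name.authority) if r.accepted_name else "",
                    r.step.value if r.step else "",
                    f"{r.score:.4f}" if r.score is not None else "",
                    r.outcome.value,
                    ";".join(str(a) for a in r.alternatives),
                    ";".join(r.notes),
                ]
            )


def read_match_log_csv(path: str | Path) -> list[dict[str, str]]:
    """Read a match log back as a list of row dicts (round-trip check)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _name_to_json(name: Name) -> dict[str, Any]:
    return {
        "genus": name.genus,
        "epithet": name.epithet,
        "rank": name.rank.value,
        "infraspecific_epithet": name.infraspecific_epithet,
        "hybrid": name.hybrid,
        "authority": str(name.authority),
        "raw": name.raw,
    }


def _name_from_json(doc: dict[str, Any]) -> Name:
    return Name(
        genus=doc["genus"],
        epithet=doc.get("epithet", ""),
        rank=Rank(doc.get("rank", "species")),
        infraspecific_epithet=doc.get("infraspecific_epithet", ""),
        hybrid=doc.get("hybrid", False),
        authority=parse_authority(doc.get("authority", "")),
        raw=doc.get("raw", ""),
    )


def save_taxa_json(ts: TaxonSet, path: str | Path) -> None:
    """Persist a TaxonSet to the versioned JSON store format."""
    doc = {
        "format": JSON_FORMAT,
        "version": JSON_VERSION,
        "taxa": [
            {
                "name": _name_to_json(t.name),
                "synonyms": [_name_to_json(s) for s in t.synonyms],
                "data": t.data,
                "distribution": sorted(t.distribution),
            }
            for t in ts
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")


def load_taxa_json(path: str | Path) -> TaxonSet:
    """Load a TaxonSet from the JSON store; ``save → load`` is the identity.

    Raises :class:`SchemaError` on an unknown format or version;
    ``json.JSONDecodeError`` propagates for malformed files.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("format") != JSON_FORMAT:
        raise SchemaError(f"not a {JSON_FORMAT} document: {path}")
    if doc.get("version") != JSON_VERSION:
        raise SchemaError(
            f"unsupported store version {doc.get('version')!r} "
            f"(supported: {JSON_VERSION})"
        )
    ts = TaxonSet()
    for tdoc in doc.get("taxa", []):
        ts.add(
            Taxon(
                name=_name_from_json(tdoc["name"]),
                synonyms=[_name_from_json(s) for s in tdoc.get("synonyms", [])],
                data=tdoc.get("data", {}),
                distribution=set(tdoc.get("distribution", [])),
            )
        )
    return ts
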