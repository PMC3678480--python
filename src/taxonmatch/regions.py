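"""Standardize free-text distribution region names to canonical codes.

Species distributions are typically recorded as lists of country or region
names, and every data source spells them differently. A RegionIndex maps
names, alternative names (aliases) and named groups ("major regions") onto
a canonical scheme of coded units at a stated level — the TDWG World
Geographical Scheme for Recording Plant Distributions defines such units at
four nested scales, and its published tables load directly. The engine is
scheme-agnostic: any table in the documented CSV format works, and a small
synthetic 12-region scheme ships with the package for tests and demos.

Table format (CSV, header required)::

    code,name,level,aliases,groups

``aliases`` is pipe-separated; each alias is either a bare alternative name
for the row's own code, or ``name=CODE1+CODE2`` to target explicit codes
(how a country maps onto several level-3 units). ``groups`` is a
pipe-separated list of group names this code belongs to.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "RegionIndex",
    "RegionTableError",
    "load_region_index",
    "demo_region_index",
    "resolve_region",
    "standardize_distribution",
]


class RegionTableError(ValueError):
    """The region table violates an integrity constraint."""


def normalize_region_name(name: str) -> str:
    """Case-fold and strip diacritics: 'Río Negro' == 'rio negro'."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


@dataclass
class RegionIndex:
    """Lookup structure from names/aliases/groups to canonical code sets."""

    level: int = 0
    canonical: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, set[str]] = field(default_factory=dict)
    groups: dict[str, set[str]] = field(default_factory=dict)

    def is_known(self, name: str) -> bool:
        key = normalize_region_name(name)
        return (
            name in self.canonical
            or name.upper() in self.canonical
            or key in self.aliases
            or key in self.groups
        )

    def __len__(self) -> int:
        return len(self.canonical)


def load_region_index(table_path: str | Path) -> RegionIndex:
    """Build a RegionIndex from a region-table CSV.

    Canonical names and codes self-resolve; every explicit alias target is
    checked against the code column (:class:`RegionTableError` otherwise).
    An empty table yields an empty index.
    """
    idx = RegionIndex()
    pending: list[tuple[str, set[str]]] = []  # alias key -> explicit codes
    levels: set[int] = set()
    with open(table_path, newline="", encoding="utf-8-sig") as fh:
        for row in csv.DictReader(fh):
            code = (row.get("code") or "").strip()
            name = (row.get("name") or "").strip()
            if not code:
                continue
            if (row.get("level") or "").strip():
                levels.add(int(row["level"]))
            idx.canonical[code] = name
            idx.aliases.setdefault(normalize_region_name(code), set()).add(code)
            if name:
                idx.aliases.setdefault(normalize_region_name(name), set()).add(code)
            for alias in (row.get("aliases") or "").split("|"):
                alias = alias.strip()
                if not alias:
                    continue
                if "=" in alias:
                    alias_name, _, targets = alias.partition("=")
                    codes = {c.strip() for c in targets.split("+") if c.strip()}
                    pending.append((normalize_region_name(alias_name), codes))
                else:
                    idx.aliases.setdefault(normalize_region_name(alias), set()).add(code)
            for group in (row.get("groups") or "").split("|"):
                group = group.strip()
                if group:
                    idx.groups.setdefault(normalize_region_name(group), set()).add(code)
    for key, codes in pending:
        unknown = codes - idx.canonical.keys()
        if unknown:
            raise RegionTableError(
                f"alias {key!r} references unknown code(s): {sorted(unknown)}"
            )
        idx.aliases.setdefault(key, set()).update(codes)
    if len(levels) > 1:
        raise RegionTableError(f"mixed levels in one table: {sorted(levels)}")
    idx.level = levels.pop() if levels else 0
    return idx


def demo_region_index() -> RegionIndex:
    """The bundled synthetic 12-region demo scheme (tests and examples)."""
    ref = resources.files("taxonmatch.data") / "regions_demo_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_region_index(path)


def resolve_region(name: str, idx: RegionIndex) -> set[str]:
    """The set of canonical codes a single region name denotes.

    Canonical names and codes map to themselves, aliases to their targets,
    group names to the full member set. An unknown name resolves to the
    empty set — use :meth:`RegionIndex.is_known` to distinguish "unknown"
    from a genuinely empty group.
    """
    key = normalize_region_name(name)
    out: set[str] = set()
    if key in idx.aliases:
        out |= idx.aliases[key]
    if key in idx.groups:
        out |= idx.groups[key]
    return out


def standardize_distribution(
    names: Iterable[str], idx: RegionIndex
) -> tuple[set[str], list[str]]:
    """Convert a free-text region list to (codes, unresolved names).

    The code set is the union over all resolvable entries; unresolved names
    are reported in input order, deduplicated.
    """
    codes: set[str] = set()
    unresolved: list[str] = []
    seen_unresolved: set[str] = set()
    for name in names:
        resolved = resolve_region(name, idx)
        if resolved:
            codes |= resolved
        else:
            key = normalize_region_name(name)
            if key not in seen_unresolved:
                seen_unresolved.add(key)
                unresolved.append(name)
    return codes, unresolved
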