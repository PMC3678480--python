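"""Taxon and TaxonSet: accepted names, synonyms, attached data, name index.

A taxon has exactly one accepted name (as defined by whichever reference
source it came from) plus any number of synonyms, and may carry arbitrary
attached data (trait values, distribution codes). A TaxonSet indexes every
name — accepted or synonym — by its binomial string WITHOUT the authority,
so homonyms (one name string used for several taxa, e.g. "Glycyrrhiza
glandulifera" for both G. glabra and G. uralensis) collide by design and
are disambiguated downstream by the authority comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, NamedTuple

from .nomenclature import Name

__all__ = ["Taxon", "TaxonSet", "NameHit", "DuplicateTaxonError", "combine"]

logger = logging.getLogger(__name__)


class DuplicateTaxonError(ValueError):
    """An accepted name (binomial + authority) was added twice."""


class NameHit(NamedTuple):
    """One index entry: the taxon, the name as recorded, and its status."""

    taxon: "Taxon"
    name: Name
    is_accepted: bool


@dataclass
class Taxon:
    """One taxon: accepted name, synonyms, attached data, distribution."""

    name: Name
    synonyms: list[Name] = field(default_factory=list)
    data: dict[str, Any] = field(default_factory=dict)
    distribution: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        # drop synonyms equal to the accepted name and formatted duplicates
        seen = {str(self.name)}
        unique: list[Name] = []
        for syn in self.synonyms:
            key = str(syn)
            if key not in seen:
                seen.add(key)
                unique.append(syn)
        self.synonyms = unique

    def __repr__(self) -> str:
        return f"Taxon({self.name}, {len(self.synonyms)} synonyms)"


def index_key(name: Name) -> str:
    """Case-folded binomial (no authority) used for name lookup."""
    return name.binomial.casefold()


class TaxonSet:
    """A name-indexed collection of taxa supporting homonyms."""

    def __init__(self, taxa: Iterable[Taxon] = ()):  # noqa: D107
        self._taxa: list[Taxon] = []
        self._index: dict[str, list[NameHit]] = {}
        for t in taxa:
            self.add(t)

    def add(self, taxon: Taxon) -> None:
        """Add a taxon, indexing its accepted name and all synonyms.

        Raises :class:`DuplicateTaxonError` if a taxon with the same
        accepted binomial *and* the same authority is already present.
        """
        key = index_key(taxon.name)
        for hit in self._index.get(key, []):
            if hit.is_accepted and hit.name == taxon.name:
                raise DuplicateTaxonError(
                    f"accepted name already present: {taxon.name}"
                )
        self._taxa.append(taxon)
        self._index.setdefault(key, []).append(NameHit(taxon, taxon.name, True))
        for syn in taxon.synonyms:
            self._index.setdefault(index_key(syn), []).append(
                NameHit(taxon, syn, False)
            )

    def get_by_binomial(self, binomial: str | Name) -> list[NameHit]:
        """All index entries for a binomial; accepted names listed first.

        Homonyms yield several entries. Unknown names yield an empty list.
        """
        key = (
            index_key(binomial)
            if isinstance(binomial, Name)
            else " ".join(binomial.split()).casefold()
        )
        hits = self._index.get(key, [])
        return sorted(hits, key=lambda h: not h.is_accepted)

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self) -> Iterator[Taxon]:
        return iter(self._taxa)

    def __contains__(self, binomial: str | Name) -> bool:
        return bool(self.get_by_binomial(binomial))

    def names(self) -> list[str]:
        """Every distinct indexed binomial string (original casing)."""
        out: dict[str, None] = {}
        for hits in self._index.values():
            for hit in hits:
                out.setdefault(hit.name.binomial, None)
        return list(out)

    def __repr__(self) -> str:
        return f"TaxonSet({len(self)} taxa, {len(self._index)} indexed names)"


def combine(sets: Iterable[TaxonSet]) -> TaxonSet:
    """Merge several matched collections into one set.

    Taxa with equal accepted names are merged: synonym lists are unioned and
    data mappings merged, later sets overriding on key collision (each
    collision is logged). Intended for collections already matched against
    the same reference, so accepted names agree exactly.
    """
    merged: dict[tuple[str, str], Taxon] = {}
    order: list[tuple[str, str]] = []
    for ts in sets:
        for taxon in ts:
            key = (index_key(taxon.name), str(taxon.name.authority))
            if key not in merged:
                merged[key] = Taxon(
                    name=taxon.name,
                    synonyms=list(taxon.synonyms),
                    data=dict(taxon.data),
                    distribution=set(taxon.distribution),
                )
                order.append(key)
                continue
            target = merged[key]
            seen = {str(s) for s in target.synonyms} | {str(target.name)}
            for syn in taxon.synonyms:
                if str(syn) not in seen:
                    target.synonyms.append(syn)
                    seen.add(str(syn))
            for k, v in taxon.data.items():
                if k in target.data and target.data[k] != v:
                    logger.warning(
                        "combine: key %r of %s overridden (%r -> %r)",
                        k, taxon.name, target.data[k], v,
                    )
                target.data[k] = v
            target.distribution |= taxon.distribution
    return TaxonSet(merged[k] for k in order)
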