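"""Shared fixtures: the worked-example reference set and a random Name maker."""

from __future__ import annotations

import random

import pytest

from taxonmatch import Authority, AuthorToken, Name, Rank, Taxon, TaxonSet, parse_name

#: Letters only; avoids tokens the authority grammar treats as separators.
_FORBIDDEN_SURNAMES = {"ex", "non", "et", "and"}


def random_name(rng: random.Random) -> Name:
    """A structurally valid random Name, authorities and ranks included."""

    def word(lo: int, hi: int) -> str:
        while True:
            w = "".join(rng.choice("abcdefghijklmnopqrstuvwxyz")
                        for _ in range(rng.randint(lo, hi)))
            if w not in _FORBIDDEN_SURNAMES:  # citation keywords, never epithets
                return w

    def surname() -> str:
        while True:
            s = word(2, 8).capitalize()
            if s.lower() not in _FORBIDDEN_SURNAMES:
                break
        if rng.random() < 0.4:
            s += "."
        return s

    def author() -> AuthorToken:
        initials = tuple(
            rng.choice("ABCDEFGHJKLMPRSTW") + "."
            for _ in range(rng.choice([0, 0, 0, 1, 2]))
        )
        return AuthorToken(surname=surname(), initials=initials)

    primary = tuple(author() for _ in range(rng.choice([0, 1, 1, 1, 2])))
    authority = Authority(
        primary_authors=primary,
        basionym_authors=tuple(author() for _ in range(rng.choice([0, 0, 0, 1]))),
        ex_authors=(
            tuple(author() for _ in range(1)) if primary and rng.random() < 0.1 else ()
        ),
        excluded_authors=(
            (author(),) if rng.random() < 0.1 else ()
        ),
        year=rng.randint(1753, 2012) if rng.random() < 0.3 else None,
    )
    rank = rng.choice(
        [Rank.species] * 5 + [Rank.subspecies, Rank.variety, Rank.form, Rank.genus]
    )
    epithet = word(3, 10) if rank is not Rank.genus else ""
    infra = (
        word(3, 10)
        if rank in (Rank.subspecies, Rank.variety, Rank.form)
        else ""
    )
    return Name(
        genus=word(3, 10).capitalize(),
        epithet=epithet,
        rank=rank,
        infraspecific_epithet=infra,
        hybrid=rng.random() < 0.1,
        authority=authority,
    )


@pytest.fixture
def classic_reference() -> TaxonSet:
    """Reference set built around the classic homonym/promotion/fuzzy examples."""
    return TaxonSet(
        [
            Taxon(
                parse_name("Glycyrrhiza glabra L."),
                synonyms=[parse_name("Glycyrrhiza glandulifera Ledeb.")],
            ),
            Taxon(
                parse_name("Glycyrrhiza uralensis Fisch."),
                synonyms=[parse_name("Glycyrrhiza glandulifera Boiss.")],
            ),
            Taxon(parse_name("Zea mays L.")),
            Taxon(parse_name("Mucuna holtonii (Kuntze) Moldenke")),
            Taxon(parse_name("Mucuna restonii")),
            Taxon(parse_name("Viscum album L.")),
        ]
    )
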