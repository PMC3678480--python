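"""Parsing and formatting of scientific names and author citations.

Scientific names follow the Linnaean binomial convention: a capitalized
genus, a lowercase specific epithet, optionally an infraspecific rank and
epithet ("Zea mays subsp. mays"), and an author citation ("L.", "(L.) Merr.",
"Ledeb."). Botanical names mark infraspecific ranks explicitly ("subsp.",
"var.", "f."); zoological names write bare trinomials ("Canis lupus lupus").

The authority grammar here is a tolerant tokenizer plus a small state
machine, not a full grammar of either nomenclatural Code: unknown fragments
are attached to the nearest author group and a parse never fails. That
tolerance is deliberate — downstream matching must cope with the citation
styles found in real datasets, not reject them.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field, replace

__all__ = [
    "Rank",
    "AuthorToken",
    "Authority",
    "Name",
    "NameParseError",
    "parse_name",
    "parse_authority",
    "format_name",
]


class Rank(enum.Enum):
    """Taxonomic rank of a parsed name."""

    genus = "genus"
    species = "species"
    subspecies = "subspecies"
    variety = "variety"
    form = "form"


#: Rank markers recognized in botanical-style names.
RANK_MARKERS = {
    "subsp.": Rank.subspecies,
    "ssp.": Rank.subspecies,
    "subsp": Rank.subspecies,
    "ssp": Rank.subspecies,
    "var.": Rank.variety,
    "var": Rank.variety,
    "f.": Rank.form,
    "forma": Rank.form,
}

#: Canonical marker used when formatting.
_FORMAT_MARKER = {
    Rank.subspecies: "subsp.",
    Rank.variety: "var.",
    Rank.form: "f.",
}

# Year window: Linnaean era onward; avoids swallowing page numbers.
_YEAR_MIN, _YEAR_MAX = 1750, 2100

_EPITHET_RE = re.compile(r"[a-z][a-z-]*$")
_GENUS_RE = re.compile(r"[A-Z][a-zA-Z-]*$")
_INITIAL_RE = re.compile(r"[A-Za-z]\.$")
_YEAR_RE = re.compile(r"(\d{4})$")


class NameParseError(ValueError):
    """Raised when a string has no recognizable genus word.

    Carries the offending input as ``.raw``.
    """

    def __init__(self, message: str, raw: str):
        super().__init__(f"{message}: {raw!r}")
        self.raw = raw


@dataclass(frozen=True)
class AuthorToken:
    """One author in a citation: surname, optional initials.

    ``is_abbreviation`` is true when the surname is a standard abbreviation
    ending in a period ("Ledeb.", "L.").
    """

    surname: str
    initials: tuple[str, ...] = ()

    @property
    def is_abbreviation(self) -> bool:
        return self.surname.endswith(".")

    def __str__(self) -> str:
        return " ".join((*self.initials, self.surname))


@dataclass(frozen=True)
class Authority:
    """A parsed author citation.

    ``basionym_authors`` come from a leading parenthesized group ("(L.)"),
    ``ex_authors`` precede an "ex" separator, and ``excluded_authors`` follow
    the qualifier "non" — the botanical convention for *not* the name defined
    by that author, which is treated as positive evidence of non-identity.
    """

    primary_authors: tuple[AuthorToken, ...] = ()
    basionym_authors: tuple[AuthorToken, ...] = ()
    ex_authors: tuple[AuthorToken, ...] = ()
    excluded_authors: tuple[AuthorToken, ...] = ()
    year: int | None = None
    raw: str = ""

    def __bool__(self) -> bool:
        """True when the citation carries any information at all."""
        return bool(
            self.primary_authors
            or self.basionym_authors
            or self.ex_authors
            or self.excluded_authors
            or self.year
        )

    def __str__(self) -> str:
        parts: list[str] = []
        if self.basionym_authors:
            parts.append("(" + " & ".join(map(str, self.basionym_authors)) + ")")
        if self.ex_authors:
            parts.append(" & ".join(map(str, self.ex_authors)))
            parts.append("ex")
        if self.primary_authors:
            parts.append(" & ".join(map(str, self.primary_authors)))
        if self.year is not None:
            parts.append(str(self.year))
        if self.excluded_authors:
            parts.append("non " + " & ".join(map(str, self.excluded_authors)))
        return " ".join(parts)


@dataclass(frozen=True)
class Name:
    """A structured scientific name.

    Invariants: the genus is capitalized; epithets are lowercase
    letters/hyphens; an infraspecific epithet is present exactly when the
    rank is below species.
    """

    genus: str
    epithet: str = ""
    rank: Rank = Rank.species
    infraspecific_epithet: str = ""
    hybrid: bool = False
    authority: Authority = field(default_factory=Authority)
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.genus or not _GENUS_RE.match(self.genus):
            raise ValueError(f"invalid genus: {self.genus!r}")
        below_species = self.rank in (Rank.subspecies, Rank.variety, Rank.form)
        if below_species and not self.infraspecific_epithet:
            raise ValueError(f"rank {self.rank.value} requires an infraspecific epithet")
        if not below_species and self.infraspecific_epithet:
            raise ValueError(f"rank {self.rank.value} forbids an infraspecific epithet")
        if self.rank is Rank.genus and self.epithet:
            raise ValueError("genus-rank name cannot carry an epithet")
        if self.rank is not Rank.genus and not self.epithet:
            raise ValueError(f"rank {self.rank.value} requires an epithet")

    # Equality must ignore the verbatim input; compare structure only.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Name):
            return NotImplemented
        return (
            self.genus == other.genus
            and self.epithet == other.epithet
            and self.rank == other.rank
            and self.infraspecific_epithet == other.infraspecific_epithet
            and self.hybrid == other.hybrid
            and replace(self.authority, raw="") == replace(other.authority, raw="")
        )

    def __hash__(self) -> int:
        return hash(
            (
                self.genus,
                self.epithet,
                self.rank,
                self.infraspecific_epithet,
                self.hybrid,
                replace(self.authority, raw=""),
            )
        )

    @property
    def binomial(self) -> str:
        """The name without its authority ("Zea mays subsp. mays")."""
        return format_name(self, with_authority=False)

    @property
    def parent_binomial(self) -> "Name | None":
        """The parent species of an infraspecific name, else ``None``."""
        if self.rank in (Rank.subspecies, Rank.variety, Rank.form):
            return Name(self.genus, self.epithet, Rank.species, hybrid=self.hybrid)
        return None

    @property
    def is_nominal_infraspecific(self) -> bool:
        """True for autonyms like "Zea mays subsp. mays"."""
        return (
            bool(self.infraspecific_epithet)
            and self.infraspecific_epithet == self.epithet
        )

    def __str__(self) -> str:
        return format_name(self, with_authority=True)


def _normalize(s: str) -> str:
    s = unicodedata.normalize("NFC", s)
    return " ".join(s.split())


def _split_authors(tokens: list[str]) -> tuple[AuthorToken, ...]:
    """Split a token run on author separators and build AuthorTokens.

    Within one author chunk, leading single-letter-with-period tokens are
    initials; everything else joins into the surname ("de Candolle",
    "Hook. f."). A chunk of only initial-shaped tokens keeps the last as
    the surname ("L.").
    """
    groups: list[list[str]] = [[]]
    for tok in tokens:
        stripped = tok.strip(",")
        if stripped.lower() in ("&", "et", "and") or not stripped:
            if groups[-1]:
                groups.append([])
            continue
        groups[-1].append(stripped)
        if tok.endswith(","):
            groups.append([])
    authors = []
    for group in groups:
        if not group:
            continue
        initials: list[str] = []
        rest = list(group)
        while len(rest) > 1 and _INITIAL_RE.match(rest[0]):
            initials.append(rest.pop(0))
        surname = " ".join(rest)
        if surname and not surname.strip(".,()").isdigit():
            authors.append(AuthorToken(surname=surname, initials=tuple(initials)))
    return tuple(authors)


def _extract_year(tokens: list[str]) -> tuple[int | None, list[str]]:
    """Pull the first plausible publication year out of a token list."""
    year: int | None = None
    kept: list[str] = []
    for tok in tokens:
        ym = _YEAR_RE.match(tok.strip(",()"))
        if year is None and ym and _YEAR_MIN <= int(ym.group(1)) <= _YEAR_MAX:
            year = int(ym.group(1))
            continue
        kept.append(tok)
    return year, kept


def parse_authority(raw: str) -> Authority:
    """Parse an author citation into its components.

    Recognizes a leading parenthesized basionym-author group, the "ex"
    separator, the exclusion qualifier "non", and a publication year
    (a 4-digit token in 1750–2100). Never raises: unrecognized fragments
    are kept with the nearest author group.

    >>> parse_authority("(L.) Merr.").basionym_authors[0].surname
    'L.'
    """
    raw = "" if raw is None else raw
    text = _normalize(raw)
    if not text:
        return Authority(raw=raw)

    basionym: tuple[AuthorToken, ...] = ()
    basionym_year: int | None = None
    m = re.match(r"\(([^)]*)\)\s*", text)
    if m:
        basionym_year, kept = _extract_year(m.group(1).split())
        basionym = _split_authors(kept)
        text = text[m.end():]

    # "non X" — everything after the qualifier names the excluded author(s).
    excluded: tuple[AuthorToken, ...] = ()
    nm = re.search(r"(?:^|[\s,])non(?:\s+|$)", text, flags=re.IGNORECASE)
    if nm:
        excluded = _split_authors(text[nm.end():].split())
        text = text[: nm.start()].strip(" ,")
        if not excluded:
            # "non" with nothing usable after it still records the exclusion
            excluded = (AuthorToken(surname="?"),)

    year, kept_tokens = _extract_year(text.split())
    if year is None:
        year = basionym_year

    ex_authors: tuple[AuthorToken, ...] = ()
    lowered = [t.lower() for t in kept_tokens]
    if "ex" in lowered:
        cut = lowered.index("ex")
        ex_authors = _split_authors(kept_tokens[:cut])
        kept_tokens = kept_tokens[cut + 1:]

    primary = _split_authors(kept_tokens)
    return Authority(
        primary_authors=primary,
        basionym_authors=basionym,
        ex_authors=ex_authors,
        excluded_authors=excluded,
        year=year,
        raw=raw,
    )


def _looks_like_epithet(token: str) -> bool:
    """Accept lowercase (or shouting ALL-CAPS data) epithet-shaped tokens.

    A Capitalized mixed-case word after the genus is read as an author
    surname, per citation convention; citation keywords ("non", "ex", …)
    can never be epithets.
    """
    if token.isupper():
        token = token.lower()
    if token in ("non", "ex", "et", "and", "x"):
        return False
    return bool(_EPITHET_RE.match(token))


def parse_name(raw: str, style: str = "botanical") -> Name:
    """Parse a scientific name string, splitting off any author citation.

    ``style`` selects between botanical conventions (infraspecific ranks
    marked "subsp."/"ssp."/"var."/"f.") and zoological ones, where a bare
    lowercase trinomial is read as a subspecies. Hybrid markers ("×" or a
    leading "x ") set ``hybrid`` and are stripped from the name parts.

    Raises :class:`NameParseError` when no genus word can be found.
    """
    if style not in ("botanical", "zoological"):
        raise ValueError(f"unknown style: {style!r}")
    original = raw
    text = _normalize(raw)
    if not text:
        raise NameParseError("empty name", original)

    hybrid = False
    # multiplication sign, possibly fused to the genus, or a leading "x "
    text = text.replace("\N{MULTIPLICATION SIGN}", " \N{MULTIPLICATION SIGN} ")
    tokens = text.split()
    cleaned: list[str] = []
    for i, tok in enumerate(tokens):
        if tok == "\N{MULTIPLICATION SIGN}" or (tok in ("x", "X") and i < 2):
            hybrid = True
            continue
        cleaned.append(tok)
    tokens = cleaned
    if not tokens:
        raise NameParseError("no genus word", original)

    genus = tokens[0]
    if not re.match(r"[A-Za-z][a-zA-Z-]*$", genus):
        raise NameParseError("no recognizable genus word", original)
    genus = genus[0].upper() + genus[1:].lower()
    rest = tokens[1:]

    if not rest or not _looks_like_epithet(rest[0]) or _INITIAL_RE.match(rest[0]):
        # genus-rank name; remainder (if any) is an authority
        return Name(
            genus=genus,
            rank=Rank.genus,
            hybrid=hybrid,
            authority=parse_authority(" ".join(rest)),
            raw=original,
        )

    epithet = rest[0].lower()
    rest = rest[1:]

    rank = Rank.species
    infra = ""
    authority_tokens: list[str] = []

    # find a rank marker anywhere after the epithet; tokens before it are
    # a species-level citation, tokens after the infra epithet the final one
    marker_idx = None
    for i, tok in enumerate(rest):
        if tok.lower() in RANK_MARKERS and i + 1 < len(rest) and _looks_like_epithet(rest[i + 1]):
            marker_idx = i
            break
    if marker_idx is not None:
        rank = RANK_MARKERS[rest[marker_idx].lower()]
        infra = rest[marker_idx + 1].lower()
        authority_tokens = rest[:marker_idx] + rest[marker_idx + 2:]
    elif (
        style == "zoological"
        and rest
        and _looks_like_epithet(rest[0])
        and not _INITIAL_RE.match(rest[0])
    ):
        rank = Rank.subspecies
        infra = rest[0].lower()
        authority_tokens = rest[1:]
    else:
        authority_tokens = rest

    return Name(
        genus=genus,
        epithet=epithet,
        rank=rank,
        infraspecific_epithet=infra,
        hybrid=hybrid,
        authority=parse_authority(" ".join(authority_tokens)),
        raw=original,
    )


def format_name(n: Name, with_authority: bool = True) -> str:
    """Render a Name canonically: "Genus epithet [marker infra] [authority]".

    ``parse_name(format_name(n))`` reproduces ``n`` (up to the verbatim
    ``raw`` field).
    """
    parts = []
    if n.hybrid:
        parts.append("\N{MULTIPLICATION SIGN}")
    parts.append(n.genus)
    if n.epithet:
        parts.append(n.epithet)
    if n.rank in _FORMAT_MARKER:
        parts.append(_FORMAT_MARKER[n.rank])
        parts.append(n.infraspecific_epithet)
    if with_authority and n.authority:
        parts.append(str(n.authority))
    return " ".join(parts)
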