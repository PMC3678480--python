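"""The matching cascade: resolve query names against a reference TaxonSet.

For each query name the steps are tried strictly in order:

1. exact binomial hit whose authority *agrees* with the query's;
2. binomial hit with a neutral (missing-information) or — if allowed —
   disagreeing authority; a candidate whose authority comparison is
   *incompatible* (a "non X" exclusion naming the other side's author) is
   always vetoed;
3. for an infraspecific query with no hit, retry the parent species
   (for all infraspecifics, only nominal ones like "Zea mays subsp. mays",
   or never, per configuration);
4. blocked q-gram fuzzy lookup, then the same authority filtering.

Homonyms — several surviving candidates for one name string — are resolved
by preferring the single candidate reached via an accepted name when the
query carries no authority, by asking a user-supplied callback, or by
reporting the query as ambiguous. Every decision is recorded in a
MatchResult so a run is fully auditable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Sequence

from . import fuzzy_match
from .fuzzy_match import FuzzyConfig, build_index, lookup_fuzzy
from .nomenclature import Authority, AuthorToken, Name, Rank
from .taxa import NameHit, Taxon, TaxonSet, index_key

__all__ = [
    "AuthorityVerdict",
    "MatchConfig",
    "MatchStep",
    "MatchOutcome",
    "Candidate",
    "MatchResult",
    "ConfigError",
    "compare_authorities",
    "match_name",
    "match_dataset",
]


class ConfigError(ValueError):
    """Invalid matcher configuration (e.g. interactive policy, no decider)."""


class AuthorityVerdict(enum.Enum):
    agree = "agree"
    neutral = "neutral"
    disagree = "disagree"
    incompatible = "incompatible"


class MatchStep(enum.Enum):
    exact_with_authority = "exact_with_authority"
    name_only = "name_only"
    infraspecific_promotion = "infraspecific_promotion"
    fuzzy = "fuzzy"


class MatchOutcome(enum.Enum):
    matched = "matched"
    ambiguous = "ambiguous"
    unmatched = "unmatched"
    rejected_by_user = "rejected_by_user"


@dataclass(frozen=True)
class MatchConfig:
    """Tunable knobs of the cascade.

    ``infraspecific_promotion``: "all" promotes every below-species query
    with no hit to its parent species, "nominal_only" promotes only autonyms
    (infraspecific epithet repeating the species epithet), "off" disables
    the step. ``homonym_policy``: "prefer_accepted" auto-picks the single
    accepted-name candidate when the query has no authority, "interactive"
    delegates to a decider callback, "reject" reports every homonym as
    ambiguous.
    """

    allow_authority_mismatch: bool = True
    infraspecific_promotion: str = "nominal_only"
    fuzzy: FuzzyConfig = field(default_factory=FuzzyConfig)
    homonym_policy: str = "prefer_accepted"
    max_fuzzy_candidates: int = 5

    def __post_init__(self) -> None:
        if self.infraspecific_promotion not in ("all", "nominal_only", "off"):
            raise ConfigError(
                f"bad infraspecific_promotion: {self.infraspecific_promotion!r}"
            )
        if self.homonym_policy not in ("prefer_accepted", "interactive", "reject"):
            raise ConfigError(f"bad homonym_policy: {self.homonym_policy!r}")


@dataclass(frozen=True)
class Candidate:
    """One surviving match candidate, with its provenance."""

    taxon: Taxon
    matched_name: Name
    is_accepted: bool
    verdict: AuthorityVerdict
    score: float | None = None


@dataclass
class MatchResult:
    """Outcome of matching one query, with the full decision trail."""

    query: Name
    outcome: MatchOutcome
    matched_taxon: Taxon | None = None
    accepted_name: Name | None = None
    step: MatchStep | None = None
    score: float | None = None
    alternatives: list[Name] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# Decider callback: given (query, candidates) return a Candidate to accept,
# a replacement Name to re-match, or None to reject all options.
Decider = Callable[[Name, Sequence[Candidate]], "Candidate | Name | None"]


def _surname_key(tok: AuthorToken) -> str:
    return tok.surname.rstrip(".").casefold()


def _surnames_match(a: AuthorToken, b: AuthorToken) -> bool:
    """Abbreviation-aware surname comparison: "Ledeb." matches "Ledebour"."""
    sa, sb = _surname_key(a), _surname_key(b)
    if not sa or not sb:
        return False
    if sa == sb:
        return True
    if a.is_abbreviation and sb.startswith(sa):
        return True
    if b.is_abbreviation and sa.startswith(sb):
        return True
    return False


def _author_lists_match(
    xs: Sequence[AuthorToken], ys: Sequence[AuthorToken]
) -> bool:
    """Every author on the shorter list matches one on the longer."""
    short, long_ = (xs, ys) if len(xs) <= len(ys) else (ys, xs)
    return all(any(_surnames_match(s, l) for l in long_) for s in short)


def _initials_conflict(xs: Sequence[AuthorToken], ys: Sequence[AuthorToken]) -> bool:
    """True when matched authors carry initials on both sides that differ."""
    for x in xs:
        for y in ys:
            if _surnames_match(x, y) and x.initials and y.initials:
                if [i.casefold() for i in x.initials] != [
                    i.casefold() for i in y.initials
                ]:
                    return True
    return False


def _effective_authors(a: Authority) -> tuple[AuthorToken, ...]:
    return a.primary_authors or a.ex_authors or a.basionym_authors


def compare_authorities(a: Authority, b: Authority) -> AuthorityVerdict:
    """Compare two author citations the way a taxonomist would.

    *incompatible*: one side's primary or basionym author is named by the
    other side's "non ..." exclusion — explicit evidence the names denote
    different taxa; this verdict vetoes a match unconditionally.
    *neutral*: either citation carries no information. *agree*: primary
    surnames match (abbreviation-aware), with initials and years compared
    only when present on both sides. *disagree*: anything else.
    """
    # exclusion evidence first: it overrides everything
    for left, right in ((a, b), (b, a)):
        if right.excluded_authors:
            positives = left.primary_authors + left.basionym_authors
            for p in positives:
                if any(_surnames_match(p, e) for e in right.excluded_authors):
                    return AuthorityVerdict.incompatible

    if not a or not b:
        return AuthorityVerdict.neutral
    ea, eb = _effective_authors(a), _effective_authors(b)
    if not ea or not eb:
        return AuthorityVerdict.neutral

    if not _author_lists_match(ea, eb):
        return AuthorityVerdict.disagree
    if _initials_conflict(ea, eb):
        return AuthorityVerdict.disagree
    if a.year is not None and b.year is not None and a.year != b.year:
        return AuthorityVerdict.disagree
    if a.basionym_authors and b.basionym_authors:
        if not _author_lists_match(a.basionym_authors, b.basionym_authors):
            return AuthorityVerdict.disagree
    return AuthorityVerdict.agree


def _grade_hits(query: Name, hits: Iterable[NameHit]) -> list[Candidate]:
    out = []
    for hit in hits:
        verdict = compare_authorities(query.authority, hit.name.authority)
        out.append(Candidate(hit.taxon, hit.name, hit.is_accepted, verdict))
    return out


def _resolve_survivors(
    query: Name,
    survivors: list[Candidate],
    step: MatchStep,
    cfg: MatchConfig,
    decider: Decider | None,
    result: MatchResult,
    reference: TaxonSet,
) -> MatchResult | None:
    """Turn surviving candidates into a final result, or None to keep trying.

    Exactly one survivor wins outright. Several survivors are a homonym and
    go through the configured policy.
    """
    if not survivors:
        return None
    if len(survivors) == 1:
        return _accept(result, survivors[0], step)

    result.alternatives = [c.matched_name for c in survivors]
    if cfg.homonym_policy == "prefer_accepted":
        if not query.authority:
            accepted = [c for c in survivors if c.is_accepted]
            if len(accepted) == 1:
                result.notes.append(
                    "homonym: accepted-name candidate preferred over "
                    f"{len(survivors) - 1} synonym hit(s)"
                )
                return _accept(result, accepted[0], step)
        result.outcome = MatchOutcome.ambiguous
        result.step = step
        result.notes.append(f"homonym: {len(survivors)} candidates")
        return result
    if cfg.homonym_policy == "reject":
        result.outcome = MatchOutcome.ambiguous
        result.step = step
        result.notes.append("homonym rejected by policy")
        return result
    # interactive
    if decider is None:
        raise ConfigError("homonym_policy='interactive' requires a decider callback")
    choice = decider(query, survivors)
    if choice is None:
        result.outcome = MatchOutcome.rejected_by_user
        result.step = step
        return result
    if isinstance(choice, Candidate):
        result.notes.append("homonym resolved interactively")
        return _accept(result, choice, step)
    # a replacement Name: restart the cascade with it
    replacement = match_name(choice, reference, cfg, decider)
    replacement.query = query
    replacement.notes.append(f"replacement name supplied: {choice}")
    return replacement


def _accept(result: MatchResult, cand: Candidate, step: MatchStep) -> MatchResult:
    result.outcome = MatchOutcome.matched
    result.matched_taxon = cand.taxon
    result.accepted_name = cand.taxon.name
    result.step = step
    result.score = cand.score
    if cand.verdict is AuthorityVerdict.disagree:
        result.notes.append(
            "authority mismatch accepted: "
            f"query {str(result.query.authority)!r} vs "
            f"reference {str(cand.matched_name.authority)!r}"
        )
    if not cand.is_accepted:
        result.notes.append(f"matched via synonym {cand.matched_name.binomial}")
    return result


def _authority_identical(a: Authority, b: Authority) -> bool:
    """Literal citation identity (canonical formatting, case-insensitive)."""
    return str(a).casefold() == str(b).casefold()


def _binomial_steps(
    query: Name,
    reference: TaxonSet,
    cfg: MatchConfig,
    decider: Decider | None,
    result: MatchResult,
    step_exact: MatchStep,
    step_name_only: MatchStep,
) -> MatchResult | None:
    """Steps 1–2 for one binomial.

    Step 1 demands a literally identical author citation ("an exact match,
    including the authority"). Step 2 takes any binomial hit but grades the
    citations with the bespoke comparator: agreeing candidates outrank
    neutral and (if allowed) disagreeing ones, and incompatible candidates
    are vetoed outright. The tiering is what lets a citation like "Ledeb"
    single out the right homonym among several same-named synonyms.
    """
    candidates = _grade_hits(query, reference.get_by_binomial(query))
    vetoed = [c for c in candidates if c.verdict is AuthorityVerdict.incompatible]
    for c in vetoed:
        result.notes.append(
            f"candidate {c.matched_name} vetoed: authorities incompatible"
        )
    candidates = [c for c in candidates if c.verdict is not AuthorityVerdict.incompatible]

    exact = [
        c for c in candidates
        if _authority_identical(query.authority, c.matched_name.authority)
    ]
    res = _resolve_survivors(query, exact, step_exact, cfg, decider, result, reference)
    if res is not None:
        return res

    tiers = [
        [c for c in candidates if c.verdict is AuthorityVerdict.agree],
        [c for c in candidates if c.verdict is AuthorityVerdict.neutral]
        + (
            [c for c in candidates if c.verdict is AuthorityVerdict.disagree]
            if cfg.allow_authority_mismatch
            else []
        ),
    ]
    for tier in tiers:
        res = _resolve_survivors(
            query, tier, step_name_only, cfg, decider, result, reference
        )
        if res is not None:
            return res
    return None


def _fuzzy_index_for(reference: TaxonSet, fuzzy_cfg: FuzzyConfig):
    """Build (and cache on the TaxonSet) the fuzzy index of all its names."""
    cache = getattr(reference, "_fuzzy_cache", None)
    if cache is not None and cache[0] == fuzzy_cfg:
        return cache[1]
    index = build_index(reference.names(), fuzzy_cfg)
    reference._fuzzy_cache = (fuzzy_cfg, index)  # type: ignore[attr-defined]
    return index


def match_name(
    query: Name,
    reference: TaxonSet,
    cfg: MatchConfig | None = None,
    decider: Decider | None = None,
) -> MatchResult:
    """Match one query name against the reference, trying the cascade in order."""
    cfg = cfg or MatchConfig()
    if cfg.homonym_policy == "interactive" and decider is None:
        raise ConfigError("homonym_policy='interactive' requires a decider callback")
    result = MatchResult(query=query, outcome=MatchOutcome.unmatched)

    res = _binomial_steps(
        query, reference, cfg, decider, result,
        MatchStep.exact_with_authority, MatchStep.name_only,
    )
    if res is not None:
        return res

    # step 3: infraspecific promotion to the parent species
    parent = query.parent_binomial
    if parent is not None and cfg.infraspecific_promotion != "off":
        if cfg.infraspecific_promotion == "all" or query.is_nominal_infraspecific:
            promoted = replace(parent, authority=query.authority)
            result.notes.append(f"promoted to parent species {parent.binomial}")
            res = _binomial_steps(
                promoted, reference, cfg, decider, result,
                MatchStep.infraspecific_promotion, MatchStep.infraspecific_promotion,
            )
            if res is not None:
                res.query = query
                return res
            del result.notes[-1]

    # step 4: blocked fuzzy lookup over every indexed name string
    index = _fuzzy_index_for(reference, cfg.fuzzy)
    ranked = lookup_fuzzy(index, query.binomial, cfg.fuzzy)
    for name_str, score in ranked[: cfg.max_fuzzy_candidates]:
        hits = reference.get_by_binomial(name_str)
        cands = [
            replace(c, score=score)
            for c in _grade_hits(query, hits)
            if c.verdict is not AuthorityVerdict.incompatible
        ]
        tiers = [
            [c for c in cands if c.verdict is AuthorityVerdict.agree],
            [c for c in cands if c.verdict is AuthorityVerdict.neutral]
            + (
                [c for c in cands if c.verdict is AuthorityVerdict.disagree]
                if cfg.allow_authority_mismatch
                else []
            ),
        ]
        for tier in tiers:
            res = _resolve_survivors(
                query, tier, MatchStep.fuzzy, cfg, decider, result, reference
            )
            if res is not None:
                return res

    result.outcome = MatchOutcome.unmatched
    return result


def match_dataset(
    queries: Sequence[tuple[Name, dict[str, Any]]],
    reference: TaxonSet,
    cfg: MatchConfig | None = None,
    decider: Decider | None = None,
) -> tuple[TaxonSet, list[MatchResult]]:
    """Match a whole dataset, regrouping records under accepted names.

    Each matched query's data mapping is attached to its accepted taxon in
    the output set (synonymous queries therefore merge); unmatched and
    ambiguous queries appear only in the result log, which follows input
    order.
    """
    cfg = cfg or MatchConfig()
    out = TaxonSet()
    by_key: dict[str, Taxon] = {}
    results: list[MatchResult] = []
    for query, data in queries:
        result = match_name(query, reference, cfg, decider)
        results.append(result)
        if result.outcome is not MatchOutcome.matched:
            continue
        accepted = result.accepted_name
        assert accepted is not None
        key = index_key(accepted) + "|" + str(accepted.authority)
        taxon = by_key.get(key)
        if taxon is None:
            taxon = Taxon(name=accepted)
            by_key[key] = taxon
            out.add(taxon)
        taxon.data.update(data)
    return out, results
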