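"""Synthetic reference synonymies and corrupted query lists, with scoring.

The generator builds pronounceable pseudo-Latin binomials from syllable
templates (so q-gram statistics and prefix-bucket occupancy resemble real
names), attaches author citations and synonyms, and can inject homonyms —
one synonym string shared between two taxa under different authorities.

Query corruption emulates the failure modes that plague real name lists:

* typos — one random substitution/deletion/insertion, never in the first
  three characters of the binomial (errors there defeat prefix blocking by
  construction; a diagnostic flag allows them to quantify that loss);
* gender swaps — the Latin adjective endings -a/-um/-us permuted, the
  classic "Viscum alba" for "Viscum album" confusion;
* synonym use — the query cites a synonym instead of the accepted name;
* authority drops — the citation is simply missing.

Ground truth is carried alongside every query, so a matching run can be
scored exactly (precision, recall, and a histogram of cascade steps).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from .nomenclature import Authority, Name, Rank, parse_authority
from .resolver import MatchOutcome, MatchResult
from .taxa import Taxon, TaxonSet

__all__ = [
    "CorruptionConfig",
    "generate_reference",
    "corrupt_queries",
    "score_matching",
]

_ONSETS = "b c d f g l m n p r s t v br cr dr gr pl pr st tr ch th".split()
_VOWELS = "a e i o u ae".split()
_CODAS = ["", "", "", "n", "r", "s", "x"]
_EPITHET_ENDINGS = ["a", "um", "us", "is", "ii", "ens", "ata", "osa"]
_GENDER_ENDINGS = ("a", "um", "us")


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-name corruption probabilities; ``seed`` fixes all randomness."""

    typo_rate: float = 0.0
    gender_swap_rate: float = 0.0
    synonym_use_rate: float = 0.0
    authority_drop_rate: float = 0.0
    homonym_count: int = 0
    seed: int = 0
    allow_blocked_typos: bool = False  # diagnostic: typos in the first 3 chars

    def __post_init__(self) -> None:
        for name in ("typo_rate", "gender_swap_rate", "synonym_use_rate",
                     "authority_drop_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS)


def _word(rng: random.Random, n_syllables: int, ending: str = "") -> str:
    word = "".join(_syllable(rng) for _ in range(n_syllables))
    if not ending:
        ending = rng.choice(_CODAS)
    return word + ending


def _surname(rng: random.Random) -> str:
    name = _word(rng, rng.randint(2, 3)).capitalize()
    if rng.random() < 0.5:
        cut = rng.randint(3, max(3, len(name) - 1))
        return name[:cut] + "."
    return name


def _authority(rng: random.Random) -> Authority:
    parts = [_surname(rng)]
    if rng.random() < 0.2:
        parts.append("& " + _surname(rng))
    if rng.random() < 0.3:
        parts.append(str(rng.randint(1753, 2012)))
    return parse_authority(" ".join(parts))


def _binomial(rng: random.Random) -> Name:
    genus = _word(rng, rng.randint(2, 3), ending=rng.choice(["a", "um", "us", "ia", "on"]))
    epithet = _word(rng, rng.randint(2, 3), ending=rng.choice(_EPITHET_ENDINGS))
    return Name(
        genus=genus.capitalize(),
        epithet=epithet,
        rank=Rank.species,
        authority=_authority(rng),
    )


def generate_reference(
    n_taxa: int,
    synonyms_per_taxon: int = 0,
    seed: int = 0,
    homonym_count: int = 0,
) -> TaxonSet:
    """Generate a deterministic synthetic reference synonymy.

    ``homonym_count`` taxon pairs additionally share one synonym *string*
    under different authorities — the classic homonym trap.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = random.Random(seed)
    taxa: list[Taxon] = []
    used_binomials: set[str] = set()
    while len(taxa) < n_taxa:
        name = _binomial(rng)
        if name.binomial in used_binomials:
            continue
        used_binomials.add(name.binomial)
        synonyms = []
        for _ in range(synonyms_per_taxon):
            syn = _binomial(rng)
            if syn.binomial not in used_binomials:
                used_binomials.add(syn.binomial)
                synonyms.append(syn)
        taxa.append(Taxon(name=name, synonyms=synonyms))

    rng2 = random.Random(seed + 1)
    pairs = min(homonym_count, len(taxa) // 2)
    for i in range(pairs):
        a, b = taxa[2 * i], taxa[2 * i + 1]
        shared = _binomial(rng2)
        a.synonyms.append(replace(shared, authority=_authority(rng2)))
        b.synonyms.append(replace(shared, authority=_authority(rng2)))
    return TaxonSet(taxa)


def _typo(word: str, rng: random.Random, min_pos: int) -> str:
    """One random substitution/deletion/insertion at position >= min_pos."""
    if len(word) <= min_pos:
        return word
    pos = rng.randrange(min_pos, len(word))
    op = rng.choice(["sub", "del", "ins"])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if op == "sub":
        repl = rng.choice([c for c in alphabet if c != word[pos].lower()])
        return word[:pos] + repl + word[pos + 1 :]
    if op == "del" and len(word) > min_pos + 1:
        return word[:pos] + word[pos + 1 :]
    return word[:pos] + rng.choice(alphabet) + word[pos:]


def _gender_swap(epithet: str, rng: random.Random) -> str:
    for ending in _GENDER_ENDINGS:
        if epithet.endswith(ending) and len(epithet) > len(ending) + 2:
            stem = epithet[: -len(ending)]
            other = rng.choice([e for e in _GENDER_ENDINGS if e != ending])
            return stem + other
    return epithet


def corrupt_queries(
    ts: TaxonSet, cfg: CorruptionConfig
) -> list[tuple[Name, Name]]:
    """One (query, true accepted name) pair per taxon in the reference.

    Each corruption is applied independently at its configured rate. Typos
    hit the epithet only, so the binomial's first three characters — the
    blocking key — are untouched unless ``allow_blocked_typos`` asks for
    the genus head to be fair game too.
    """
    if len(ts) == 0:
        raise ValueError("reference TaxonSet is empty")
    out: list[tuple[Name, Name]] = []
    for i, taxon in enumerate(ts):
        # One RNG stream per query, so changing one corruption rate never
        # perturbs the draws of other queries or of other corruption kinds
        # (degradation stays monotone in each rate).
        rng = random.Random(f"{cfg.seed}:{i}")
        u_syn, u_gender, u_typo, u_auth = (rng.random() for _ in range(4))
        query = taxon.name
        if taxon.synonyms and u_syn < cfg.synonym_use_rate:
            query = rng.choice(taxon.synonyms)
        genus, epithet = query.genus, query.epithet
        if u_gender < cfg.gender_swap_rate:
            epithet = _gender_swap(epithet, rng)
        if u_typo < cfg.typo_rate:
            if cfg.allow_blocked_typos and rng.random() < 0.5:
                genus = _typo(genus, rng, 0)
                genus = genus[0].upper() + genus[1:].lower() if genus else genus
            else:
                epithet = _typo(epithet, rng, 0)
        authority = query.authority
        if u_auth < cfg.authority_drop_rate:
            authority = Authority()
        corrupted = Name(
            genus=genus,
            epithet=epithet,
            rank=query.rank,
            infraspecific_epithet=query.infraspecific_epithet,
            hybrid=query.hybrid,
            authority=authority,
        )
        out.append((corrupted, taxon.name))
    return out


def score_matching(
    results: Sequence[MatchResult], truth: Sequence[Name]
) -> dict:
    """Precision, recall and a cascade-step histogram for a benchmark run.

    ``precision`` = correct matches / all matches; ``recall`` = correct
    matches / all queries; a match is correct when the resolved accepted
    name equals the true one (authority included).
    """
    if len(results) != len(truth):
        raise ValueError(
            f"results ({len(results)}) and truth ({len(truth)}) differ in length"
        )
    n_matched = 0
    n_correct = 0
    histogram: dict[str, int] = {}
    for result, true_name in zip(results, truth):
        if result.outcome is not MatchOutcome.matched:
            continue
        n_matched += 1
        step = result.step.value if result.step else "?"
        histogram[step] = histogram.get(step, 0) + 1
        if result.accepted_name == true_name:
            n_correct += 1
    return {
        "n_queries": len(results),
        "n_matched": n_matched,
        "n_correct": n_correct,
        "precision": n_correct / n_matched if n_matched else 0.0,
        "recall": n_correct / len(results) if results else 0.0,
        "step_histogram": histogram,
    }
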