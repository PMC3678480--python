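"""Front-padded q-gram string similarity and a blocked fuzzy index.

A name is broken into overlapping chunks of ``q`` letters after prepending
``q - 1`` padding characters; no trailing pads are added, which deliberately
down-weights the word ending, where the spelling of Latin names most often
varies (gender endings, -i vs -ii). "Mucuna holtoni" thus yields the grams
'∧∧M', '∧Mu', 'Muc', 'ucu', … and the similarity between two names is the
Jaccard ratio of their gram sets. "Mucuna holtoni" vs "Mucuna holtonii"
shares 14 of 15 grams: 93%.

Lookups are blocked: only names whose first ``q`` characters match the
query's (case-insensitively) are compared, which keeps scans over large
reference synonymies fast at the cost of missing matches whose error falls
in the first three characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FuzzyConfig",
    "QGramSet",
    "FuzzyIndex",
    "qgrams",
    "gram_sequence",
    "similarity",
    "build_index",
    "lookup_fuzzy",
]

#: Padding sentinel; does not occur in normalized scientific names.
PAD_CHAR = "\N{LOGICAL AND}"  # ∧


@dataclass(frozen=True)
class FuzzyConfig:
    """Parameters of the q-gram comparison.

    ``n_front_pads`` must equal ``q - 1`` so every leading character
    participates in ``q`` grams; the acceptance ``threshold`` is inclusive.
    """

    q: int = 3
    n_front_pads: int = 2
    threshold: float = 0.70
    pad_char: str = PAD_CHAR

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.n_front_pads != self.q - 1:
            raise ValueError("n_front_pads must equal q - 1")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if len(self.pad_char) != 1:
            raise ValueError("pad_char must be a single character")


DEFAULT_CONFIG = FuzzyConfig()


@dataclass(frozen=True)
class QGramSet:
    """The q-gram decomposition of one string (set semantics)."""

    grams: frozenset[str]
    source: str

    def __len__(self) -> int:
        return len(self.grams)


def qgrams(s: str, cfg: FuzzyConfig = DEFAULT_CONFIG) -> QGramSet:
    """Decompose ``s`` into its set of front-padded q-grams.

    Case is preserved here (the printed decomposition of a name keeps its
    capital); :func:`similarity` case-folds before calling this. The empty
    string yields an empty set.
    """
    if not s:
        return QGramSet(frozenset(), s)
    padded = cfg.pad_char * cfg.n_front_pads + s
    grams = frozenset(
        padded[i : i + cfg.q] for i in range(len(padded) - cfg.q + 1)
    )
    return QGramSet(grams, s)


def gram_sequence(s: str, cfg: FuzzyConfig = DEFAULT_CONFIG) -> list[str]:
    """The q-grams of ``s`` in positional order (duplicates retained)."""
    if not s:
        return []
    padded = cfg.pad_char * cfg.n_front_pads + s
    return [padded[i : i + cfg.q] for i in range(len(padded) - cfg.q + 1)]


def similarity(a: str, b: str, cfg: FuzzyConfig = DEFAULT_CONFIG) -> float:
    """Jaccard similarity of the two names' q-gram sets, in [0, 1].

    Symmetric; 1.0 exactly when the (case-folded) gram sets coincide;
    0.0 if either string is empty.
    """
    if not a or not b:
        return 0.0
    ga = qgrams(a.casefold(), cfg).grams
    gb = qgrams(b.casefold(), cfg).grams
    if not ga and not gb:
        return 0.0
    return len(ga & gb) / len(ga | gb)


def _block_key(s: str, cfg: FuzzyConfig) -> str:
    return s.casefold()[: cfg.q]


@dataclass
class FuzzyIndex:
    """Names bucketed by their first ``q`` characters, grams precomputed."""

    cfg: FuzzyConfig = field(default_factory=FuzzyConfig)
    buckets: dict[str, list[tuple[str, frozenset[str]]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(b) for b in self.buckets.values())


def build_index(names, cfg: FuzzyConfig = DEFAULT_CONFIG) -> FuzzyIndex:
    """Index ``names`` for blocked fuzzy lookup."""
    index = FuzzyIndex(cfg=cfg)
    for name in names:
        if not name:
            continue
        key = _block_key(name, cfg)
        entry = (name, qgrams(name.casefold(), cfg).grams)
        index.buckets.setdefault(key, []).append(entry)
    return index


def lookup_fuzzy(
    index: FuzzyIndex, query: str, cfg: FuzzyConfig | None = None
) -> list[tuple[str, float]]:
    """All indexed names in the query's block scoring >= the threshold.

    Sorted by descending score, ties broken by name; empty when the block
    has no candidates. The first ``q`` characters of the query must match a
    candidate exactly (case-insensitively) for it to be considered at all.
    """
    if not query:
        return []
    cfg = index.cfg if cfg is None else cfg
    qset = qgrams(query.casefold(), cfg).grams
    results: list[tuple[str, float]] = []
    for name, grams in index.buckets.get(_block_key(query, cfg), ()):
        if not qset and not grams:
            continue
        score = len(qset & grams) / len(qset | grams)
        if score >= cfg.threshold:
            results.append((name, score))
    results.sort(key=lambda pair: (-pair[1], pair[0]))
    return results
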