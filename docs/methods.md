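# Methods

## Name model

A scientific name is parsed into genus, specific epithet, rank, optional
infraspecific epithet, hybrid flag, and author citation. Botanical style
recognizes the rank markers `subsp.`/`ssp.`, `var.` and `f.`/`forma`;
zoological style additionally reads a bare lowercase trinomial as a
subspecies (the codes differ mainly in citation format, and this is the one
operational difference the parser needs). Normalization: Unicode NFC,
genus title-cased, epithets lower-cased; the multiplication sign `×` (or a
leading `x `) sets the hybrid flag and is stripped from the name parts. A
Capitalized mixed-case word after the genus is read as the start of the
citation, per convention; fully upper-case input (`ZEA MAYS`) is folded.
The verbatim input is preserved in a `raw` field for logs but ignored by
equality, so `format → parse` is the identity on structured names.

The citation grammar is a tolerant tokenizer plus a small state machine,
deliberately not a full grammar of either nomenclatural Code: a leading
parenthesized group gives the basionym authors, `ex` separates the
publishing from the validating authors, `non` marks excluded authors, and a
4-digit token in 1750–2100 is a publication year (the lower bound is the
start of Linnaean nomenclature; the window avoids swallowing page numbers).
Unrecognized fragments attach to the nearest author group and a parse never
fails — matching must tolerate the citation styles found in real data.
Validation against the standard author-abbreviation list is out of scope.

## Citation comparison

Two citations compare to one of four verdicts. **incompatible**: one side's
primary or basionym author is named by the other's `non` exclusion — the
only verdict treated as positive evidence of non-identity, and it vetoes a
candidate at every cascade step. **neutral**: either side carries no
information. **agree**: primary surnames match pairwise, where an
abbreviation matches any surname it prefixes (`Ledeb.` ≡ `Ledebour`);
initials and years are compared only when present on both sides, and the
author list lengths may differ (`Hook. & Arn.` agrees with `Hook.`).
**disagree**: everything else. Abbreviation-prefix matching is permissive
by design (`L.` would match any L-surname); the cascade tolerates this
because agreement is only used to *rank* same-binomial candidates, never to
overrule an exclusion.

## The cascade

Steps run strictly in order; the first that produces a result wins.

1. *exact_with_authority* — a candidate whose canonical citation string is
   literally identical (case-insensitive) to the query's. Identity, not
   mere agreement: `Ledeb` vs `Ledeb.` is not exact.
2. *name_only* — all same-binomial candidates, graded by the comparator in
   two tiers: agreeing citations outrank neutral ones, and disagreeing
   candidates are admitted (with a warning note in the result) only while
   `allow_authority_mismatch` is true. Incompatible candidates are removed
   before tiering.
3. *infraspecific_promotion* — a below-species query with no hit retries as
   its parent binomial, carrying its citation along. Policy `nominal_only`
   (default) promotes only autonyms (infraspecific epithet repeating the
   species epithet); `all` promotes every trinomial, `off` disables the
   step. Varieties and forms follow the same switch as subspecies.
4. *fuzzy* — blocked q-gram lookup over every indexed name string;
   candidate names are visited in descending score order (ties broken
   lexicographically for determinism), and the first name whose candidates
   survive the same authority tiering as step 2 wins. The similarity score
   is recorded in the result.

Homonyms — several candidates surviving one tier — go through the homonym
policy. `prefer_accepted` (default) auto-picks a candidate only when the
query has no citation *and* exactly one candidate was reached via an
accepted name (a citation-less query gives no other basis to choose; with
several accepted candidates the query is reported ambiguous).
`interactive` delegates to a caller-supplied callback, which may pick a
candidate, supply a replacement name (re-entering the cascade), or reject
all; configuring it without a callback is an error, and the CLI's
`--non-interactive` maps it to rejection for scriptability. `reject`
reports every homonym as ambiguous. With the default policy the whole
pipeline is deterministic: identical inputs give byte-identical outputs.

## Q-gram similarity

Names are case-folded, prefixed with `q − 1` pad characters (`∧`, a
sentinel absent from normalized names) and cut into overlapping chunks of
`q = 3`; no trailing pads are added, so the ending — where Latin spelling
varies most (gender endings, `-i`/`-ii`) — contributes fewer chunks.
Chunks form a *set* (duplicates collapse), and similarity is the Jaccard
ratio: intersection over union. On the canonical example, `Mucuna holtoni`
vs `Mucuna holtonii` share 14 chunks of 15 in the union — 93%. Jaccard was
chosen over Dice (which gives 96.6% here) and over
proportion-of-the-shorter-string (100%) because it is a true metric
complement and gives the sensible graded behavior on single-letter
variants. Similarity is computed on the whole `Genus epithet` string, not
per word. The acceptance threshold (default 0.70) is inclusive. Blocking
on the first three characters makes lookups fast but unable to recover an
error inside those characters; that trade-off is measured, not hidden (see
the benchmark's `allow_blocked_typos` diagnostic).

## Data model and I/O

A taxon holds one accepted name (as defined by whichever reference source
it came from), a duplicate-free synonym list, an arbitrary data mapping and
an optional distribution code set. A TaxonSet indexes every name by its
case-folded binomial *without* the authority, so homonyms collide by
design and are disambiguated by the cascade, not the index. Adding the
same accepted binomial twice is an error only when the authority is also
the same; merging collections (`combine`) unions synonyms and data, with
later sets winning data-key collisions (each collision logged).

CSV reading takes a column map (name column; optional separate authority
column, else the citation is split out of the name field; optional synonym
columns; remaining columns become data). Reading is total: an unparseable
name yields an explicit skip record so row counts are conserved. Stores
persist as versioned JSON (`format: taxonmatch-taxa, version: 1`);
`save → load` is the identity, including nested data values. The match log
is a fixed-column CSV (original name/authority, matched accepted
name/authority, step, score, outcome, alternatives, notes), one row per
query in input order.

## Regions

A region index maps normalized names (case-folded, diacritics stripped),
aliases and named groups to sets of canonical codes at one level of a
scheme. The table format is scheme-agnostic CSV
(`code,name,level,aliases,groups`); aliases may target their own row's code
or explicit codes (`Islandia=ISL+SKE`, how one country maps onto several
level-3 units), and explicit targets are integrity-checked at load. The
full TDWG level 1–4 tables are not bundled — the loader accepts any
user-supplied extract — and a 12-region synthetic demo scheme ships for
tests and examples. Unknown names resolve to the empty set and are
reported, deduplicated, in input order; standardization is idempotent on
already-canonical code lists and monotone in its input.

## Synthetic benchmark

The generator builds pseudo-Latin binomials from syllable templates
(onset+vowel syllables, Latin adjective endings), so chunk statistics and
prefix-bucket occupancy resemble real names, with citations (abbreviated
surnames, occasional second authors and years), per-taxon synonyms, and
optionally injected homonym pairs sharing one synonym string under
different authorities. Corruption models the documented failure modes,
each applied independently per query at a configured rate: single-edit
typos (substitution/deletion/insertion), gender-ending swaps
(`-a`/`-um`/`-us` permuted), citing a synonym instead of the accepted name,
and dropping the citation. Typos are applied to the epithet, which always
begins after the genus's three leading characters, so the blocking key
stays intact; errors in the first three characters are unmatchable by
design and can be switched on (`allow_blocked_typos`) to quantify exactly
that loss. Genus-internal typos beyond the third character are not
modeled. Each query draws from its own seeded RNG stream, so changing one
rate never perturbs other queries' draws and recall degrades monotonically
as a rate rises.

Scoring: precision = correct / matched, recall = correct / queries, where
correct means the resolved accepted name equals the ground truth
(authority included), plus a histogram of cascade steps. With all rates at
zero the cascade must recover every query at *exact_with_authority* with
precision = recall = 1, and the default test sizes (60–100 taxa, 5 seeds
for rate sweeps) keep the whole suite under a few seconds while leaving
bucket collisions and homonyms well represented.

What the benchmark does *not* emulate: OCR-specific error distributions,
rank-marker corruption, citation misspellings, or reference synonymies
with internal inconsistencies. Passing it shows the cascade and its
bookkeeping are correct under the modeled error processes, not that any
particular real dataset will reach a given recall.

## Known limitations

- Citation parsing is heuristic; exotic multi-part citations (nested
  parentheses, `in`-attributions) are retained but not structured.
- Abbreviation-prefix author matching can over-agree on very short
  abbreviations; it never overrides a `non` exclusion.
- Fuzzy matching cannot recover errors in a name's first three characters
  (the blocking key), nor in the genus beyond them when only the default
  corruption model is considered.
- The JSON store schema is this package's own; compatibility with other
  tools' formats is a non-goal.
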