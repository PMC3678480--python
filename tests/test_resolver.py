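"""The matching cascade: step order, authority verdicts, homonym policies."""

import pytest

from taxonmatch import (
    AuthorityVerdict,
    MatchConfig,
    MatchOutcome,
    MatchStep,
    Taxon,
    TaxonSet,
    compare_authorities,
    match_dataset,
    match_name,
    parse_authority,
    parse_name,
    similarity,
)
from taxonmatch.resolver import ConfigError, FuzzyConfig


class TestCompareAuthorities:
    @pytest.mark.parametrize(
        "a, b, verdict",
        [
            ("Vahl", "non Vahl", AuthorityVerdict.incompatible),
            ("Ledeb", "Ledeb.", AuthorityVerdict.agree),
            ("Ledeb.", "Ledebour", AuthorityVerdict.agree),
            ("", "L.", AuthorityVerdict.neutral),
            ("Hook.", "Arn.", AuthorityVerdict.disagree),
            ("Hook. & Arn.", "Hook.", AuthorityVerdict.agree),
            ("Sm. 1820", "Sm. 1850", AuthorityVerdict.disagree),
            ("Sm. 1820", "Sm.", AuthorityVerdict.agree),
            ("A. Sm.", "B. Sm.", AuthorityVerdict.disagree),
            ("A. Sm.", "Sm.", AuthorityVerdict.agree),
            ("(L.) Merr.", "Merr.", AuthorityVerdict.agree),
            ("(Vahl) DC.", "non Vahl", AuthorityVerdict.incompatible),
        ],
    )
    def test_verdicts(self, a, b, verdict):
        assert compare_authorities(parse_authority(a), parse_authority(b)) is verdict

    def test_symmetric_incompatibility(self):
        va, nv = parse_authority("Vahl"), parse_authority("non Vahl")
        assert compare_authorities(nv, va) is AuthorityVerdict.incompatible


class TestCascade:
    def test_homonym_resolved_by_authority(self, classic_reference):
        result = match_name(parse_name("Glycyrrhiza glandulifera Ledeb"), classic_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.step is MatchStep.name_only
        assert result.accepted_name.binomial == "Glycyrrhiza glabra"

    def test_nominal_subspecies_promoted(self, classic_reference):
        result = match_name(parse_name("Zea mays subsp. mays"), classic_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.step is MatchStep.infraspecific_promotion
        assert result.accepted_name.binomial == "Zea mays"

    def test_non_nominal_subspecies_not_promoted_under_nominal_only(
        self, classic_reference
    ):
        result = match_name(parse_name("Zea mays subsp. parviglumis"), classic_reference)
        assert result.outcome is MatchOutcome.unmatched
        cfg = MatchConfig(infraspecific_promotion="all")
        result = match_name(parse_name("Zea mays subsp. parviglumis"), classic_reference, cfg)
        assert result.step is MatchStep.infraspecific_promotion

    def test_promotion_off(self, classic_reference):
        cfg = MatchConfig(infraspecific_promotion="off")
        result = match_name(parse_name("Zea mays subsp. mays"), classic_reference, cfg)
        assert result.outcome is MatchOutcome.unmatched

    def test_fuzzy_worked_example(self, classic_reference):
        result = match_name(parse_name("Mucuna holtoni"), classic_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.step is MatchStep.fuzzy
        assert result.score == pytest.approx(14 / 15)
        assert result.accepted_name.binomial == "Mucuna holtonii"

    def test_fuzzy_gender_confusion(self, classic_reference):
        result = match_name(parse_name("Viscum alba"), classic_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.step is MatchStep.fuzzy
        assert result.score == pytest.approx(similarity("Viscum alba", "Viscum album"))

    def test_exact_step_always_preferred(self, classic_reference):
        """An identical binomial+citation wins regardless of configuration."""
        for cfg in (
            MatchConfig(),
            MatchConfig(allow_authority_mismatch=False),
            MatchConfig(infraspecific_promotion="off", homonym_policy="reject"),
        ):
            result = match_name(parse_name("Zea mays L."), classic_reference, cfg)
            assert result.step is MatchStep.exact_with_authority

    def test_incompatible_authority_vetoes(self):
        reference = TaxonSet(
            [
                Taxon(
                    parse_name("Carex fusca All."),
                    synonyms=[parse_name("Carex acuta non Vahl")],
                )
            ]
        )
        for cfg in (MatchConfig(), MatchConfig(allow_authority_mismatch=True)):
            result = match_name(parse_name("Carex acuta Vahl"), reference, cfg)
            assert result.outcome is MatchOutcome.unmatched
            assert any("vetoed" in n for n in result.notes)

    def test_disagreeing_authority_accepted_with_note(self, classic_reference):
        result = match_name(parse_name("Zea mays Mill."), classic_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.step is MatchStep.name_only
        assert any("authority mismatch" in n for n in result.notes)

    def test_disagreeing_authority_rejected_when_disallowed(self, classic_reference):
        cfg = MatchConfig(allow_authority_mismatch=False)
        result = match_name(parse_name("Zea mays Mill."), classic_reference, cfg)
        assert result.outcome is MatchOutcome.unmatched

    def test_fuzzy_threshold_one_rejects_misspelling(self, classic_reference):
        cfg = MatchConfig(fuzzy=FuzzyConfig(threshold=1.0))
        result = match_name(parse_name("Mucuna holtoni"), classic_reference, cfg)
        assert result.outcome is MatchOutcome.unmatched


@pytest.fixture
def homonym_accepted_reference() -> TaxonSet:
    """One accepted name colliding with another taxon's synonym."""
    return TaxonSet(
        [
            Taxon(parse_name("Bromus secalinus L.")),
            Taxon(
                parse_name("Bromus hordeaceus L."),
                synonyms=[parse_name("Bromus secalinus Gaudin")],
            ),
        ]
    )


class TestHomonymPolicies:
    def test_prefer_accepted_without_authority(self, homonym_accepted_reference):
        result = match_name(parse_name("Bromus secalinus"), homonym_accepted_reference)
        assert result.outcome is MatchOutcome.matched
        assert result.accepted_name.binomial == "Bromus secalinus"
        assert len(result.alternatives) == 2

    def test_two_accepted_candidates_are_ambiguous(self):
        reference = TaxonSet(
            [
                Taxon(parse_name("Bromus secalinus L.")),
                Taxon(parse_name("Bromus secalinus Gaudin")),
            ]
        )
        result = match_name(parse_name("Bromus secalinus"), reference)
        assert result.outcome is MatchOutcome.ambiguous
        assert len(result.alternatives) == 2

    def test_reject_policy(self, homonym_accepted_reference):
        cfg = MatchConfig(homonym_policy="reject")
        result = match_name(
            parse_name("Bromus secalinus"), homonym_accepted_reference, cfg
        )
        assert result.outcome is MatchOutcome.ambiguous

    def test_interactive_requires_decider(self, homonym_accepted_reference):
        cfg = MatchConfig(homonym_policy="interactive")
        with pytest.raises(ConfigError):
            match_name(parse_name("Bromus secalinus"), homonym_accepted_reference, cfg)

    def test_interactive_pick(self, homonym_accepted_reference):
        cfg = MatchConfig(homonym_policy="interactive")

        def decider(query, candidates):
            return next(c for c in candidates if not c.is_accepted)

        result = match_name(
            parse_name("Bromus secalinus"), homonym_accepted_reference, cfg, decider
        )
        assert result.outcome is MatchOutcome.matched
        assert result.accepted_name.binomial == "Bromus hordeaceus"

    def test_interactive_reject_all(self, homonym_accepted_reference):
        cfg = MatchConfig(homonym_policy="interactive")
        result = match_name(
            parse_name("Bromus secalinus"),
            homonym_accepted_reference,
            cfg,
            lambda q, cands: None,
        )
        assert result.outcome is MatchOutcome.rejected_by_user

    def test_interactive_replacement_name(self, homonym_accepted_reference):
        cfg = MatchConfig(homonym_policy="interactive")
        result = match_name(
            parse_name("Bromus secalinus"),
            homonym_accepted_reference,
            cfg,
            lambda q, cands: parse_name("Bromus hordeaceus L."),
        )
        assert result.outcome is MatchOutcome.matched
        assert result.accepted_name.binomial == "Bromus hordeaceus"
        assert any("replacement" in n for n in result.notes)


class TestMatchDataset:
    def test_synonymous_queries_merge(self, classic_reference):
        queries = [
            (parse_name("Glycyrrhiza glandulifera Ledeb."), {"trait_a": 1}),
            (parse_name("Glycyrrhiza glabra L."), {"trait_b": 2}),
        ]
        out, results = match_dataset(queries, classic_reference)
        assert len(out) == 1
        (taxon,) = out
        assert taxon.name.binomial == "Glycyrrhiza glabra"
        assert taxon.data == {"trait_a": 1, "trait_b": 2}

    def test_worked_example_trio_steps(self, classic_reference):
        queries = [
            (parse_name("Mucuna holtoni"), {}),
            (parse_name("Zea mays subsp. mays"), {}),
            (parse_name("Glycyrrhiza glandulifera Ledeb"), {}),
        ]
        _, results = match_dataset(queries, classic_reference)
        assert [r.step for r in results] == [
            MatchStep.fuzzy,
            MatchStep.infraspecific_promotion,
            MatchStep.name_only,
        ]

    def test_unmatched_only_in_log(self, classic_reference):
        queries = [
            (parse_name("Zea mays L."), {"a": 1}),
            (parse_name("Nonexistens speciens"), {"b": 2}),
        ]
        out, results = match_dataset(queries, classic_reference)
        assert len(out) == 1
        assert [r.outcome for r in results] == [
            MatchOutcome.matched,
            MatchOutcome.unmatched,
        ]

    def test_deterministic_output(self, classic_reference):
        queries = [
            (parse_name("Mucuna holtoni"), {"x": 1}),
            (parse_name("Viscum alba"), {}),
            (parse_name("Zea mays subsp. mays"), {}),
        ]
        runs = []
        for _ in range(2):
            out, results = match_dataset(queries, classic_reference)
            runs.append(
                (
                    [str(t.name) for t in out],
                    [(r.outcome, r.step, r.score, tuple(r.notes)) for r in results],
                )
            )
        assert runs[0] == runs[1]
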