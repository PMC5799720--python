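import numpy as np
import pytest

from _helpers import VOCAB, oracle_stage, random_lexicon, random_term
from laylink.errors import IntegrityError
from laylink.lexicon import (
    ConceptRecord,
    ModifierList,
    Provenance,
    SemanticTypeConfig,
    default_modifier_list,
)
from laylink.linker import (
    AnnotatedNote,
    LookupPolicy,
    annotate,
    classify_policy,
    lookup,
    parse_annotations,
    render_html,
    serialize_annotations,
    trim_modifiers,
)
from laylink.recognizer import ConceptMatch

MODS = ModifierList(words=frozenset({"chronic", "severe", "left"}))
CONFIG = SemanticTypeConfig(
    prioritized=frozenset({"Disease or Syndrome", "Pharmacologic Substance"}),
    deprioritized=frozenset({"Temporal Concept", "Geographic Area"}),
)


def _match(surface, preferred="Unrelated Name", types=("Disease or Syndrome",)):
    return ConceptMatch(
        0,
        len(surface),
        surface,
        ConceptRecord(surface.lower(), "C1", preferred, frozenset(types)),
    )


class TestClassifyPolicy:
    @pytest.mark.parametrize(
        "types,expected",
        [
            (("Disease or Syndrome",), LookupPolicy.FULL),
            (("Temporal Concept",), LookupPolicy.SKIP),
            (("Temporal Concept", "Disease or Syndrome"), LookupPolicy.FULL),
            (("Temporal Concept", "Finding"), LookupPolicy.SHALLOW),
            (("Finding",), LookupPolicy.SHALLOW),
        ],
    )
    def test_any_all_rule(self, types, expected):
        assert classify_policy(_match("x", types=types), CONFIG) is expected


class TestTrimModifiers:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("chronic left heart failure", "heart failure"),
            ("severe", ""),
            ("community acquired pneumonia", "community acquired pneumonia"),
        ],
    )
    def test_examples(self, term, expected):
        assert trim_modifiers(term, MODS) == expected

    def test_order_preserved(self):
        assert trim_modifiers("a chronic b severe c", MODS) == "a b c"


class TestLookup:
    def test_stage1_direct_hit(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(_match("bacteremia"), lexicon, LookupPolicy.FULL, modifiers)
        assert result.stage == 1 and not result.partial
        assert result.items[0].definition_text == (
            "The presence of bacteria, a type of germ, in the blood"
        )

    def test_stage4_word_fallback_two_items(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(
            _match("community acquired pneumonia", preferred="Community-Acquired Pneumonia"),
            lexicon,
            LookupPolicy.FULL,
            modifiers,
        )
        assert result.stage == 4 and result.partial
        assert [(i.label, i.definition_text) for i in result.items] == [
            ("community", "A group of people."),
            ("pneumonia", "An infection of the lungs, usually caused by viruses or bacteria."),
        ]

    def test_stage4_single_word(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(
            _match("normal sinus rhythm", preferred="Normal Sinus Rhythm"),
            lexicon,
            LookupPolicy.FULL,
            modifiers,
        )
        assert result.stage == 4
        assert [i.label for i in result.items] == ["rhythm"]

    def test_stage2_preferred_name(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(
            _match("blood infection", preferred="Bacteremia"),
            lexicon,
            LookupPolicy.FULL,
            modifiers,
        )
        assert result.stage == 2

    def test_stage3_trimmed_surface(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(
            _match("severe bacteremia"), lexicon, LookupPolicy.FULL, modifiers
        )
        assert result.stage == 3

    def test_shallow_blocks_stage3(self, demo):
        lexicon, _, _, modifiers = demo
        assert (
            lookup(_match("severe bacteremia"), lexicon, LookupPolicy.SHALLOW, modifiers)
            is None
        )

    def test_drug_class_provenance(self, demo):
        lexicon, _, _, modifiers = demo
        result = lookup(_match("Hecoria", preferred="Hecoria"), lexicon, LookupPolicy.FULL, modifiers)
        assert result.stage == 1
        assert result.items[0].provenance is Provenance.DRUG_CLASS

    def test_skip_policy_rejected(self, demo):
        lexicon, _, _, modifiers = demo
        with pytest.raises(ValueError):
            lookup(_match("bacteremia"), lexicon, LookupPolicy.SKIP, modifiers)


class TestStageMinimalityOracle:
    """lookup() must agree with an independent brute-force evaluation of
    all four stages on randomized (term, lexicon, policy) instances."""

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            lexicon = random_lexicon(rng, n_entries=int(rng.integers(3, 12)))
            modifiers = ModifierList(
                words=frozenset(
                    str(w) for w in rng.choice(VOCAB, size=int(rng.integers(0, 4)))
                )
            )
            surface = random_term(rng)
            preferred = random_term(rng)
            shallow = bool(rng.random() < 0.4)
            policy = LookupPolicy.SHALLOW if shallow else LookupPolicy.FULL
            result = lookup(_match(surface, preferred=preferred), lexicon, policy, modifiers)
            expected = oracle_stage(surface, preferred, lexicon, modifiers, shallow)
            if expected is None:
                assert result is None
            else:
                stage, payload = expected
                assert result is not None and result.stage == stage
                assert result.partial is (stage == 4)
                if stage == 4:
                    assert [i.label for i in result.items] == payload


class TestAnnotate:
    def test_planted_recovery(self, bundle):
        for text, gold in bundle.notes:
            note = annotate(text, bundle.concepts, bundle.lexicon, bundle.config, bundle.modifiers)
            got = [(r.match.start, r.match.end, r.stage, r.partial) for r in note.results]
            assert got == [(g.start, g.end, g.stage, g.partial) for g in gold]

    def test_cache_transparency(self, bundle):
        for text, _ in bundle.notes:
            with_cache = annotate(
                text, bundle.concepts, bundle.lexicon, bundle.config, bundle.modifiers
            )
            without = annotate(
                text,
                bundle.concepts,
                bundle.lexicon,
                bundle.config,
                bundle.modifiers,
                use_cache=False,
            )
            assert serialize_annotations(with_cache) == serialize_annotations(without)

    def test_shared_cache_across_notes(self, bundle):
        cache = {}
        for text, gold in bundle.notes:
            note = annotate(
                text, bundle.concepts, bundle.lexicon, bundle.config, bundle.modifiers, cache=cache
            )
            got = [(r.match.start, r.match.end, r.stage, r.partial) for r in note.results]
            assert got == [(g.start, g.end, g.stage, g.partial) for g in gold]
        assert cache  # interim results were actually stored

    def test_all_deprioritized_note_empty(self, demo):
        lexicon, _, _, modifiers = demo
        from laylink.lexicon import ConceptTable

        table = ConceptTable()
        table.add(
            ConceptRecord("bacteremia", "C1", "Bacteremia", frozenset({"Temporal Concept"}))
        )
        config = SemanticTypeConfig(
            prioritized=frozenset(), deprioritized=frozenset({"Temporal Concept"})
        )
        note = annotate("bacteremia noted", table, lexicon, config, modifiers)
        assert note.results == []


class TestSerialization:
    def test_round_trip(self, demo, bundle):
        for text, _ in bundle.notes:
            note = annotate(text, bundle.concepts, bundle.lexicon, bundle.config, bundle.modifiers)
            record = serialize_annotations(note)
            assert parse_annotations(record, text) == note

    def test_empty_note(self):
        note = AnnotatedNote(text="plain text", results=[])
        record = serialize_annotations(note)
        assert parse_annotations(record, "plain text") == note

    def test_wrong_text_is_integrity_error(self, bundle):
        text, _ = bundle.notes[0]
        note = annotate(text, bundle.concepts, bundle.lexicon, bundle.config, bundle.modifiers)
        with pytest.raises(IntegrityError):
            parse_annotations(serialize_annotations(note), text + " tampered")


class TestRenderHtml:
    def test_plain_note_escaped_only(self):
        out = render_html(AnnotatedNote(text="a < b & c", results=[]))
        assert out == "a &lt; b &amp; c"

    def test_script_outside_annotations_escaped(self, demo):
        lexicon, concepts, config, modifiers = demo
        text = "<script>alert(1)</script> bacteremia"
        note = annotate(text, concepts, lexicon, config, modifiers)
        out = render_html(note)
        assert "<script>" not in out
        assert "&lt;script&gt;" in out

    def test_no_hyperlinks(self, demo):
        lexicon, concepts, config, modifiers = demo
        note = annotate("bacteremia and normal sinus rhythm", concepts, lexicon, config, modifiers)
        assert "<a " not in render_html(note)

    def test_golden_stage1_and_stage4(self, demo):
        # frozen after manual inspection
        lexicon, concepts, config, modifiers = demo
        note = annotate("bacteremia. normal sinus rhythm.", concepts, lexicon, config, modifiers)
        expected = (
            '<span class="laylink-term" data-stage="1" '
            'title="The presence of bacteria, a type of germ, in the blood">bacteremia</span>. '
            '<span class="laylink-term" data-stage="4" '
            'title="[rhythm]: The pattern of the heartbeat.">normal sinus rhythm</span>.'
        )
        assert render_html(note) == expected

    def test_stage4_labels_bracketed(self, demo):
        lexicon, concepts, config, modifiers = demo
        note = annotate("community acquired pneumonia", concepts, lexicon, config, modifiers)
        out = render_html(note)
        assert "[community]: A group of people." in out
        assert "[pneumonia]:" in out
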