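"""Schema validation, standoff round trips, and corpus statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rannote import (
    AnnotatedDocument,
    EntityMention,
    EntityType,
    RelationMention,
    RelationType,
    corpus_stats,
    parse_standoff,
    format_standoff,
    type_distribution,
    validate_document,
)
from rannote.standoff import StandoffParseError, read_standoff, write_standoff


def ent(id, type, start, end, text):
    return EntityMention(id, EntityType(type), start, end, text)


class TestValidateDocument:
    def test_clean_document_has_no_violations(self):
        doc = AnnotatedDocument(
            "d", "心脏杂音10月余", [
                ent("T1", "BodyPart", 0, 2, "心脏"),
                ent("T2", "MedicalDiscovery", 2, 4, "杂音"),
                ent("T3", "TemporalWord", 4, 8, "10月余"),
            ],
        )
        assert validate_document(doc) == []

    def test_no_entities_is_vacuously_clean(self):
        assert validate_document(AnnotatedDocument("d", "平文无标注。")) == []

    def test_direct_overlap_yields_one_violation(self):
        doc = AnnotatedDocument(
            "d", "abcd", [ent("T1", "Disease", 0, 2, "ab"),
                         ent("T2", "Disease", 1, 3, "bc")],
        )
        violations = validate_document(doc)
        assert [v.kind for v in violations] == ["overlap"]

    def test_nested_span_is_reported(self):
        doc = AnnotatedDocument(
            "d", "abcdef", [ent("T1", "Disease", 0, 6, "abcdef"),
                            ent("T2", "BodyPart", 2, 4, "cd")],
        )
        assert [v.kind for v in validate_document(doc)] == ["overlap"]

    def test_text_mismatch_detected(self):
        doc = AnnotatedDocument("d", "abcd", [ent("T1", "Disease", 0, 2, "xx")])
        assert [v.kind for v in validate_document(doc)] == ["text-mismatch"]

    def test_malformed_offsets_are_hard_errors(self):
        doc = AnnotatedDocument(
            "d", "abcd",
            [EntityMention("T1", EntityType.DISEASE, 3, 2, "x"),
             EntityMention("T2", EntityType.DISEASE, 0, 99, "y")],
        )
        kinds = [v.kind for v in validate_document(doc)]
        assert kinds == ["bad-span", "bad-span"]

    def test_punctuation_edge_is_warning_not_error(self):
        doc = AnnotatedDocument("d", "头晕。", [ent("T1", "MedicalDiscovery", 0, 3, "头晕。")])
        violations = validate_document(doc)
        assert [(v.kind, v.severity) for v in violations] == [
            ("punctuation-edge", "warning")
        ]

    def test_incompatible_relation_flagged(self):
        doc = AnnotatedDocument(
            "d", "心脏杂音", [
                ent("T1", "BodyPart", 0, 2, "心脏"),
                ent("T2", "MedicalDiscovery", 2, 4, "杂音"),
            ],
            [RelationMention("R1", RelationType.TRSY, "T1", "T2")],
        )
        assert [v.kind for v in validate_document(doc)] == ["relation-type"]

    def test_dangling_relation_flagged(self):
        doc = AnnotatedDocument(
            "d", "杂音", [ent("T1", "MedicalDiscovery", 0, 2, "杂音")],
            [RelationMention("R1", RelationType.BRSY, "T9", "T1")],
        )
        assert [v.kind for v in validate_document(doc)] == ["dangling-relation"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 18), st.integers(1, 5)), max_size=20))
    def test_overlap_detection_matches_bruteforce(self, spans):
        """The sweep reports exactly the pairs a brute-force O(n^2) scan finds."""
        text = "x" * 24
        ents = [
            EntityMention(f"T{i}", EntityType.DISEASE, s, min(s + l, 24),
                          text[s:min(s + l, 24)])
            for i, (s, l) in enumerate(spans)
        ]
        doc = AnnotatedDocument("d", text, ents)
        got = sum(1 for v in validate_document(doc) if v.kind == "overlap")
        expected = sum(
            1
            for i in range(len(ents))
            for j in range(i + 1, len(ents))
            if ents[i].start < ents[j].end and ents[j].start < ents[i].end
        )
        assert got == expected


class TestStandoff:
    def test_round_trip_identity(self, tmp_path):
        doc = AnnotatedDocument(
            "note1", "心脏杂音10月余", [
                ent("T1", "BodyPart", 0, 2, "心脏"),
                ent("T2", "MedicalDiscovery", 2, 4, "杂音"),
            ],
            [RelationMention("R1", RelationType.BRSY, "T1", "T2")],
        )
        write_standoff(doc, tmp_path)
        back = read_standoff(tmp_path / "note1.txt", tmp_path / "note1.ann")
        assert back == doc
        # annotation lines byte-identical on a second round trip
        assert format_standoff(back) == format_standoff(doc)

    def test_admission_fragment_parses_to_three_mentions(self):
        """'heart murmur for more than 10 months' splits into body part,
        discovery and temporal word."""
        text = "心脏杂音10月余"
        ann = (
            "T1\tBodyPart 0 2\t心脏\n"
            "T2\tMedicalDiscovery 2 4\t杂音\n"
            "T3\tTemporalWord 4 8\t10月余\n"
        )
        doc = parse_standoff(text, ann)
        assert [e.type for e in doc.entities] == [
            EntityType.BODY_PART,
            EntityType.MEDICAL_DISCOVERY,
            EntityType.TEMPORAL_WORD,
        ]
        assert validate_document(doc) == []

    @pytest.mark.parametrize(
        "ann, fragment",
        [
            ("T1\tBodyPart 0 99\t心脏", "out of range"),
            ("T1\tOrgan 0 2\t心脏", "unknown entity type"),
            ("T1\tBodyPart 0 2\t心脏\nT1\tBodyPart 2 4\t杂音", "duplicate"),
            ("X1\tBodyPart 0 2\t心脏", "unknown annotation line"),
            ("T1\tBodyPart 2 0\t心脏", "out of range"),
        ],
    )
    def test_parse_errors_name_the_line(self, ann, fragment):
        with pytest.raises(StandoffParseError) as err:
            parse_standoff("心脏杂音10月余", ann)
        assert fragment in str(err.value)
        assert "line" in str(err.value)


class TestCorpusStats:
    def test_distribution_from_reference_counts(self):
        # the documented corpus distribution: 14,953 of 66,943 body parts
        counts = {
            EntityType.MEDICAL_DISCOVERY: 29247,
            EntityType.TEMPORAL_WORD: 1631,
            EntityType.INSPECTION: 6915,
            EntityType.LABORATORY_TEST: 2127,
            EntityType.TREATMENT: 2601,
            EntityType.MEASUREMENT: 2839,
            EntityType.DISEASE: 5286,
            EntityType.MEDICATION: 1344,
            EntityType.BODY_PART: 14953,
        }
        pct = type_distribution(counts)
        assert pct[EntityType.BODY_PART] == 22.34

    def test_single_entity_is_100_percent(self):
        doc = AnnotatedDocument("d", "杂音。", [ent("T1", "MedicalDiscovery", 0, 2, "杂音")])
        stats = corpus_stats([doc])
        assert stats.per_type_percent[EntityType.MEDICAL_DISCOVERY] == 100.00
        assert all(
            stats.per_type_percent[t] == 0.0
            for t in EntityType
            if t != EntityType.MEDICAL_DISCOVERY
        )

    def test_entity_totals_sum_over_documents(self):
        d1 = AnnotatedDocument(
            "a", "心脏杂音头晕。",
            [ent("T1", "BodyPart", 0, 2, "心脏"),
             ent("T2", "MedicalDiscovery", 2, 4, "杂音"),
             ent("T3", "MedicalDiscovery", 4, 6, "头晕")],
        )
        d2 = AnnotatedDocument(
            "b", "肝功能ALT高血压胃炎杂音。",
            [ent("T1", "LaboratoryTest", 0, 3, "肝功能"),
             ent("T2", "LaboratoryTest", 3, 6, "ALT"),
             ent("T3", "Disease", 6, 9, "高血压"),
             ent("T4", "Disease", 9, 11, "胃炎"),
             ent("T5", "MedicalDiscovery", 11, 13, "杂音")],
        )
        stats = corpus_stats([d1, d2])
        assert stats.n_entities == 8
        assert stats.n_documents == 2

    def test_percentages_sum_to_100_within_rounding(self, small_corpus):
        stats = corpus_stats(small_corpus)
        assert abs(sum(stats.per_type_percent.values()) - 100.0) <= 0.05

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            corpus_stats([])
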