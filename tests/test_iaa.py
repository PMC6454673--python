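"""Inter-annotator agreement: matching, P/R/F arithmetic, report tables."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rannote import (
    AgreementCounts,
    EntityMention,
    EntityType,
    GeneratorConfig,
    PerturbationConfig,
    agreement_report,
    generate_corpus,
    match_annotations,
    match_documents,
    perturb_annotations,
    prf,
)
from rannote.iaa import TOTAL, f_from_pr
from rannote.schema import AnnotatedDocument


def ment(type, start, end):
    return EntityMention(f"T{start}_{end}", EntityType(type), start, end,
                         "x" * (end - start))


class TestPrf:
    @pytest.mark.parametrize(
        "n_a, n_b, n_c, expected",
        [
            # internally consistent rows of the published consistency tables
            (85, 93, 77, (82.80, 90.59, 86.52)),    # Disease, round 1
            (29, 26, 22, (84.62, 75.86, 80.00)),    # Treatment, round 1
            (65, 63, 56, (88.89, 86.15, 87.50)),    # Temporal word, round 2
            (510, 465, 426, (91.61, 83.53, 87.38)),  # Inspection, round 2
            (11, 11, 11, (100.00, 100.00, 100.00)),  # Medication, round 2
        ],
    )
    def test_reference_count_triples(self, n_a, n_b, n_c, expected):
        assert prf(AgreementCounts("t", n_a, n_b, n_c)).rounded() == expected

    def test_perfect_agreement(self):
        assert prf(AgreementCounts("t", 7, 7, 7)).rounded() == (100.0, 100.0, 100.0)

    def test_zero_consistent_uses_defined_zero(self):
        assert prf(AgreementCounts("t", 10, 10, 0)).rounded() == (0.0, 0.0, 0.0)
        assert prf(AgreementCounts("t", 0, 0, 0)).rounded() == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            AgreementCounts("t", -1, 3, 0)

    def test_consistent_cannot_exceed_either_side(self):
        with pytest.raises(ValueError):
            AgreementCounts("t", 3, 5, 4)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.integers(0, 5000), st.integers(0, 5000), st.data())
    def test_matches_rational_arithmetic_oracle(self, n_a, n_b, data):
        """Float P/R/F rounded once at the end agrees with exact fractions."""
        n_c = data.draw(st.integers(0, min(n_a, n_b)))
        got = prf(AgreementCounts("t", n_a, n_b, n_c)).rounded()
        p = Fraction(100 * n_c, n_b) if n_b else Fraction(0)
        r = Fraction(100 * n_c, n_a) if n_a else Fraction(0)
        f = 2 * p * r / (p + r) if p + r else Fraction(0)
        oracle = tuple(float(round(v, 2)) for v in (p, r, f))
        assert got == oracle

    def test_f_from_already_rounded_p_and_r(self):
        # pooled micro row computed from its printed P and R
        assert round(f_from_pr(97.78, 97.69), 2) == 97.73


class TestMatchAnnotations:
    def test_self_agreement(self):
        mentions = [ment("Disease", 0, 2), ment("Disease", 3, 5),
                    ment("BodyPart", 6, 8), ment("BodyPart", 9, 11),
                    ment("Treatment", 12, 15)]
        counts = match_annotations(mentions, list(mentions))
        assert counts["Disease"].n_consistent == 2
        assert counts["BodyPart"].n_consistent == 2
        assert counts["Treatment"].n_consistent == 1
        assert counts[TOTAL].n_consistent == 5

    def test_same_span_different_type_no_match(self):
        a = [ment("Disease", 0, 2)]
        b = [ment("BodyPart", 0, 2)]
        counts = match_annotations(a, b)
        assert counts[TOTAL].n_consistent == 0

    def test_boundary_difference_breaks_exact_match(self):
        a = [ment("Disease", 0, 2), ment("BodyPart", 3, 5)]
        b = [ment("Disease", 0, 2), ment("BodyPart", 3, 6)]
        counts = match_annotations(a, b)
        # brute force over A x B pairs: only the [0,2) Disease pair agrees
        assert counts[TOTAL].n_consistent == 1

    def test_overlap_criterion_accepts_boundary_shift(self):
        a = [ment("Disease", 0, 2), ment("BodyPart", 3, 5)]
        b = [ment("Disease", 0, 2), ment("BodyPart", 3, 6)]
        counts = match_annotations(a, b, criterion="overlap")
        assert counts[TOTAL].n_consistent == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 10), st.sampled_from(["Disease", "BodyPart"])),
                 max_size=8, unique=True),
        st.lists(st.tuples(st.integers(0, 10), st.sampled_from(["Disease", "BodyPart"])),
                 max_size=8, unique=True),
    )
    def test_exact_matching_equals_bruteforce(self, setup_a, setup_b):
        a = [ment(t, 2 * s, 2 * s + 2) for s, t in setup_a]
        b = [ment(t, 2 * s, 2 * s + 2) for s, t in setup_b]
        counts = match_annotations(a, b)
        brute = sum(
            1 for m in a for m2 in b
            if (m.start, m.end, m.type) == (m2.start, m2.end, m2.type)
        )
        assert counts[TOTAL].n_consistent == brute

    def test_mixed_documents_rejected(self):
        d1 = AnnotatedDocument("a", "xxxx")
        d2 = AnnotatedDocument("b", "yyyy")
        with pytest.raises(ValueError, match="different documents"):
            match_documents(d1, d2)


class TestAgreementReport:
    def test_identical_corpora_score_100(self, small_corpus):
        report = agreement_report(small_corpus, small_corpus)
        represented = report[report["n_A"] > 0]
        assert (represented["P"] == 100.0).all()
        assert (represented["R"] == 100.0).all()
        assert (represented["F"] == 100.0).all()

    def test_reference_treatment_row_formatting(self):
        row = prf(AgreementCounts("Treatment", 29, 26, 22)).rounded()
        assert row == (84.62, 75.86, 80.00)

    def test_swapping_annotators_swaps_p_and_r(self, small_corpus):
        perturbed = perturb_annotations(
            small_corpus, PerturbationConfig(deletion_rate=0.3, spurious_rate=0.2,
                                             seed=5)
        )
        fwd = agreement_report(small_corpus, perturbed)
        rev = agreement_report(perturbed, small_corpus)
        assert (fwd["P"] == rev["R"]).all()
        assert (fwd["R"] == rev["P"]).all()
        assert (fwd["F"] == rev["F"]).all()

    def test_total_row_is_micro_sum(self, small_corpus):
        perturbed = perturb_annotations(
            small_corpus, PerturbationConfig(deletion_rate=0.2, seed=3)
        )
        report = agreement_report(small_corpus, perturbed)
        body = report[report["type"] != TOTAL]
        total = report[report["type"] == TOTAL].iloc[0]
        assert total["n_consistent"] == body["n_consistent"].sum()
        assert total["n_A"] == body["n_A"].sum()

    def test_known_deletions_reduce_total_consistent(self):
        config = GeneratorConfig(n_documents=1, sentences_per_doc=30, seed=21)
        corpus = generate_corpus(config)
        gold_n = len(corpus[0].entities)
        perturbed = perturb_annotations(corpus, PerturbationConfig(deletion_rate=0.4,
                                                                   seed=9))
        deleted = gold_n - len(perturbed[0].entities)
        report = agreement_report(corpus, perturbed)
        total = report[report["type"] == TOTAL].iloc[0]
        assert total["n_consistent"] == gold_n - deleted

    def test_doc_id_mismatch_lists_difference(self, small_corpus):
        with pytest.raises(ValueError, match="doc"):
            agreement_report(small_corpus, small_corpus[:-1])
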