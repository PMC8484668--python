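"""Information content, Resnik term similarity and profile-level scores,
checked against exhaustive brute-force oracles on the 7-term fixture."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoprio.models import DiseaseProfile, PatientPhenotype
from phenoprio.similarity import (
    compute_ic,
    profile_similarity,
    symmetric_bma,
    term_similarity,
)


def disease(disease_id, terms, gene="G", inheritance="AR"):
    return DiseaseProfile(disease_id, disease_id, gene, inheritance,
                          frozenset(terms))


@pytest.fixture(scope="module")
def four_diseases(mini_ontology):
    # annotation counts after propagation (N=4):
    #   A1a: 1, A1b: 1, A1: 3 (d1,d2,d4), A: 3, B1: 2, B: 2, root: 4
    return [
        disease("d1", {"HP:A1a"}),
        disease("d2", {"HP:A1b", "HP:B1"}),
        disease("d3", {"HP:B1"}),
        disease("d4", {"HP:A1"}),
    ]


@pytest.fixture(scope="module")
def ic(mini_ontology, four_diseases):
    return compute_ic(mini_ontology, four_diseases)


class TestInformationContent:
    def test_root_ic_is_zero(self, ic, mini_ontology):
        assert ic[mini_ontology.root] == 0.0

    def test_singleton_term_ic(self, ic):
        # HP:A1a annotates exactly 1 of 4 diseases
        assert ic["HP:A1a"] == pytest.approx(-math.log(1 / 4))

    def test_propagated_counts(self, ic):
        assert ic["HP:A1"] == pytest.approx(-math.log(3 / 4))
        assert ic["HP:B1"] == pytest.approx(-math.log(2 / 4))

    def test_unannotated_term_gets_max_observed_ic(self, mini_ontology):
        diseases = [disease("d1", {"HP:A1a"}), disease("d2", {"HP:B1"})]
        ic = compute_ic(mini_ontology, diseases)
        # HP:A1b never annotated -> IC of the rarest annotated term
        assert ic["HP:A1b"] == pytest.approx(-math.log(1 / 2))

    def test_ic_non_decreasing_parent_to_child(self, ic, mini_ontology):
        for term, parents in mini_ontology.parents.items():
            for parent in parents:
                assert ic[term] >= ic[parent] - 1e-12

    def test_empty_disease_set_errors(self, mini_ontology):
        with pytest.raises(ValueError):
            compute_ic(mini_ontology, [])


class TestTermSimilarity:
    def test_self_similarity_is_own_ic(self, mini_ontology, ic):
        for term in mini_ontology.terms:
            assert term_similarity(term, term, mini_ontology, ic) == ic[term]

    def test_cross_branch_similarity_is_zero(self, mini_ontology, ic):
        # A1a and B1 share only the root
        assert term_similarity("HP:A1a", "HP:B1", mini_ontology, ic) == 0.0

    def test_sibling_mica(self, mini_ontology, ic):
        # A1a vs A1b: most informative common ancestor is A1
        got = term_similarity("HP:A1a", "HP:A1b", mini_ontology, ic)
        assert got == pytest.approx(ic["HP:A1"])

    def test_matches_brute_force_over_ancestor_sets(self, mini_ontology, ic):
        terms = sorted(mini_ontology.terms)
        for t1 in terms:
            for t2 in terms:
                common = mini_ontology.ancestors(t1) & mini_ontology.ancestors(t2)
                expected = max((ic[a] for a in common), default=0.0)
                assert term_similarity(t1, t2, mini_ontology, ic) == pytest.approx(
                    expected
                )


def brute_force_bma(terms_a, terms_b, onto, ic):
    """Oracle: all-pairs Resnik matrix, then symmetric best-match average."""
    best_a = [
        max(
            max((ic[c] for c in onto.ancestors(a) & onto.ancestors(b)), default=0.0)
            for b in terms_b
        )
        for a in terms_a
    ]
    best_b = [
        max(
            max((ic[c] for c in onto.ancestors(a) & onto.ancestors(b)), default=0.0)
            for a in terms_a
        )
        for b in terms_b
    ]
    return 0.5 * (sum(best_a) / len(best_a) + sum(best_b) / len(best_b))


class TestProfileSimilarity:
    def test_identical_profiles_score_one(self, mini_ontology, ic, four_diseases):
        patient = PatientPhenotype("p", frozenset({"HP:A1a"}))
        score = profile_similarity(patient, four_diseases[0], mini_ontology, ic)
        assert score.value == pytest.approx(1.0)

    def test_only_root_shared_scores_zero(self, mini_ontology, ic):
        patient = PatientPhenotype("p", frozenset({"HP:A1a"}))
        other_branch = disease("d", {"HP:B1"})
        score = profile_similarity(patient, other_branch, mini_ontology, ic)
        assert score.value == 0.0

    def test_matches_exhaustive_pairwise_oracle(self, mini_ontology, ic):
        patient_terms = frozenset({"HP:A1a", "HP:B1"})
        disease_terms = frozenset({"HP:A1b", "HP:B1", "HP:A"})
        patient = PatientPhenotype("p", patient_terms)
        raw = brute_force_bma(sorted(patient_terms), sorted(disease_terms),
                              mini_ontology, ic)
        self_raw = brute_force_bma(sorted(patient_terms), sorted(patient_terms),
                                   mini_ontology, ic)
        expected = min(raw / self_raw, 1.0)
        score = profile_similarity(patient, disease("d", disease_terms),
                                   mini_ontology, ic)
        assert score.value == pytest.approx(expected, abs=1e-12)

    def test_empty_patient_scores_zero_with_warning(self, mini_ontology, ic,
                                                    four_diseases):
        patient = PatientPhenotype("p", frozenset())
        with pytest.warns(UserWarning, match="empty phenotype"):
            score = profile_similarity(patient, four_diseases[0], mini_ontology, ic)
        assert score.value == 0.0

    def test_jaccard_metric_bounded_and_symmetric_in_terms(self, mini_ontology, ic):
        patient = PatientPhenotype("p", frozenset({"HP:A1a", "HP:B1"}))
        score = profile_similarity(patient, disease("d", {"HP:A1b"}),
                                   mini_ontology, ic, metric="jaccard_ancestors")
        assert 0.0 <= score.value <= 1.0


TERM_SETS = st.frozensets(
    st.sampled_from(["HP:A", "HP:A1", "HP:A1a", "HP:A1b", "HP:B", "HP:B1", "HP:R"]),
    min_size=1, max_size=4,
)


@given(terms_a=TERM_SETS, terms_b=TERM_SETS)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_symmetric_bma_is_exactly_symmetric(terms_a, terms_b, mini_ontology,
                                            four_diseases):
    ic = compute_ic(mini_ontology, four_diseases)
    forward = symmetric_bma(terms_a, terms_b, mini_ontology, ic)
    backward = symmetric_bma(terms_b, terms_a, mini_ontology, ic)
    assert forward == pytest.approx(backward, abs=1e-12)


@given(terms_a=TERM_SETS, terms_b=TERM_SETS)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_profile_scores_bounded(terms_a, terms_b, mini_ontology, four_diseases):
    ic = compute_ic(mini_ontology, four_diseases)
    patient = PatientPhenotype("p", terms_a)
    score = profile_similarity(patient, disease("d", terms_b), mini_ontology, ic)
    assert 0.0 <= score.value <= 1.0


@given(terms_a=TERM_SETS, terms_b=TERM_SETS)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_adding_most_informative_patient_term_never_decreases_score(
    terms_a, terms_b, mini_ontology, four_diseases
):
    """Adding the patient's most informative term to the disease profile can
    only improve both directions of the best-match average (a less
    informative shared term can dilute the disease-to-patient mean, so the
    guarantee is stated for the max-IC term)."""
    ic = compute_ic(mini_ontology, four_diseases)
    patient = PatientPhenotype("p", terms_a)
    shared = max(sorted(terms_a), key=lambda t: (ic[t], t))
    base = profile_similarity(patient, disease("d", terms_b), mini_ontology, ic)
    grown = profile_similarity(
        patient, disease("d", terms_b | {shared}), mini_ontology, ic
    )
    assert grown.value >= base.value - 1e-12
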