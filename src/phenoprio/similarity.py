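"""Step 3 — semantic similarity between patient phenotype and disease profiles.

Information content (IC) of each ontology term is estimated from the disease
annotation corpus: annotations propagate to all ancestors, and
``IC(t) = -ln(n_t / N)`` where ``n_t`` diseases are annotated at or below *t*
out of *N*. Pairwise term similarity is Resnik's measure (IC of the most
informative common ancestor); profiles are compared by a symmetric best-match
average, normalized by the patient profile's self-similarity so a perfect
match scores 1.

A Jaccard-over-ancestors metric is provided as a config-switchable
alternative, useful for checking that rankings are robust to the choice of
similarity measure.
"""

from __future__ import annotations

import math
import warnings

from .models import DiseaseProfile, Ontology, PatientPhenotype, SimilarityScore


def compute_ic(
    ontology: Ontology, disease_profiles: list[DiseaseProfile]
) -> dict[str, float]:
    """Information content of every ontology term from disease annotations.

    Terms never reached by any (propagated) annotation get the IC of the
    rarest annotated term, so an unannotated patient term neither dominates
    nor vanishes.
    """
    if not disease_profiles:
        raise ValueError("cannot compute IC from an empty disease set")
    n_total = len(disease_profiles)
    counts: dict[str, int] = {}
    for profile in disease_profiles:
        covered: set[str] = set()
        for term in profile.hpo_terms:
            covered |= ontology.ancestors(term)
        for term in covered:
            counts[term] = counts.get(term, 0) + 1
    annotated_ic = {
        term: -math.log(count / n_total) for term, count in counts.items()
    }
    max_ic = max(annotated_ic.values())
    ic = {
        term: annotated_ic.get(term, max_ic) for term in ontology.terms
    }
    ic[ontology.root] = 0.0
    return ic


def term_similarity(
    t1: str, t2: str, ontology: Ontology, ic: dict[str, float]
) -> float:
    """Resnik similarity: maximum IC over the common ancestors of t1 and t2."""
    common = ontology.common_ancestors(t1, t2)
    if not common:
        return 0.0
    return max(ic[a] for a in common)


def _best_match_average(
    terms_a: frozenset[str],
    terms_b: frozenset[str],
    ontology: Ontology,
    ic: dict[str, float],
) -> float:
    """Mean over terms_a of the best Resnik match in terms_b (directional)."""
    return sum(
        max(term_similarity(a, b, ontology, ic) for b in terms_b) for a in terms_a
    ) / len(terms_a)


def symmetric_bma(
    terms_a: frozenset[str],
    terms_b: frozenset[str],
    ontology: Ontology,
    ic: dict[str, float],
) -> float:
    """Symmetric best-match average of Resnik similarities (unnormalized).

    This core is exactly symmetric in its two term sets; the normalized
    profile score divides it by the patient profile's self-BMA, which is
    role-specific by construction.
    """
    if not terms_a or not terms_b:
        return 0.0
    forward = _best_match_average(terms_a, terms_b, ontology, ic)
    backward = _best_match_average(terms_b, terms_a, ontology, ic)
    return 0.5 * (forward + backward)


def profile_similarity(
    patient: PatientPhenotype,
    disease: DiseaseProfile,
    ontology: Ontology,
    ic: dict[str, float],
    metric: str = "resnik_bma",
) -> SimilarityScore:
    """Phenotype-match score in [0, 1] between a patient and a disease.

    ``resnik_bma``: symmetric best-match average of Resnik similarities,
    normalized by the patient profile's self-BMA (capped at 1). An empty
    patient term set scores 0 (phenotype-free mode) with a warning.

    ``jaccard_ancestors``: Jaccard index of the two profiles' propagated
    ancestor sets.
    """
    if not patient.hpo_terms:
        warnings.warn(
            f"case {patient.case_id}: empty phenotype, similarity defined as 0",
            stacklevel=2,
        )
        return SimilarityScore(0.0)
    if metric == "jaccard_ancestors":
        anc_p: set[str] = set()
        for t in patient.hpo_terms:
            anc_p |= ontology.ancestors(t)
        anc_d: set[str] = set()
        for t in disease.hpo_terms:
            anc_d |= ontology.ancestors(t)
        union = anc_p | anc_d
        return SimilarityScore(len(anc_p & anc_d) / len(union) if union else 0.0)
    if metric != "resnik_bma":
        raise ValueError(f"unknown similarity metric {metric!r}")

    raw = symmetric_bma(patient.hpo_terms, disease.hpo_terms, ontology, ic)
    self_bma = _best_match_average(
        patient.hpo_terms, patient.hpo_terms, ontology, ic
    )
    if self_bma <= 0.0:
        # patient terms carry no information (all at root): nothing to match
        return SimilarityScore(0.0)
    return SimilarityScore(min(raw / self_bma, 1.0))
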