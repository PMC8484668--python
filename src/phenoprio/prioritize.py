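"""End-to-end per-case prioritization.

Composes the three steps — frequency filtration, ACMG-AMP classification with
Bayesian tiering, and HPO similarity scoring — then enforces
inheritance-consistent genotypes, ranks candidates (tier first, similarity
within tier), and selects the final candidate(s) or declares the case
"not found".

A single heterozygous variant in a recessive-disease gene (a monoallelic AR
genotype) is never selected by default: without phase data or
genotype–phenotype priors the pipeline cannot justify a recessive diagnosis
from one allele. ``allow_monoallelic_ar=True`` relaxes this, reproducing the
human curators' phenotype-driven override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .acmg import PM2_THRESHOLD, classify
from .filters import FilterConfig, filter_case
from .io import KnowledgeBase
from .models import (
    BayesConfig,
    CandidateVariant,
    PatientPhenotype,
    PrioritizationResult,
    VariantAnnotation,
    VariantCall,
    chrom_sort_key,
    format_key,
)
from .similarity import compute_ic, profile_similarity


@dataclass
class PipelineConfig:
    """Everything tunable in one place; snapshotted into result provenance."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    score_threshold: float = 0.5
    pm2_threshold: float = PM2_THRESHOLD
    similarity_metric: str = "resnik_bma"
    allow_monoallelic_ar: bool = False
    seed: Optional[int] = None

    def snapshot(self) -> dict:
        return {
            "filter_profile": self.filter.profile,
            "ba1_threshold": self.filter.ba1_threshold,
            "founder_subpopulations": sorted(self.filter.founder_subpopulations),
            "hl_ar_threshold": self.filter.hl_ar_threshold,
            "hl_ad_threshold": self.filter.hl_ad_threshold,
            "prior": self.bayes.prior,
            "odds_very_strong": self.bayes.odds_very_strong,
            "tier_cutoffs": [
                self.bayes.tier1_cutoff,
                self.bayes.tier2_cutoff,
                self.bayes.tier3_cutoff,
            ],
            "score_threshold": self.score_threshold,
            "pm2_threshold": self.pm2_threshold,
            "similarity_metric": self.similarity_metric,
            "allow_monoallelic_ar": self.allow_monoallelic_ar,
            "seed": self.seed,
        }


def genotype_consistent(
    candidates_in_gene: list[VariantCall], inheritance: str
) -> list[tuple[bool, bool]]:
    """Per-candidate (consistent, carrier_flag) under one inheritance mode.

    AD: any non-reference genotype. AR: homozygous, or >= 2 distinct
    heterozygous variants surviving classification in the gene (assumed
    trans). XL: hemizygous, or heterozygous flagged as a possible carrier
    but still evaluated under the dominant rule. MT: any non-reference.
    """
    results: list[tuple[bool, bool]] = []
    if inheritance == "AR":
        n_het = sum(1 for c in candidates_in_gene if c.zygosity == "heterozygous")
        for call in candidates_in_gene:
            if call.zygosity in ("homozygous", "hemizygous"):
                results.append((True, False))
            else:
                results.append((n_het >= 2, False))
    elif inheritance == "XL":
        for call in candidates_in_gene:
            if call.zygosity == "hemizygous":
                results.append((True, False))
            else:
                results.append((True, True))
    else:  # AD and MT: any non-reference genotype
        results = [(True, False) for _ in candidates_in_gene]
    return results


def _sort_key(candidate: CandidateVariant):
    call = candidate.classified.call
    return (
        candidate.classified.tier,
        -candidate.similarity,
        -candidate.classified.posterior,
        chrom_sort_key(call.chrom),
        call.pos,
        call.ref,
        call.alt,
    )


def rank_candidates(candidates: list[CandidateVariant]) -> list[CandidateVariant]:
    """Order candidates and assign ranks.

    Rankable candidates (inheritance-consistent, tier assigned) sort by
    (tier ascending, similarity descending, posterior descending, genomic
    coordinate ascending) and get ranks 1..n; the rest are kept after them,
    unranked, for audit.
    """
    rankable = [
        c
        for c in candidates
        if c.inheritance_consistent and c.classified.tier is not None
    ]
    excluded = [
        c
        for c in candidates
        if not (c.inheritance_consistent and c.classified.tier is not None)
    ]
    rankable.sort(key=_sort_key)
    for i, candidate in enumerate(rankable, start=1):
        candidate.rank = i
    for candidate in excluded:
        candidate.rank = None
    excluded.sort(
        key=lambda c: (
            chrom_sort_key(c.classified.call.chrom),
            c.classified.call.pos,
            c.disease.disease_id,
        )
    )
    return rankable + excluded


def prioritize_case(
    vcf_calls: list[VariantCall],
    annotations: dict[tuple, VariantAnnotation],
    patient: PatientPhenotype,
    kb: KnowledgeBase,
    config: Optional[PipelineConfig] = None,
    vcf_build: Optional[str] = None,
) -> PrioritizationResult:
    """Run the full pipeline for one case.

    Steps: build check -> frequency filter -> ACMG classification (one
    candidate per variant x disease of its gene) -> phenotype similarity ->
    genotype-consistency -> ranking -> selection. The top-ranked candidate is
    selected; for a recessive disease its trans partner in the same gene is
    selected with it. A case with no rankable candidate is "not found".
    """
    config = config or PipelineConfig()
    if vcf_build is not None and vcf_build != kb.build:
        raise ValueError(
            f"genome build mismatch: VCF declares {vcf_build!r}, "
            f"knowledge base declares {kb.build!r}"
        )
    missing = patient.hpo_terms - kb.ontology.terms
    if missing:
        raise ValueError(f"patient terms not in ontology: {sorted(missing)}")

    # -- step 1: frequency filtration -------------------------------------
    inheritance_by_key = {}
    for call in vcf_calls:
        ann = annotations.get(call.key)
        if ann is not None:
            profiles = kb.diseases_for_gene(ann.gene)
            if profiles:
                # stricter bound wins when a gene has both AR and AD diseases
                modes = {p.inheritance for p in profiles}
                inheritance_by_key[call.key] = "AD" if modes != {"AR"} else "AR"
    retained, drop_log = filter_case(
        vcf_calls,
        annotations,
        kb.known_variants,
        config.filter,
        inheritance_by_key=inheritance_by_key,
    )

    # -- step 2: classification -------------------------------------------
    retained_by_gene: dict[str, list[VariantCall]] = {}
    for call in retained:
        ann = annotations.get(call.key)
        if ann is not None:
            retained_by_gene.setdefault(ann.gene, []).append(call)

    ic = compute_ic(kb.ontology, kb.diseases)
    candidates: list[CandidateVariant] = []
    declassified: dict[str, str] = {}
    for call in retained:
        ann = annotations.get(call.key)
        if ann is None or not kb.diseases_for_gene(ann.gene):
            declassified[format_key(call.key)] = "no disease association"
            continue
        gene_mates = [
            (mate, annotations[mate.key])
            for mate in retained_by_gene.get(ann.gene, [])
            if mate.key != call.key
        ]
        for disease in kb.diseases_for_gene(ann.gene):
            classified = classify(
                call,
                ann,
                kb.known_variants,
                disease_profile=disease,
                bayes_config=config.bayes,
                score_threshold=config.score_threshold,
                pm2_threshold=config.pm2_threshold,
                constrained_genes=kb.constrained_genes,
                gene_mates=gene_mates,
            )
            if not classified.is_candidate:
                declassified[format_key(call.key)] = (
                    f"classified {classified.classification} for {disease.disease_id}"
                )
                continue
            # -- step 3: phenotype similarity -----------------------------
            score = profile_similarity(
                patient, disease, kb.ontology, ic, metric=config.similarity_metric
            )
            candidates.append(
                CandidateVariant(
                    classified=classified,
                    disease=disease,
                    similarity=score.value,
                    inheritance_consistent=True,  # set below
                )
            )

    # -- genotype consistency ---------------------------------------------
    by_group: dict[tuple[str, str], list[CandidateVariant]] = {}
    for candidate in candidates:
        group = (candidate.disease.gene, candidate.disease.inheritance)
        by_group.setdefault(group, []).append(candidate)
    for (gene, inheritance), group in by_group.items():
        calls = [c.classified.call for c in group]
        # distinct variants only: two candidate rows for one variant (two
        # diseases) must not fake a compound het
        distinct: dict[tuple, VariantCall] = {c.key: c for c in calls}
        verdicts = dict(
            zip(
                distinct.keys(),
                genotype_consistent(list(distinct.values()), inheritance),
            )
        )
        for candidate in group:
            consistent, carrier = verdicts[candidate.classified.call.key]
            if config.allow_monoallelic_ar and inheritance == "AR":
                consistent = True
            candidate.inheritance_consistent = consistent
            candidate.carrier_flag = carrier

    # -- best candidate per variant, then rank ------------------------------
    best_by_variant: dict[tuple, CandidateVariant] = {}
    for candidate in candidates:
        key = candidate.classified.call.key
        incumbent = best_by_variant.get(key)
        if incumbent is None or _representative_order(candidate) < _representative_order(
            incumbent
        ):
            best_by_variant[key] = candidate
    audit_rows = [c for c in candidates if best_by_variant[c.classified.call.key] is not c]
    ranked = rank_candidates(list(best_by_variant.values()))

    # -- selection -----------------------------------------------------------
    selected: list[tuple] = []
    top = next((c for c in ranked if c.rank == 1), None)
    if top is not None:
        selected.append(top.classified.call.key)
        if (
            top.disease.inheritance == "AR"
            and top.classified.call.zygosity == "heterozygous"
        ):
            partner = next(
                (
                    c
                    for c in ranked
                    if c.rank is not None
                    and c.rank > 1
                    and c.disease.gene == top.disease.gene
                    and c.disease.inheritance == "AR"
                    and c.classified.call.zygosity == "heterozygous"
                ),
                None,
            )
            if partner is not None:
                selected.append(partner.classified.call.key)

    classifications = {}
    for candidate in ranked:
        key = candidate.classified.call.key
        if key in selected:
            classifications[format_key(key)] = candidate.classified.classification

    for row in audit_rows:
        row.rank = None
    return PrioritizationResult(
        case_id=patient.case_id,
        ranked_candidates=ranked + audit_rows,
        selected=selected,
        status="found" if selected else "not_found",
        provenance=config.snapshot(),
        filter_log={
            "dropped": len(drop_log),
            "declassified": declassified,
            "reasons": _summarize_reasons(drop_log),
        },
        classifications=classifications,
    )


def _representative_order(candidate: CandidateVariant):
    """Order used to pick the best (variant, disease) row per variant."""
    tier = candidate.classified.tier
    return (
        not candidate.inheritance_consistent,
        tier is None,
        tier if tier is not None else 99,
        -candidate.similarity,
        -candidate.classified.posterior,
        candidate.disease.disease_id,
    )


def _summarize_reasons(drop_log: dict[str, str]) -> dict[str, int]:
    summary: dict[str, int] = {}
    for reason in drop_log.values():
        summary[reason] = summary.get(reason, 0) + 1
    return summary
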