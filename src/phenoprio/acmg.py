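"""Step 2 — ACMG-AMP 2015 classification with Bayesian tiering.

Criteria are assigned from the annotation sidecar's curated evidence flags by
a deterministic rule table, combined into the categorical five-class call by
the 2015 guideline's combining rules, converted into a posterior probability
of pathogenicity by the point-based Bayesian framework (supporting/moderate/
strong/very-strong evidence worth 1/2/4/8 points, benign evidence negative,
points exponentiating a fixed odds of pathogenicity against a prior of 0.1),
and binned into tiers at posterior > 0.9 / > 0.499 / > 0.1.

Criterion strengths are not modulated (no PVS1 downgrade rules, no
disease-specific strength adjustment): every criterion scores at the default
strength of its code prefix.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .models import (
    BayesConfig,
    ClassifiedVariant,
    Criterion,
    CriteriaSet,
    DiseaseProfile,
    KnownVariantRecord,
    LOF_CONSEQUENCES,
    VariantAnnotation,
    VariantCall,
)

#: default population-absence bound for PM2
PM2_THRESHOLD = 1e-4


def assign_criteria(
    call: VariantCall,
    annotation: VariantAnnotation,
    known_variants: dict[tuple, KnownVariantRecord],
    disease_profile: Optional[DiseaseProfile] = None,
    score_threshold: float = 0.5,
    pm2_threshold: float = PM2_THRESHOLD,
    constrained_genes: frozenset[str] = frozenset(),
    gene_mates: Iterable[tuple[VariantCall, VariantAnnotation]] = (),
) -> tuple[CriteriaSet, bool]:
    """Assign ACMG-AMP criteria from curated flags and scores.

    ``gene_mates`` are the *other* retained calls in the same gene for this
    case (used by PM3). Returns the criteria set and a flag that is True when
    PM3 was applied to two heterozygotes assuming a trans configuration
    (no phase data is consulted).

    Rules (all deterministic):

    * PVS1 — predicted-null consequence in a gene with an established
      loss-of-function disease mechanism.
    * PS1 / PM5 — same amino-acid change, or a different change at the same
      residue, previously established as pathogenic.
    * PS2 / PM6 — confirmed / assumed de novo occurrence.
    * PS3 / BS3 — well-established functional studies, damaging / benign.
    * PM1 — mutational hotspot or critical functional domain.
    * PM2 — every provided population frequency below ``pm2_threshold``
      (or no frequency observed at all).
    * PM3 — recessive disease with a second pathogenic-asserted retained
      variant in the gene, or a homozygous genotype.
    * PP1 — co-segregation with disease.
    * PP2 — missense in a missense-constrained gene.
    * PP3 / BP4 — >= 2 provided in-silico scores above ``score_threshold`` /
      below ``1 - score_threshold`` (a single score suffices when only one
      tool reported).
    * PP4 — phenotype highly specific for the disease.
    * PP5 / BP6 — reputable-source (ClinVar) pathogenic / benign assertion.
    * BS2 — homozygotes observed in population controls for a recessive
      disease.
    """
    codes: list[str] = []
    flags = annotation.curated_flags
    pm3_assumed_trans = False

    if annotation.consequence in LOF_CONSEQUENCES and "lof_mechanism_gene" in flags:
        codes.append("PVS1")
    if "same_protein_change_pathogenic" in flags:
        codes.append("PS1")
    if "de_novo_confirmed" in flags:
        codes.append("PS2")
    if "functional_damaging" in flags:
        codes.append("PS3")
    if "hotspot_domain" in flags:
        codes.append("PM1")

    afs = annotation.provided_afs()
    if not afs or all(af < pm2_threshold for af in afs):
        codes.append("PM2")

    inheritance = disease_profile.inheritance if disease_profile else None
    if inheritance == "AR":
        if call.zygosity == "homozygous":
            codes.append("PM3")
        else:
            for mate_call, _ in gene_mates:
                record = known_variants.get(mate_call.key)
                if record is not None and record.assertion in (
                    "pathogenic",
                    "likely_pathogenic",
                ):
                    codes.append("PM3")
                    if call.zygosity == "heterozygous":
                        pm3_assumed_trans = True
                    break

    if "other_change_same_residue_pathogenic" in flags:
        codes.append("PM5")
    if "de_novo_assumed" in flags:
        codes.append("PM6")
    if "segregates" in flags:
        codes.append("PP1")
    if annotation.consequence == "missense" and annotation.gene in constrained_genes:
        codes.append("PP2")

    scores = list(annotation.insilico_scores.values())
    needed = 1 if len(scores) == 1 else 2
    if scores:
        if sum(s > score_threshold for s in scores) >= needed:
            codes.append("PP3")
        if sum(s < (1.0 - score_threshold) for s in scores) >= needed:
            codes.append("BP4")

    if "phenotype_specific_match" in flags:
        codes.append("PP4")
    if "clinvar_pathogenic" in flags:
        codes.append("PP5")
    if "clinvar_benign" in flags:
        codes.append("BP6")
    if "functional_benign" in flags:
        codes.append("BS3")
    if "population_homozygotes_observed" in flags and inheritance == "AR":
        codes.append("BS2")

    return CriteriaSet.from_codes(codes), pm3_assumed_trans


def _strength_counts(criteria: CriteriaSet) -> dict[str, int]:
    counts = {
        "very_strong": 0,
        "strong": 0,
        "moderate": 0,
        "supporting": 0,
        "stand_alone": 0,
        "benign_strong": 0,
        "benign_supporting": 0,
    }
    for criterion in criteria:
        counts[criterion.strength] += 1
    return counts


def combine_criteria(criteria: CriteriaSet) -> str:
    """Combine criteria into the categorical five-class call (ACMG-AMP 2015).

    Pathogenic:
      (i)   PVS1 with >=1 strong, >=2 moderate, 1 moderate + 1 supporting,
            or >=2 supporting;
      (ii)  >=2 strong;
      (iii) 1 strong with >=3 moderate, 2 moderate + >=2 supporting, or
            1 moderate + >=4 supporting.
    Likely pathogenic: PVS1 + 1 moderate; 1 strong + 1-2 moderate; 1 strong +
      >=2 supporting; >=3 moderate; 2 moderate + >=2 supporting; 1 moderate +
      >=4 supporting.
    Benign: BA1, or >=2 benign-strong. Likely benign: 1 benign-strong +
      1 benign-supporting, or >=2 benign-supporting.
    Pathogenic and benign rules both met -> conflicting evidence -> VUS;
    nothing met -> VUS.
    """
    n = _strength_counts(criteria)
    pvs, ps, pm, pp = n["very_strong"], n["strong"], n["moderate"], n["supporting"]
    ba, bs, bp = n["stand_alone"], n["benign_strong"], n["benign_supporting"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return "vus"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "vus"


def bayesian_posterior(
    criteria: CriteriaSet, config: Optional[BayesConfig] = None
) -> float:
    """Posterior probability of pathogenicity from summed evidence points.

    odds = odds_very_strong ** (points / 8);
    posterior = odds * prior / ((odds - 1) * prior + 1).
    """
    config = config or BayesConfig()
    points = criteria.points()
    odds = config.odds_very_strong ** (points / 8.0)
    return odds * config.prior / ((odds - 1.0) * config.prior + 1.0)


def assign_tier(posterior: float, config: Optional[BayesConfig] = None) -> Optional[int]:
    """Tier 1 above 0.9, tier 2 above 0.499, tier 3 above 0.1; else None.

    All cutoffs are strict lower bounds.
    """
    config = config or BayesConfig()
    if posterior > config.tier1_cutoff:
        return 1
    if posterior > config.tier2_cutoff:
        return 2
    if posterior > config.tier3_cutoff:
        return 3
    return None


def classify(
    call: VariantCall,
    annotation: VariantAnnotation,
    known_variants: dict[tuple, KnownVariantRecord],
    disease_profile: Optional[DiseaseProfile] = None,
    bayes_config: Optional[BayesConfig] = None,
    score_threshold: float = 0.5,
    pm2_threshold: float = PM2_THRESHOLD,
    constrained_genes: frozenset[str] = frozenset(),
    gene_mates: Iterable[tuple[VariantCall, VariantAnnotation]] = (),
) -> ClassifiedVariant:
    """Assign criteria, combine, score and tier one retained call."""
    criteria, pm3_assumed = assign_criteria(
        call,
        annotation,
        known_variants,
        disease_profile=disease_profile,
        score_threshold=score_threshold,
        pm2_threshold=pm2_threshold,
        constrained_genes=constrained_genes,
        gene_mates=gene_mates,
    )
    classification = combine_criteria(criteria)
    posterior = bayesian_posterior(criteria, bayes_config)
    tier = assign_tier(posterior, bayes_config)
    return ClassifiedVariant(
        call=call,
        criteria=criteria,
        classification=classification,
        posterior=posterior,
        tier=tier,
        pm3_assumed_trans=pm3_assumed,
    )
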