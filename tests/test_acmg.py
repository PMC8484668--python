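"""ACMG-AMP engine: criteria assignment rules, the 2015 combining table
(checked against an independent enumeration oracle), the Bayesian posterior
and the tier step function."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoprio.acmg import (
    assign_criteria,
    assign_tier,
    bayesian_posterior,
    classify,
    combine_criteria,
)
from phenoprio.models import (
    CriteriaSet,
    DiseaseProfile,
    KnownVariantRecord,
    VariantAnnotation,
    VariantCall,
)

AR_DISEASE = DiseaseProfile("D-AR", "ar disease", "GENE", "AR",
                            frozenset({"HP:0000407"}))
AD_DISEASE = DiseaseProfile("D-AD", "ad disease", "GENE", "AD",
                            frozenset({"HP:0000407"}))


def call(zyg="heterozygous"):
    return VariantCall("1", 100, "A", "G", zyg, "s")


def ann(consequence="missense", flags=(), scores=None, subpops=None, total=None,
        gene="GENE"):
    return VariantAnnotation(
        gene=gene, consequence=consequence, curated_flags=set(flags),
        insilico_scores=scores or {}, subpop_afs=subpops or {}, total_af=total,
    )


class TestAssignCriteria:
    def test_lof_de_novo_functional_phenotype_match(self):
        # splice-donor null in a LoF-mechanism gene, confirmed de novo,
        # damaging in a functional assay, disease-specific phenotype, AF absent
        a = ann("splice_donor",
                flags=["lof_mechanism_gene", "de_novo_confirmed",
                       "functional_damaging", "phenotype_specific_match"])
        criteria, _ = assign_criteria(call(), a, {}, AD_DISEASE)
        assert criteria.codes == {"PVS1", "PS2", "PS3", "PM2", "PP4"}

    def test_synonymous_benign_scores(self):
        a = ann("synonymous", scores={"REVEL": 0.1, "ada_score": 0.1})
        criteria, _ = assign_criteria(call(), a, {}, AD_DISEASE)
        assert criteria.codes == {"PM2", "BP4"}

    def test_constrained_missense_with_concordant_scores(self):
        a = ann("missense", scores={"REVEL": 0.6, "ada_score": 0.7})
        criteria, _ = assign_criteria(
            call(), a, {}, AD_DISEASE, constrained_genes=frozenset({"GENE"})
        )
        assert criteria.codes == {"PM2", "PP2", "PP3"}

    def test_pvs1_requires_lof_mechanism_flag(self):
        criteria, _ = assign_criteria(call(), ann("stop_gained"), {}, AD_DISEASE)
        assert "PVS1" not in criteria

    def test_pm2_blocked_by_any_observed_frequency(self):
        a = ann(subpops={"gnomAD_EAS": 0.0009})
        criteria, _ = assign_criteria(call(), a, {}, AD_DISEASE)
        assert "PM2" not in criteria
        a_rare = ann(subpops={"gnomAD_EAS": 0.00005})
        criteria, _ = assign_criteria(call(), a_rare, {}, AD_DISEASE)
        assert "PM2" in criteria

    def test_single_insilico_score_suffices(self):
        high, _ = assign_criteria(call(), ann(scores={"REVEL": 0.9}), {}, AD_DISEASE)
        low, _ = assign_criteria(call(), ann(scores={"REVEL": 0.1}), {}, AD_DISEASE)
        assert "PP3" in high and "BP4" not in high
        assert "BP4" in low and "PP3" not in low

    def test_discordant_scores_give_neither(self):
        criteria, _ = assign_criteria(
            call(), ann(scores={"REVEL": 0.9, "ada_score": 0.1}), {}, AD_DISEASE
        )
        assert "PP3" not in criteria and "BP4" not in criteria

    def test_pm3_homozygous_in_recessive_disease(self):
        criteria, assumed = assign_criteria(call("homozygous"), ann(), {}, AR_DISEASE)
        assert "PM3" in criteria and not assumed

    def test_pm3_trans_partner_assumed_for_two_heterozygotes(self):
        mate = VariantCall("1", 200, "C", "T", "heterozygous", "s")
        known = {mate.key: KnownVariantRecord(key=mate.key, assertion="pathogenic")}
        criteria, assumed = assign_criteria(
            call(), ann(), known, AR_DISEASE, gene_mates=[(mate, ann())]
        )
        assert "PM3" in criteria and assumed

    def test_pm3_not_for_dominant_disease(self):
        criteria, _ = assign_criteria(call("homozygous"), ann(), {}, AD_DISEASE)
        assert "PM3" not in criteria

    def test_bs2_population_homozygotes_recessive_only(self):
        a = ann(flags=["population_homozygotes_observed"])
        ar, _ = assign_criteria(call(), a, {}, AR_DISEASE)
        ad, _ = assign_criteria(call(), a, {}, AD_DISEASE)
        assert "BS2" in ar and "BS2" not in ad


# ---------------------------------------------------------------------------
# combining table
# ---------------------------------------------------------------------------

#: the eight printed worked examples (criteria -> class) from the clinical
#: comparison of manual and automated calls
PRINTED_ROWS = [
    ({"PVS1", "PM2", "PP5"}, "pathogenic"),                                  # GJB3 c.538C>T
    ({"PM1", "PM2", "PM3", "PP2", "PP3", "PP5"}, "likely_pathogenic"),       # SLC26A4 c.2168A>G
    ({"PM2", "PM3", "PP3", "PP4"}, "likely_pathogenic"),                     # OTOF c.2521G>A
    ({"PM2", "PP2", "PP3"}, "vus"),                                          # PTPN11 c.1001T>A
    ({"PS2", "PM1", "PM2", "PM5", "PP1", "PP2", "PP3", "PP5"}, "pathogenic"),  # PTPN11 c.922A>G
    ({"PS2", "PM1", "PM2", "PM5", "PP1", "PP2", "PP3", "PP5"}, "pathogenic"),  # PTPN11 c.922A>G (2nd proband)
    ({"PS2", "PM1", "PM2", "PM5", "PM6", "PP2", "PP3", "PP5"}, "pathogenic"),  # PTPN11 c.836A>G
    ({"PVS1", "PS2", "PS3", "PM2", "PP4"}, "pathogenic"),                    # EFTUD2 c.271+1G>A
]


@pytest.mark.parametrize("codes,expected", PRINTED_ROWS)
def test_printed_criteria_rows_reproduce(codes, expected):
    assert combine_criteria(CriteriaSet.from_codes(codes)) == expected


def test_empty_set_is_vus():
    assert combine_criteria(CriteriaSet()) == "vus"


def oracle_combine(pvs, ps, pm, pp, ba, bs, bp):
    """Independent transcription of the 2015 combining table as literal
    rule patterns over evidence counts."""
    pathogenic_rules = [
        pvs >= 1 and ps >= 1,
        pvs >= 1 and pm >= 2,
        pvs >= 1 and pm == 1 and pp >= 1,
        pvs >= 1 and pp >= 2,
        ps >= 2,
        ps == 1 and pm >= 3,
        ps == 1 and pm == 2 and pp >= 2,
        ps == 1 and pm == 1 and pp >= 4,
    ]
    likely_rules = [
        pvs >= 1 and pm == 1,
        ps == 1 and pm in (1, 2),
        ps == 1 and pp >= 2,
        pm >= 3,
        pm == 2 and pp >= 2,
        pm == 1 and pp >= 4,
    ]
    benign_rules = [ba >= 1, bs >= 2]
    likely_benign_rules = [bs == 1 and bp >= 1, bp >= 2]

    path_side = any(pathogenic_rules) or any(likely_rules)
    benign_side = any(benign_rules) or any(likely_benign_rules)
    if path_side and benign_side:
        return "vus"
    if any(pathogenic_rules):
        return "pathogenic"
    if any(likely_rules):
        return "likely_pathogenic"
    if any(benign_rules):
        return "benign"
    if any(likely_benign_rules):
        return "likely_benign"
    return "vus"


def test_combining_table_matches_enumeration_oracle():
    """Exhaustive check over every criteria multiset of size <= 6.

    Distinct codes of the same strength are interchangeable, so the
    enumeration runs over count vectors and materializes one concrete
    criteria set per vector.
    """
    families = {
        "PVS": ["PVS1"],
        "PS": [f"PS{i}" for i in range(1, 5)],
        "PM": [f"PM{i}" for i in range(1, 7)],
        "PP": [f"PP{i}" for i in range(1, 6)],
        "BA": ["BA1"],
        "BS": [f"BS{i}" for i in range(1, 5)],
        "BP": [f"BP{i}" for i in range(1, 8)],
    }
    ranges = [range(len(v) + 1) for v in families.values()]
    n_checked = 0
    for counts in itertools.product(*ranges):
        if sum(counts) > 6:
            continue
        codes = [
            code
            for (family, members), n in zip(families.items(), counts)
            for code in members[:n]
        ]
        got = combine_criteria(CriteriaSet.from_codes(codes))
        expected = oracle_combine(*counts)
        assert got == expected, f"counts={counts}: {got} != {expected}"
        n_checked += 1
    assert n_checked == 1075  # all count vectors with total size <= 6


# ---------------------------------------------------------------------------
# Bayesian posterior and tiers
# ---------------------------------------------------------------------------


class TestBayesianPosterior:
    def test_empty_set_returns_prior(self):
        assert bayesian_posterior(CriteriaSet()) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "codes,expected",
        [
            ({"PVS1", "PM2", "PP5"}, 0.9971),   # 11 points, odds 350**1.375
            ({"PM2", "PP2", "PP3"}, 0.6752),    # 4 points, odds 350**0.5
        ],
    )
    def test_worked_posteriors(self, codes, expected):
        posterior = bayesian_posterior(CriteriaSet.from_codes(codes))
        assert posterior == pytest.approx(expected, abs=1e-4)

    def test_closed_form_agreement(self):
        # independent evaluation of the stated formula
        for codes in ({"PS1"}, {"PM1", "PP3"}, {"BS1", "BP4"}):
            cs = CriteriaSet.from_codes(codes)
            odds = 350.0 ** (cs.points() / 8.0)
            expected = odds * 0.1 / ((odds - 1) * 0.1 + 1)
            assert bayesian_posterior(cs) == pytest.approx(expected, rel=1e-12)

    def test_posterior_in_open_unit_interval(self):
        for codes in ({"PVS1", "PS1", "PS2", "PS3"}, {"BA1", "BS1", "BS2"}):
            p = bayesian_posterior(CriteriaSet.from_codes(codes))
            assert 0.0 < p < 1.0


PATHOGENIC_CODES = ["PVS1"] + [f"PS{i}" for i in range(1, 5)] + \
    [f"PM{i}" for i in range(1, 7)] + [f"PP{i}" for i in range(1, 6)]
BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + \
    [f"BP{i}" for i in range(1, 8)]


@given(
    codes=st.sets(st.sampled_from(PATHOGENIC_CODES + BENIGN_CODES), max_size=8),
    extra=st.sampled_from(PATHOGENIC_CODES + BENIGN_CODES),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_posterior_monotone_in_added_evidence(codes, extra):
    if extra in codes:
        return
    base = bayesian_posterior(CriteriaSet.from_codes(codes))
    grown = bayesian_posterior(CriteriaSet.from_codes(codes | {extra}))
    if extra in PATHOGENIC_CODES:
        assert grown >= base
    else:
        assert grown <= base


class TestTiers:
    @pytest.mark.parametrize(
        "posterior,tier",
        [
            (0.9971, 1), (0.91, 1),
            (0.9, 2), (0.6752, 2), (0.5, 2),
            (0.499, 3), (0.2, 3), (0.11, 3),
            (0.1, None), (0.05, None), (0.0, None),
        ],
    )
    def test_step_function_with_strict_bounds(self, posterior, tier):
        assert assign_tier(posterior) == tier

    def test_tier_non_decreasing_in_posterior(self):
        grid = [i / 1000 for i in range(1001)]
        order = {None: 0, 3: 1, 2: 2, 1: 3}
        tiers = [order[assign_tier(p)] for p in grid]
        assert tiers == sorted(tiers)


class TestClassify:
    def test_bundles_all_four_operations(self):
        a = ann("stop_gained", flags=["lof_mechanism_gene", "clinvar_pathogenic"])
        cv = classify(call(), a, {}, AD_DISEASE)
        assert cv.criteria.codes == {"PVS1", "PM2", "PP5"}
        assert cv.classification == "pathogenic"
        assert cv.posterior == pytest.approx(0.9971, abs=1e-4)
        assert cv.tier == 1
        assert cv.is_candidate

    def test_benign_marked_non_candidate(self):
        a = ann(flags=["functional_benign", "clinvar_benign"],
                scores={"REVEL": 0.05, "ada_score": 0.1},
                subpops={"gnomAD_NFE": 0.01})
        cv = classify(call(), a, {}, AD_DISEASE)
        assert cv.classification in ("benign", "likely_benign")
        assert not cv.is_candidate
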