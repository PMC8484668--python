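"""Shared fixtures: the packaged demo knowledge base, a tiny hand-drawn
ontology, and programmatic builders for the two human-vs-machine discordance
scenarios (a proband with a monoallelic recessive variant where the
automated pipeline instead selects an inheritance-consistent dominant one).
"""

from __future__ import annotations

import pytest

from phenoprio import (
    PatientPhenotype,
    PipelineConfig,
    default_kb_path,
    load_knowledge_base,
    prioritize_case,
)
from phenoprio.models import Ontology, VariantCall, variant_key


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base(default_kb_path())


@pytest.fixture(scope="session")
def mini_ontology():
    """Seven terms, two branches under one root:

        root
        ├── A ── A1 ── A1a
        │        └──── A1b
        └── B ── B1
    """
    parents = {
        "HP:R": frozenset(),
        "HP:A": frozenset({"HP:R"}),
        "HP:A1": frozenset({"HP:A"}),
        "HP:A1a": frozenset({"HP:A1"}),
        "HP:A1b": frozenset({"HP:A1"}),
        "HP:B": frozenset({"HP:R"}),
        "HP:B1": frozenset({"HP:B"}),
    }
    return Ontology(parents, root="HP:R")


def _het(chrom, pos, ref, alt, sample):
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt,
                       zygosity="heterozygous", sample_id=sample)


@pytest.fixture(scope="session")
def replay_eva_case(kb):
    """Proband with unilateral EVA + Mondini deformity carrying a pathogenic
    dominant GJB3 stop variant and a monoallelic recessive SLC26A4 missense.

    Returns (automated_result, human_selected_keys)."""
    gjb3 = _het("1", 35250398, "C", "T", "SB316-522")
    slc = _het("7", 107350577, "A", "G", "SB316-522")
    annotations = {
        gjb3.key: kb.causal_annotations[gjb3.key],
        slc.key: kb.causal_annotations[slc.key],
    }
    patient = PatientPhenotype(
        case_id="SB316-522",
        hpo_terms=frozenset({"HP:0011389", "HP:0008560", "HP:0000407"}),
    )
    result = prioritize_case([gjb3, slc], annotations, patient, kb,
                             config=PipelineConfig())
    return result, {slc.key}


@pytest.fixture(scope="session")
def replay_ansd_case(kb):
    """Proband with auditory neuropathy carrying a monoallelic recessive OTOF
    missense and a dominant-compatible PTPN11 VUS.

    Returns (automated_result, human_selected_keys)."""
    otof = _het("2", 26695775, "C", "T", "SB422-823")
    ptpn = _het("12", 112915602, "T", "A", "SB422-823")
    annotations = {
        otof.key: kb.causal_annotations[otof.key],
        ptpn.key: kb.causal_annotations[ptpn.key],
    }
    patient = PatientPhenotype(
        case_id="SB422-823",
        hpo_terms=frozenset({"HP:0000404", "HP:0008527"}),
    )
    result = prioritize_case([otof, ptpn], annotations, patient, kb,
                             config=PipelineConfig())
    return result, {otof.key}


GJB3_KEY = variant_key("1", 35250398, "C", "T")
SLC26A4_KEY = variant_key("7", 107350577, "A", "G")
OTOF_KEY = variant_key("2", 26695775, "C", "T")
PTPN11_VUS_KEY = variant_key("12", 112915602, "T", "A")
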