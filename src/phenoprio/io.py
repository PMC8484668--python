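"""Readers and writers for the pipeline's external formats.

VCF v4.2 (via cyvcf2), OBO 1.2 ontologies (via obonet), the TSV knowledge-base
tables (disease map, known variants, annotation sidecar) and JSON results.
All readers are deterministic functions of file bytes; TSV/JSON round-trips
are lossless.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import obonet
import pandas as pd
import yaml
from cyvcf2 import VCF

from .models import (
    CandidateVariant,
    DiseaseProfile,
    KnownVariantRecord,
    Ontology,
    PrioritizationResult,
    SEX_CHROMOSOMES,
    VariantAnnotation,
    VariantCall,
    format_key,
    normalize_chrom,
    parse_key,
    variant_key,
)

PathLike = Union[str, Path]

#: documented 14-column annotation sidecar header
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "total_af",
    "subpop_afs",
    "insilico_scores",
    "curated_flags",
    "notes",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: PathLike) -> list[VariantCall]:
    """Read a single-sample VCF into one ``VariantCall`` per carried ALT.

    Multi-allelic records are split; zygosity is derived from GT (haploid
    genotypes on X/Y/MT read as hemizygous). Input order is preserved.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if len(samples) != 1:
        raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
    sample = samples[0]
    calls: list[VariantCall] = []
    for record in vcf:
        gt = record.genotypes
        if not gt:
            raise ValueError(
                f"missing GT at {record.CHROM}:{record.POS} {record.REF}>{record.ALT}"
            )
        alleles = [a for a in gt[0][:-1] if a != -2]  # trailing element is phasing
        if not alleles or all(a == -1 for a in alleles):
            raise ValueError(
                f"missing GT at {record.CHROM}:{record.POS} {record.REF}>{record.ALT}"
            )
        chrom = normalize_chrom(record.CHROM)
        haploid = len(alleles) == 1
        for alt_index, alt in enumerate(record.ALT, start=1):
            copies = alleles.count(alt_index)
            if copies == 0:
                continue
            if haploid:
                zyg = "hemizygous" if chrom in SEX_CHROMOSOMES else "homozygous"
            elif copies == 2:
                zyg = "homozygous"
            else:
                zyg = "heterozygous"
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    zygosity=zyg,
                    sample_id=sample,
                )
            )
    return calls


def read_vcf_build(path: PathLike) -> Optional[str]:
    """Extract the genome-build string from ``##genome_build=`` or ``##reference=``."""
    vcf = VCF(str(path))
    header = vcf.raw_header
    for line in header.splitlines():
        m = re.match(r"##(?:genome_build|reference)=(.+)$", line)
        if m:
            return m.group(1).strip()
    return None


_ZYG_TO_GT = {"heterozygous": "0/1", "homozygous": "1/1", "hemizygous": "1"}


def write_vcf(
    records: list[VariantCall],
    path: PathLike,
    sample_id: str = "SAMPLE",
    build: str = "GRCh37",
) -> None:
    """Write calls as a minimal single-sample VCF v4.2, coordinate-sorted."""
    records = sorted(records, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    lines = [
        "##fileformat=VCFv4.2",
        f"##genome_build={build}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(c.chrom for c in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for c in records:
        gt = _ZYG_TO_GT[c.zygosity]
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation sidecar
# ---------------------------------------------------------------------------


def _parse_map(cell: str, name: str, row: int) -> dict[str, float]:
    """Parse ``key=value;key=value`` cells; empty or '.' means absent."""
    if cell in ("", "."):
        return {}
    out: dict[str, float] = {}
    for item in cell.split(";"):
        if not item:
            continue
        try:
            key, value = item.split("=")
            out[key] = float(value)
        except ValueError as exc:
            raise ValueError(f"row {row}: malformed {name} cell {cell!r}") from exc
    return out


def _fmt_map(mapping: dict[str, float]) -> str:
    if not mapping:
        return "."
    return ";".join(f"{k}={v:g}" for k, v in sorted(mapping.items()))


def read_annotation_table(
    path: PathLike,
) -> dict[tuple[str, int, str, str], VariantAnnotation]:
    """Read the TSV annotation sidecar into a map keyed by normalized variant.

    Absent cells ('' or '.') become absent values, never 0. Duplicate keys and
    out-of-range frequencies raise, naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    table: dict[tuple[str, int, str, str], VariantAnnotation] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = variant_key(row.chrom, int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"row {i}: duplicate variant key {format_key(key)}")
        total_af = None if row.total_af in ("", ".") else float(row.total_af)
        flags_cell = row.curated_flags
        flags = (
            set()
            if flags_cell in ("", ".")
            else {f for f in flags_cell.split(";") if f}
        )
        try:
            table[key] = VariantAnnotation(
                gene=row.gene,
                transcript=row.transcript if row.transcript != "." else "",
                hgvs_c=row.hgvs_c if row.hgvs_c != "." else "",
                hgvs_p=row.hgvs_p if row.hgvs_p != "." else "",
                consequence=row.consequence,
                subpop_afs=_parse_map(row.subpop_afs, "subpop_afs", i),
                total_af=total_af,
                insilico_scores=_parse_map(row.insilico_scores, "insilico_scores", i),
                curated_flags=flags,
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return table


def write_annotation_table(
    rows: list[tuple[VariantCall, VariantAnnotation]], path: PathLike
) -> None:
    """Write (call, annotation) pairs as the 14-column sidecar TSV."""
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for call, ann in rows:
        total = "." if ann.total_af is None else f"{ann.total_af:g}"
        flags = ";".join(sorted(ann.curated_flags)) or "."
        lines.append(
            "\t".join(
                [
                    call.chrom,
                    str(call.pos),
                    call.ref,
                    call.alt,
                    ann.gene,
                    ann.transcript or ".",
                    ann.hgvs_c or ".",
                    ann.hgvs_p or ".",
                    ann.consequence,
                    total,
                    _fmt_map(ann.subpop_afs),
                    _fmt_map(ann.insilico_scores),
                    flags,
                    ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


def load_ontology(path: PathLike) -> Ontology:
    """Load an OBO 1.2 ontology as a rooted DAG, dropping obsolete terms."""
    graph = obonet.read_obo(str(path))
    obsolete = {
        n for n, data in graph.nodes(data=True) if data.get("is_obsolete") == "true"
    }
    parents: dict[str, set[str]] = {}
    for node in graph.nodes:
        if node in obsolete:
            continue
        isa = {
            v
            for _, v, k in graph.out_edges(node, keys=True)
            if k == "is_a" and v not in obsolete
        }
        parents[node] = isa
    check = nx.DiGraph(
        (child, parent) for child, ps in parents.items() for parent in ps
    )
    if check.number_of_nodes() and not nx.is_directed_acyclic_graph(check):
        raise ValueError("ontology is_a graph contains a cycle")
    roots = [t for t, ps in parents.items() if not ps]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root term, found {sorted(roots)}")
    return Ontology(
        {t: frozenset(ps) for t, ps in parents.items()}, root=roots[0]
    )


# ---------------------------------------------------------------------------
# knowledge-base tables
# ---------------------------------------------------------------------------


def read_disease_map(path: PathLike) -> list[DiseaseProfile]:
    """Read the gene–disease–inheritance–HPO table (one profile per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    profiles = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        terms = frozenset(t for t in row.hpo_terms.split(";") if t)
        try:
            profiles.append(
                DiseaseProfile(
                    disease_id=row.disease_id,
                    name=row.name,
                    gene=row.gene,
                    inheritance=row.inheritance,
                    hpo_terms=terms,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return profiles


def read_known_variants(
    path: PathLike,
) -> dict[tuple[str, int, str, str], KnownVariantRecord]:
    """Read the curated known-variant table keyed by normalized variant."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[tuple[str, int, str, str], KnownVariantRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = variant_key(row.chrom, int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"row {i}: duplicate known-variant key {format_key(key)}")
        try:
            table[key] = KnownVariantRecord(
                key=key,
                assertion=row.assertion,
                source=row.source,
                filter_exempt=row.filter_exempt.lower() in ("1", "true", "yes"),
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return table


class KnowledgeBase:
    """The bundle of curated inputs: diseases, known variants, ontology."""

    def __init__(
        self,
        diseases: list[DiseaseProfile],
        known_variants: dict[tuple[str, int, str, str], KnownVariantRecord],
        ontology: Ontology,
        constrained_genes: frozenset[str] = frozenset(),
        build: str = "GRCh37",
        founder_subpopulations: frozenset[str] = frozenset({"Finnish", "Jewish"}),
        causal_annotations: Optional[
            dict[tuple[str, int, str, str], VariantAnnotation]
        ] = None,
    ):
        self.diseases = diseases
        self.known_variants = known_variants
        self.ontology = ontology
        self.constrained_genes = constrained_genes
        self.build = build
        self.founder_subpopulations = founder_subpopulations
        self.causal_annotations = causal_annotations or {}
        self._by_gene: dict[str, list[DiseaseProfile]] = {}
        for profile in diseases:
            self._by_gene.setdefault(profile.gene, []).append(profile)

    def diseases_for_gene(self, gene: str) -> list[DiseaseProfile]:
        return self._by_gene.get(gene, [])


def load_knowledge_base(kb_dir: PathLike) -> KnowledgeBase:
    """Load a knowledge-base directory (meta.yaml + TSV tables + OBO)."""
    kb_dir = Path(kb_dir)
    meta = yaml.safe_load((kb_dir / "meta.yaml").read_text())
    ontology = load_ontology(kb_dir / meta.get("ontology", "hpo_synthetic_mini.obo"))
    diseases = read_disease_map(kb_dir / meta.get("disease_map", "disease_map.tsv"))
    for profile in diseases:
        missing = profile.hpo_terms - ontology.terms
        if missing:
            raise ValueError(
                f"{profile.disease_id}: HPO terms not in ontology: {sorted(missing)}"
            )
    known = read_known_variants(kb_dir / meta.get("known_variants", "known_variants.tsv"))
    constrained_path = kb_dir / meta.get("constrained_genes", "missense_constrained.txt")
    constrained = frozenset(
        line.strip()
        for line in constrained_path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    causal_path = kb_dir / meta.get("causal_annotations", "causal_annotations.tsv")
    causal = read_annotation_table(causal_path) if causal_path.exists() else {}
    return KnowledgeBase(
        diseases=diseases,
        known_variants=known,
        ontology=ontology,
        constrained_genes=constrained,
        build=str(meta.get("build", "GRCh37")),
        founder_subpopulations=frozenset(
            meta.get("founder_subpopulations", ["Finnish", "Jewish"])
        ),
        causal_annotations=causal,
    )


def default_kb_path() -> Path:
    """Path of the packaged synthetic demo knowledge base."""
    return Path(__file__).parent / "data" / "kb_demo"


# ---------------------------------------------------------------------------
# results JSON
# ---------------------------------------------------------------------------


def _candidate_to_dict(c: CandidateVariant) -> dict:
    cv = c.classified
    return {
        "variant": format_key(cv.call.key),
        "zygosity": cv.call.zygosity,
        "criteria": sorted(cv.criteria.codes),
        "classification": cv.classification,
        "posterior": round(cv.posterior, 10),
        "tier": cv.tier,
        "pm3_assumed_trans": cv.pm3_assumed_trans,
        "disease_id": c.disease.disease_id,
        "gene": c.disease.gene,
        "inheritance": c.disease.inheritance,
        "similarity": round(c.similarity, 10),
        "inheritance_consistent": c.inheritance_consistent,
        "carrier_flag": c.carrier_flag,
        "rank": c.rank,
    }


def result_to_dict(result: PrioritizationResult) -> dict:
    return {
        "case_id": result.case_id,
        "status": result.status,
        "selected": [format_key(k) for k in result.selected],
        "classifications": dict(sorted(result.classifications.items())),
        "ranked_candidates": [_candidate_to_dict(c) for c in result.ranked_candidates],
        "filter_log": result.filter_log,
        "provenance": result.provenance,
    }


def write_result(result: PrioritizationResult, path: PathLike) -> None:
    """Serialize a case result as deterministic (sorted-key) JSON."""
    Path(path).write_text(
        json.dumps(result_to_dict(result), indent=2, sort_keys=True) + "\n"
    )


def read_result(path: PathLike) -> dict:
    """Read a result JSON back as a dict (keys formatted as ``chrom:pos:ref>alt``)."""
    return json.loads(Path(path).read_text())


def result_selected_keys(result_dict: dict) -> set[tuple[str, int, str, str]]:
    return {parse_key(k) for k in result_dict["selected"]}
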