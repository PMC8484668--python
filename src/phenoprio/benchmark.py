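"""Synthetic spike-in exome benchmark.

Builds exome-like single-proband VCFs consisting of common background
variation — every site with minor allele frequency above 10% in every
simulated subpopulation, so the BA1 filter removes all of it — implants one
known pathogenic or likely-pathogenic deafness variant (or a biallelic pair
for recessive genes) with inheritance-appropriate zygosity, sets the patient
phenotype from the matched disease profile, and measures how the end-to-end
prioritizer ranks the implanted variant. Per-case background sizes are drawn
uniformly from 60,000–90,000 records (a reduced mode is available for quick
runs).

The background is simulated with seeded generators on exome-like coordinates
rather than sampled from real population VCFs, so the benchmark needs no
download; the spiked variants and their annotations come from the knowledge
base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from tempfile import TemporaryDirectory
from typing import Optional

import numpy as np

from .io import (
    KnowledgeBase,
    read_annotation_table,
    read_vcf,
    read_vcf_build,
    write_annotation_table,
    write_vcf,
)
from .models import (
    PatientPhenotype,
    VariantAnnotation,
    VariantCall,
    format_key,
)
from .prioritize import PipelineConfig, prioritize_case

#: per-case background size range (count of common background records)
BACKGROUND_RANGE = (60_000, 90_000)

#: autosome lengths (Mb, coarse) used to spread background sites exome-like
_CHROM_WEIGHTS = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155,
}

_BASES = np.array(list("ACGT"))
_SUBPOPS = ("gnomAD_EAS", "gnomAD_NFE", "gnomAD_AFR")


@dataclass
class BackgroundPool:
    """Common-variant pool: unique sites, every AF strictly above 10%."""

    sites: list[tuple[str, int, str, str]]
    subpop_afs: list[dict[str, float]]
    annotations: list[VariantAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class SpikePlan:
    """Which causal variant(s) to implant for one synthetic case."""

    case_id: str
    disease_id: str
    causal: list[tuple[tuple[str, int, str, str], str]]  # (key, zygosity)
    hpo_terms: frozenset[str]


def generate_pool(n_sites: int, seed: int) -> BackgroundPool:
    """Draw *n_sites* unique exome-like common sites, AF uniform in (0.10, 0.5].

    Deterministic per seed. Each site carries one AF per simulated
    subpopulation, all strictly above the 10% bound, and a benign
    (synonymous) consequence annotation.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    rng = np.random.default_rng(seed)
    chroms = list(_CHROM_WEIGHTS)
    weights = np.array([_CHROM_WEIGHTS[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    seen: set[tuple[str, int]] = set()
    sites: list[tuple[str, int, str, str]] = []
    afs: list[dict[str, float]] = []
    annotations: list[VariantAnnotation] = []
    while len(sites) < n_sites:
        need = n_sites - len(sites)
        chrom_idx = rng.choice(len(chroms), size=need, p=weights)
        # cluster positions into ~2 kb "exons" spaced across the chromosome
        exon = rng.integers(1, 60_000, size=need)
        offset = rng.integers(0, 2_000, size=need)
        ref_i = rng.integers(0, 4, size=need)
        alt_shift = rng.integers(1, 4, size=need)
        af_draw = 0.5 - rng.uniform(0.0, 0.4, size=(need, len(_SUBPOPS)))
        for j in range(need):
            chrom = chroms[chrom_idx[j]]
            pos = int(exon[j]) * 3_000 + int(offset[j]) + 1
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            ref = _BASES[ref_i[j]]
            alt = _BASES[(ref_i[j] + alt_shift[j]) % 4]
            sites.append((chrom, pos, str(ref), str(alt)))
            site_afs = {
                pop: float(af_draw[j, k]) for k, pop in enumerate(_SUBPOPS)
            }
            afs.append(site_afs)
            annotations.append(
                VariantAnnotation(
                    gene=f"BG{len(sites):06d}",
                    consequence="synonymous",
                    subpop_afs=site_afs,
                    total_af=float(np.mean(list(site_afs.values()))),
                )
            )
    return BackgroundPool(sites=sites, subpop_afs=afs, annotations=annotations)


def default_spike_plans(kb: KnowledgeBase) -> list[SpikePlan]:
    """The packaged 21-case plan set: AD/XL/MT singles, AR homozygotes and
    compound heterozygotes, including the common GJB2 filter-exempt pair."""

    def key_of(source_substring: str) -> tuple[str, int, str, str]:
        for key, record in kb.known_variants.items():
            if source_substring in record.source:
                return key
        raise KeyError(f"no known variant matching {source_substring!r}")

    spec = [
        # case, disease, [(variant, zygosity), ...]
        ("IS01", "DFNA3B", [("GJB3:c.538C>T", "heterozygous")]),
        ("IS02", "NS1", [("PTPN11:c.922A>G", "heterozygous")]),
        ("IS03", "NSML", [("PTPN11:c.836A>G", "heterozygous")]),
        ("IS04", "MFDGA", [("EFTUD2:c.271+1G>A", "heterozygous")]),
        ("IS05", "DFNA2A", [("KCNQ4:c.827G>C", "heterozygous")]),
        ("IS06", "DFNA6", [("WFS1:c.2051C>T", "heterozygous")]),
        ("IS07", "DFNA9", [("COCH:c.151C>T", "heterozygous")]),
        ("IS08", "DFNA8", [("TECTA:c.5597C>T", "heterozygous")]),
        ("IS09", "DFNA20", [("ACTG1:c.833C>T", "heterozygous")]),
        (
            "IS10",
            "DFNB1A",
            [("GJB2:c.101T>C", "heterozygous"), ("GJB2:c.109G>A", "heterozygous")],
        ),
        ("IS11", "DFNB1A", [("GJB2:c.101T>C", "homozygous")]),
        ("IS12", "DFNB1A", [("GJB2:c.109G>A", "homozygous")]),
        (
            "IS13",
            "DFNB1A",
            [("GJB2:c.235delC", "heterozygous"), ("GJB2:c.299_300delAT", "heterozygous")],
        ),
        ("IS14", "DFNB4", [("SLC26A4:c.919-2A>G", "homozygous")]),
        (
            "IS15",
            "DFNB4",
            [("SLC26A4:c.2168A>G", "heterozygous"), ("SLC26A4:c.1229C>T", "heterozygous")],
        ),
        (
            "IS16",
            "DFNB9",
            [("OTOF:c.2521G>A", "heterozygous"), ("OTOF:c.5816G>A", "heterozygous")],
        ),
        ("IS17", "DFNB2", [("MYO7A:c.6070C>T", "homozygous")]),
        ("IS18", "DFNB7", [("TMC1:c.100C>T", "homozygous")]),
        ("IS19", "DFNB8", [("TMPRSS3:c.916G>A", "homozygous")]),
        ("IS20", "DFNX2", [("POU3F4:c.499C>T", "hemizygous")]),
        ("IS21", "MTRNR1D", [("MT-RNR1:m.1555A>G", "hemizygous")]),
    ]
    diseases = {d.disease_id: d for d in kb.diseases}
    plans = []
    for case_id, disease_id, causal in spec:
        plans.append(
            SpikePlan(
                case_id=case_id,
                disease_id=disease_id,
                causal=[(key_of(name), zyg) for name, zyg in causal],
                hpo_terms=diseases[disease_id].hpo_terms,
            )
        )
    return plans


def synthesize_case(
    pool: BackgroundPool,
    plan: SpikePlan,
    kb: KnowledgeBase,
    out_dir: Path,
    seed: int,
    n_background: Optional[int] = None,
) -> tuple[Path, Path, PatientPhenotype]:
    """Write one synthetic case: VCF + annotation sidecar + phenotype.

    Samples ``n_background`` sites from the pool (drawn uniformly from
    60,000–90,000 when not given), assigns background genotypes from each
    site's allele frequency, implants the plan's causal record(s) at the
    planned zygosity, and writes a coordinate-sorted VCF with its paired
    sidecar TSV. Returns (vcf_path, sidecar_path, phenotype).
    """
    rng = np.random.default_rng(seed)
    if n_background is None:
        n_background = int(rng.integers(BACKGROUND_RANGE[0], BACKGROUND_RANGE[1] + 1))
    if n_background > len(pool):
        raise ValueError(
            f"pool has {len(pool)} sites, cannot sample {n_background}"
        )
    for key, _ in plan.causal:
        if key not in kb.known_variants:
            raise KeyError(f"causal variant {format_key(key)} absent from KB")
        if key not in kb.causal_annotations:
            raise KeyError(f"no causal annotation for {format_key(key)}")

    # never let a background site shadow a causal position
    causal_positions = {(key[0], key[1]) for key, _ in plan.causal}
    allowed = [
        i
        for i, (chrom, pos, _, _) in enumerate(pool.sites)
        if (chrom, pos) not in causal_positions
    ]
    if n_background > len(allowed):
        raise ValueError(
            f"pool has {len(allowed)} usable sites, cannot sample {n_background}"
        )
    idx = rng.choice(len(allowed), size=n_background, replace=False)
    calls: list[VariantCall] = []
    rows: list[tuple[VariantCall, VariantAnnotation]] = []
    hom_draw = rng.random(n_background)
    for j, i in enumerate(idx):
        chrom, pos, ref, alt = pool.sites[allowed[int(i)]]
        af = max(pool.subpop_afs[allowed[int(i)]].values())
        # homozygous with probability af (conditioned on carrying the allele)
        zyg = "homozygous" if hom_draw[j] < af else "heterozygous"
        if chrom in ("X", "Y", "MT"):
            zyg = "hemizygous"
        call = VariantCall(chrom=chrom, pos=int(pos), ref=ref, alt=alt, zygosity=zyg,
                           sample_id=plan.case_id)
        calls.append(call)
        rows.append((call, pool.annotations[allowed[int(i)]]))
    for key, zyg in plan.causal:
        chrom, pos, ref, alt = key
        call = VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, zygosity=zyg,
                           sample_id=plan.case_id)
        calls.append(call)
        rows.append((call, kb.causal_annotations[key]))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{plan.case_id}.vcf"
    sidecar_path = out_dir / f"{plan.case_id}.annotations.tsv"
    write_vcf(calls, vcf_path, sample_id=plan.case_id, build=kb.build)
    rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].ref, r[0].alt))
    write_annotation_table(rows, sidecar_path)
    phenotype = PatientPhenotype(case_id=plan.case_id, hpo_terms=plan.hpo_terms)
    return vcf_path, sidecar_path, phenotype


@dataclass
class BenchmarkReport:
    """Per-case causal ranks and overall recall at rank 1."""

    case_ranks: dict[str, Optional[int]]
    n_cases: int
    n_top1: int
    recall_at_1: float
    n_background: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "case_ranks": self.case_ranks,
            "n_cases": self.n_cases,
            "n_top1": self.n_top1,
            "recall_at_1": self.recall_at_1,
            "n_background": self.n_background,
        }


def run_benchmark(
    kb: KnowledgeBase,
    config: Optional[PipelineConfig] = None,
    plans: Optional[list[SpikePlan]] = None,
    seed: int = 0,
    background_range: tuple[int, int] = BACKGROUND_RANGE,
    workdir: Optional[Path] = None,
) -> BenchmarkReport:
    """Synthesize every planned case, prioritize it, and report causal ranks.

    A case counts toward recall@1 when the top-ranked variant is one of its
    implanted causal variants; ``case_ranks`` records the best rank any
    causal variant achieved (None when unranked / not found).
    """
    config = config or PipelineConfig(seed=seed)
    plans = plans if plans is not None else default_spike_plans(kb)
    rng = np.random.default_rng(seed)
    pool = generate_pool(background_range[1], seed=int(rng.integers(2**31)))

    def run_in(directory: Path) -> BenchmarkReport:
        case_ranks: dict[str, Optional[int]] = {}
        n_background_used: dict[str, int] = {}
        n_top1 = 0
        for plan in plans:
            n_bg = int(rng.integers(background_range[0], background_range[1] + 1))
            case_seed = int(rng.integers(2**31))
            vcf_path, sidecar_path, phenotype = synthesize_case(
                pool, plan, kb, directory, seed=case_seed, n_background=n_bg
            )
            calls = read_vcf(vcf_path)
            annotations = read_annotation_table(sidecar_path)
            result = prioritize_case(
                calls,
                annotations,
                phenotype,
                kb,
                config=config,
                vcf_build=read_vcf_build(vcf_path),
            )
            causal_keys = {key for key, _ in plan.causal}
            ranks = [
                c.rank
                for c in result.ranked_candidates
                if c.rank is not None and c.classified.call.key in causal_keys
            ]
            best = min(ranks) if ranks else None
            case_ranks[plan.case_id] = best
            n_background_used[plan.case_id] = n_bg
            if best == 1:
                n_top1 += 1
        return BenchmarkReport(
            case_ranks=case_ranks,
            n_cases=len(plans),
            n_top1=n_top1,
            recall_at_1=n_top1 / len(plans) if plans else 0.0,
            n_background=n_background_used,
        )

    if workdir is not None:
        return run_in(Path(workdir))
    with TemporaryDirectory() as tmp:
        return run_in(Path(tmp))
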