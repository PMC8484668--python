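"""Domain types shared across the prioritization pipeline.

Everything downstream of file parsing works on the small, validated value
objects defined here: variant calls with genotype, their functional/population
annotations, ACMG-AMP criteria sets, disease profiles with HPO terms, and the
per-case prioritization result.

Coordinates are 1-based and fully closed, as in VCF. All internal variant keys
use VCF-normalized alleles (shared suffix then prefix trimmed, position
adjusted) and chromosome names without a ``chr`` prefix, so a variant written
``chr7:107323898 CAG>CG`` and one written ``7:107323899 AG>G`` compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

# ---------------------------------------------------------------------------
# controlled vocabularies
# ---------------------------------------------------------------------------

ZYGOSITIES = ("heterozygous", "homozygous", "hemizygous")

CONSEQUENCES = (
    "missense",
    "stop_gained",
    "frameshift",
    "splice_donor",
    "splice_acceptor",
    "start_lost",
    "synonymous",
    "other",
)

#: Consequences eligible for PVS1 (predicted null) in a loss-of-function gene.
LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "start_lost"}
)

CURATED_FLAGS = frozenset(
    {
        "de_novo_confirmed",
        "de_novo_assumed",
        "functional_damaging",
        "functional_benign",
        "segregates",
        "hotspot_domain",
        "clinvar_pathogenic",
        "clinvar_benign",
        "same_protein_change_pathogenic",
        "other_change_same_residue_pathogenic",
        "lof_mechanism_gene",
        "phenotype_specific_match",
        "population_homozygotes_observed",
    }
)

INHERITANCE_MODES = ("AD", "AR", "XL", "MT")

CLASSIFICATIONS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")

ASSERTIONS = ("pathogenic", "likely_pathogenic", "benign", "vus")

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25})

SEX_CHROMOSOMES = frozenset({"X", "Y", "MT"})


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr`` prefix and map ``M`` to ``MT``."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c in ("M", "m") else c


def chrom_sort_key(chrom: str) -> int:
    """Karyotype ordering; unknown contigs sort after MT, alphabetically."""
    return _CHROM_ORDER.get(normalize_chrom(chrom), 26)


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align to minimal representation: trim shared suffix, then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalized ``(chrom, pos, ref, alt)`` tuple used as identity everywhere."""
    pos, ref, alt = normalize_alleles(int(pos), ref.upper(), alt.upper())
    return (normalize_chrom(chrom), pos, ref, alt)


def format_key(key: tuple[str, int, str, str]) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"


def parse_key(text: str) -> tuple[str, int, str, str]:
    chrom, pos, alleles = text.split(":")
    ref, alt = alleles.split(">")
    return variant_key(chrom, int(pos), ref, alt)


_ALLELE_CHARS = set("ACGT")


def _check_allele(allele: str) -> bool:
    return bool(allele) and set(allele.upper()) <= _ALLELE_CHARS


# ---------------------------------------------------------------------------
# variant-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCall:
    """One genomic variant with its genotype in a single proband."""

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not (_check_allele(self.ref) and _check_allele(self.alt)):
            raise ValueError(
                f"alleles must be non-empty over ACGT: {self.ref!r}>{self.alt!r}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


def _check_unit(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class VariantAnnotation:
    """Functional and population annotation for one variant.

    Unknown values are *absent* (``None`` / missing map entry), never 0: the
    frequency filter and PM2 both distinguish "rare" from "never observed".
    """

    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = "other"
    subpop_afs: dict[str, float] = field(default_factory=dict)
    total_af: Optional[float] = None
    insilico_scores: dict[str, float] = field(default_factory=dict)
    curated_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for pop, af in self.subpop_afs.items():
            _check_unit(f"subpop AF {pop}", af)
        _check_unit("total_af", self.total_af)
        for tool, score in self.insilico_scores.items():
            _check_unit(f"in-silico score {tool}", score)
        bad = self.curated_flags - CURATED_FLAGS
        if bad:
            raise ValueError(f"unknown curated flags: {sorted(bad)}")

    def provided_afs(self) -> list[float]:
        """All frequencies actually observed (subpopulations plus total)."""
        afs = list(self.subpop_afs.values())
        if self.total_af is not None:
            afs.append(self.total_af)
        return afs


@dataclass(frozen=True)
class KnownVariantRecord:
    """Curated assertion for a variant in the knowledge base."""

    key: tuple[str, int, str, str]
    assertion: str
    source: str = ""
    filter_exempt: bool = False

    def __post_init__(self) -> None:
        if self.assertion not in ASSERTIONS:
            raise ValueError(f"unknown assertion {self.assertion!r}")


# ---------------------------------------------------------------------------
# phenotype types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseProfile:
    """One gene–disease–inheritance association with its HPO phenotype set.

    Genes causing disease under several inheritance modes get one profile per
    mode.
    """

    disease_id: str
    name: str
    gene: str
    inheritance: str
    hpo_terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if not self.hpo_terms:
            raise ValueError(f"{self.disease_id}: hpo_terms must be non-empty")


@dataclass(frozen=True)
class PatientPhenotype:
    """A proband's phenotype as a set of HPO term IDs."""

    case_id: str
    hpo_terms: frozenset[str]


class Ontology:
    """A DAG of phenotype terms (HPO-shaped) with ancestor queries.

    ``parents`` maps each term to its ``is_a`` parents; the root is the unique
    term with none. Ancestor sets include the term itself and are memoized.
    """

    def __init__(self, parents: Mapping[str, frozenset[str]], root: str):
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        self.root = root
        self.terms: frozenset[str] = frozenset(self.parents)
        if root not in self.terms:
            raise ValueError(f"root {root!r} not among terms")
        self._anc: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of *term*, inclusive of the term itself."""
        cached = self._anc.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"term {term!r} not in ontology")
        result = {term}
        for parent in self.parents[term]:
            result |= self.ancestors(parent)
        frozen = frozenset(result)
        self._anc[term] = frozen
        return frozen

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        return self.ancestors(t1) & self.ancestors(t2)


# ---------------------------------------------------------------------------
# classification types
# ---------------------------------------------------------------------------

#: default evidence strength by criterion-code prefix
_PREFIX_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "benign_strong",
    "BP": "benign_supporting",
}

CRITERION_CODES = tuple(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

#: evidence points per strength (benign evidence counts negative)
STRENGTH_POINTS = {
    "very_strong": 8,
    "strong": 4,
    "moderate": 2,
    "supporting": 1,
    "benign_supporting": -1,
    "benign_strong": -4,
    "stand_alone": -8,
}


def default_strength(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_STRENGTH[prefix]
    raise ValueError(f"unknown criterion code {code!r}")


@dataclass(frozen=True)
class Criterion:
    """One ACMG-AMP evidence item; strength defaults from the code prefix."""

    code: str
    strength: str = ""

    def __post_init__(self) -> None:
        if self.code not in CRITERION_CODES:
            raise ValueError(f"unknown criterion code {self.code!r}")
        if not self.strength:
            object.__setattr__(self, "strength", default_strength(self.code))
        elif self.strength not in STRENGTH_POINTS:
            raise ValueError(f"unknown strength {self.strength!r}")

    @property
    def points(self) -> int:
        return STRENGTH_POINTS[self.strength]


class CriteriaSet:
    """A duplicate-free set of assigned criteria."""

    def __init__(self, criteria: Iterable[Criterion] = ()):
        items = list(criteria)
        codes = [c.code for c in items]
        if len(codes) != len(set(codes)):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate criterion codes: {dupes}")
        self._by_code: dict[str, Criterion] = {c.code: c for c in items}

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CriteriaSet":
        return cls(Criterion(code) for code in codes)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._by_code)

    def __iter__(self):
        return iter(sorted(self._by_code.values(), key=lambda c: CRITERION_CODES.index(c.code)))

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __eq__(self, other) -> bool:
        if not isinstance(other, CriteriaSet):
            return NotImplemented
        return self._by_code == other._by_code

    def __repr__(self) -> str:
        return "CriteriaSet({%s})" % ", ".join(c.code for c in self)

    def points(self) -> int:
        return sum(c.points for c in self._by_code.values())

    def add(self, criterion: Criterion) -> "CriteriaSet":
        """Return a new set with *criterion* added (duplicate code rejected)."""
        return CriteriaSet(list(self._by_code.values()) + [criterion])


@dataclass
class BayesConfig:
    """Parameters of the point-based Bayesian pathogenicity score.

    Evidence strengths map to points (supporting 1, moderate 2, strong 4,
    very strong 8; benign negative); total points are exponents of
    ``odds_very_strong`` on the 1/8 scale, combined with ``prior`` to a
    posterior. Tier cutoffs are strict lower bounds on the posterior.
    """

    prior: float = 0.1
    odds_very_strong: float = 350.0
    tier1_cutoff: float = 0.9
    tier2_cutoff: float = 0.499
    tier3_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie in (0, 1)")
        if self.odds_very_strong <= 0:
            raise ValueError("odds_very_strong must be positive")
        if not (self.tier1_cutoff > self.tier2_cutoff > self.tier3_cutoff):
            raise ValueError("tier cutoffs must be strictly decreasing")


@dataclass
class ClassifiedVariant:
    """A call after step 2: criteria, categorical class, posterior, tier."""

    call: VariantCall
    criteria: CriteriaSet
    classification: str
    posterior: float
    tier: Optional[int]
    pm3_assumed_trans: bool = False

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")

    @property
    def is_candidate(self) -> bool:
        """Only pathogenic / likely pathogenic / VUS calls go forward."""
        return self.classification in ("pathogenic", "likely_pathogenic", "vus")


# ---------------------------------------------------------------------------
# prioritization result types
# ---------------------------------------------------------------------------


@dataclass
class SimilarityScore:
    value: float

    def __post_init__(self) -> None:
        _check_unit("similarity", self.value)


@dataclass
class CandidateVariant:
    """A (variant, disease) pairing scored for one case."""

    classified: ClassifiedVariant
    disease: DiseaseProfile
    similarity: float
    inheritance_consistent: bool
    carrier_flag: bool = False
    rank: Optional[int] = None


@dataclass
class PrioritizationResult:
    """Per-case output: audit-ordered candidates plus the final selection."""

    case_id: str
    ranked_candidates: list[CandidateVariant]
    selected: list[tuple[str, int, str, str]]
    status: str
    provenance: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)
    classifications: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("found", "not_found"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "not_found") != (len(self.selected) == 0):
            raise ValueError("status not_found iff selected is empty")
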