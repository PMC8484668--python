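"""Concordance comparison of two per-case prioritization result sets.

Compares, case by case, the variant sets selected by two analysts (typically
manual curation vs the automated pipeline). A case is concordant when both
selected exactly the same variants, or both found none; any partial overlap
is discordant. The overall concordant call rate counts cases; the
per-classification rates count variants within each ACMG class.

Variant identity is the normalized (chrom, pos, ref, alt) key — HGVS strings
are display-only, so nomenclature dialects cannot split a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .models import parse_key

VERDICTS = ("concordant_found", "concordant_not_found", "discordant")


@dataclass(frozen=True)
class CaseComparison:
    """Verdict for one case given both analysts' selected variant sets."""

    case_id: str
    list_a: frozenset
    list_b: frozenset
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def compare_case(result_a: dict, result_b: dict) -> CaseComparison:
    """Compare two result dicts (as written by ``write_result``) for one case.

    Both empty -> concordant_not_found; identical non-empty sets ->
    concordant_found; anything else (including partial overlap) -> discordant.
    """
    if result_a["case_id"] != result_b["case_id"]:
        raise ValueError(
            f"case_id mismatch: {result_a['case_id']!r} vs {result_b['case_id']!r}"
        )
    set_a = frozenset(parse_key(k) for k in result_a["selected"])
    set_b = frozenset(parse_key(k) for k in result_b["selected"])
    if not set_a and not set_b:
        verdict = "concordant_not_found"
    elif set_a == set_b:
        verdict = "concordant_found"
    else:
        verdict = "discordant"
    return CaseComparison(
        case_id=result_a["case_id"], list_a=set_a, list_b=set_b, verdict=verdict
    )


def _round2(value: float) -> float:
    return float(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceReport:
    """Per-case verdicts plus case-level and variant-level summary rates."""

    comparisons: list[CaseComparison]
    counts: dict[str, int] = field(default_factory=dict)
    per_class: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {v: 0 for v in VERDICTS}
            for comparison in self.comparisons:
                self.counts[comparison.verdict] += 1

    @property
    def n_cases(self) -> int:
        return len(self.comparisons)

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "counts": self.counts,
            "concordant_call_rate": concordance_rate(self),
            "per_class": self.per_class,
            "verdicts": {c.case_id: c.verdict for c in self.comparisons},
        }


def concordance_rate(report: ConcordanceReport) -> float:
    """Percent of cases concordant (found or not-found), 2-decimal half-up."""
    total = report.n_cases
    if total == 0:
        raise ValueError("concordance rate undefined for zero cases")
    concordant = (
        report.counts["concordant_found"] + report.counts["concordant_not_found"]
    )
    return _round2(100.0 * concordant / total)


def per_class_concordance(
    results_a: list[dict], results_b: list[dict]
) -> dict[str, dict]:
    """Variant-level concordance per ACMG class.

    For each class, the denominator is the union of variants either analyst
    selected with that class; the numerator is those selected by both with
    that class.
    """
    union: dict[str, set] = {}
    matched: dict[str, set] = {}
    by_case_b = {r["case_id"]: r for r in results_b}
    for result_a in results_a:
        result_b = by_case_b.get(result_a["case_id"], {"classifications": {}})
        cls_a = result_a.get("classifications", {})
        cls_b = result_b.get("classifications", {})
        for variant, cls in cls_a.items():
            union.setdefault(cls, set()).add((result_a["case_id"], variant))
            if cls_b.get(variant) == cls:
                matched.setdefault(cls, set()).add((result_a["case_id"], variant))
        for variant, cls in cls_b.items():
            union.setdefault(cls, set()).add((result_a["case_id"], variant))
    out = {}
    for cls, members in sorted(union.items()):
        n_matched = len(matched.get(cls, set()))
        out[cls] = {
            "union": len(members),
            "matched": n_matched,
            "rate": _round2(100.0 * n_matched / len(members)) if members else 0.0,
        }
    return out


def build_report(results_a: list[dict], results_b: list[dict]) -> ConcordanceReport:
    """Pair up result lists by case_id and build the full report."""
    by_case_b = {r["case_id"]: r for r in results_b}
    missing = [r["case_id"] for r in results_a if r["case_id"] not in by_case_b]
    if missing:
        raise ValueError(f"cases missing from second result set: {missing}")
    comparisons = [compare_case(r, by_case_b[r["case_id"]]) for r in results_a]
    report = ConcordanceReport(comparisons=comparisons)
    report.per_class = per_class_concordance(results_a, results_b)
    return report
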