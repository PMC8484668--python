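"""Step 1 — allele-frequency filtration.

Two profiles are supported. The *general* profile drops variants whose minor
allele frequency exceeds the BA1 bound (default 5%) in any non-founder
subpopulation, keeping curated exceptions (known pathogenic variants that are
common, e.g. certain GJB2 alleles). The *hearing_loss* profile additionally
applies the stricter disease-specific total-MAF bounds used in manual curation
(AR: drop when > 0.005; AD: drop when >= 0.001).

Absent frequencies are treated as 0 (rare): a variant never seen in any
population database must survive filtration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import (
    KnownVariantRecord,
    VariantAnnotation,
    VariantCall,
    format_key,
)


@dataclass
class FilterConfig:
    """Thresholds and profile for step-1 filtration.

    ``common_background_threshold`` is the MAF bound (10%) used by the
    synthetic benchmark's background pool, kept here so one object carries
    every frequency convention.
    """

    ba1_threshold: float = 0.05
    common_background_threshold: float = 0.10
    founder_subpopulations: frozenset[str] = frozenset({"Finnish", "Jewish"})
    hl_ar_threshold: float = 0.005
    hl_ad_threshold: float = 0.001
    profile: str = "general"

    def __post_init__(self) -> None:
        for name in (
            "ba1_threshold",
            "common_background_threshold",
            "hl_ar_threshold",
            "hl_ad_threshold",
        ):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.hl_ad_threshold > self.hl_ar_threshold:
            raise ValueError("hl_ad_threshold must not exceed hl_ar_threshold")
        if self.profile not in ("general", "hearing_loss"):
            raise ValueError(f"unknown filter profile {self.profile!r}")
        self.founder_subpopulations = frozenset(self.founder_subpopulations)


def passes_ba1(
    annotation: Optional[VariantAnnotation],
    known_variants: dict[tuple, KnownVariantRecord],
    config: FilterConfig,
    key: Optional[tuple] = None,
) -> bool:
    """True unless the variant is BA1-common and not a curated exception.

    A variant fails iff its AF exceeds ``ba1_threshold`` in any subpopulation
    outside the founder set and the known-variant table does not mark it
    ``filter_exempt``.
    """
    if annotation is None:
        return True
    record = known_variants.get(key) if key is not None else None
    if record is not None and record.filter_exempt:
        return True
    for pop, af in annotation.subpop_afs.items():
        if pop in config.founder_subpopulations:
            continue
        if af > config.ba1_threshold:
            return False
    return True


def passes_disease_specific(
    annotation: Optional[VariantAnnotation],
    inheritance: str,
    config: FilterConfig,
) -> bool:
    """Disease-specific total-MAF bound: AR strict '> 0.005', AD '>= 0.001'.

    XL and MT use the AD bound (the stricter of the two published bounds).
    """
    if annotation is None or annotation.total_af is None:
        return True
    if inheritance == "AR":
        return not (annotation.total_af > config.hl_ar_threshold)
    return not (annotation.total_af >= config.hl_ad_threshold)


def filter_case(
    calls: list[VariantCall],
    annotations: dict[tuple, VariantAnnotation],
    known_variants: dict[tuple, KnownVariantRecord],
    config: FilterConfig,
    inheritance_by_key: Optional[dict[tuple, str]] = None,
) -> tuple[list[VariantCall], dict[str, str]]:
    """Apply the configured profile to a case; keep input order.

    Returns the retained calls and a drop log mapping formatted variant keys
    to the reason each was removed. The hearing_loss profile needs the
    candidate inheritance per variant (``inheritance_by_key``); variants
    without a known mode default to AD (the stricter bound).
    """
    retained: list[VariantCall] = []
    log: dict[str, str] = {}
    for call in calls:
        key = call.key
        ann = annotations.get(key)
        if not passes_ba1(ann, known_variants, config, key=key):
            log[format_key(key)] = (
                f"BA1: subpopulation AF above {config.ba1_threshold:g} "
                "in a non-founder population"
            )
            continue
        if config.profile == "hearing_loss":
            mode = (inheritance_by_key or {}).get(key, "AD")
            if not passes_disease_specific(ann, mode, config):
                log[format_key(key)] = (
                    f"disease-specific MAF bound for {mode} exceeded"
                )
                continue
        retained.append(call)
    return retained, log
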