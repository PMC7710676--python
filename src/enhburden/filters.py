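"""Variant prioritisation filters for enhancer and coding burden testing.

Enhancer route: keep a variant iff its population allele frequency is
strictly below ``maf_max`` (absent frequency counts as 0 — a variant never
seen in the reference panel is exactly the ultra-rare substrate of
interest) AND its conservation score strictly exceeds ``cons_min`` (an
absent score fails: the filter demands positive evidence of constraint).

Coding route: keep iff rare as above AND the annotated effect class is in
the keep-set {HIGH, MODERATE, LOW}; 'synonymous' and
'TF_binding_site_variant' are always excluded, as are unannotated/'other'
variants.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigError
from .io_formats import EnhancerGeneMap, VariantRecord

__all__ = [
    "FilterSpec",
    "filter_enhancer_variants",
    "filter_coding_variants",
    "assign_to_sets",
]


@dataclass(frozen=True)
class FilterSpec:
    maf_max: float = 0.01
    cons_min: float = 0.8
    coding_classes_keep: frozenset[str] = frozenset({"HIGH", "MODERATE", "LOW"})
    coding_classes_drop: frozenset[str] = frozenset(
        {"synonymous", "TF_binding_site_variant"}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_max < 0.5:
            raise ConfigError(f"maf_max must be in (0, 0.5), got {self.maf_max}")
        if not 0.0 <= self.cons_min <= 1.0:
            raise ConfigError(f"cons_min must be in [0, 1], got {self.cons_min}")
        if self.coding_classes_keep & self.coding_classes_drop:
            raise ConfigError("coding keep/drop classes overlap")


def _is_rare(v: VariantRecord, spec: FilterSpec) -> bool:
    af = 0.0 if v.pop_af is None else v.pop_af
    return af < spec.maf_max


def filter_enhancer_variants(
    variants: Sequence[VariantRecord], spec: FilterSpec = FilterSpec()
) -> tuple[list[int], dict[str, int]]:
    """Indices of retained enhancer variants plus per-rule drop counts."""
    retained: list[int] = []
    drops = {"common": 0, "low_conservation": 0}
    for j, v in enumerate(variants):
        if not _is_rare(v, spec):
            drops["common"] += 1
        elif v.cons_score is None or not v.cons_score > spec.cons_min:
            drops["low_conservation"] += 1
        else:
            retained.append(j)
    return retained, drops


def filter_coding_variants(
    variants: Sequence[VariantRecord], spec: FilterSpec = FilterSpec()
) -> tuple[list[int], dict[str, int]]:
    """Indices of retained coding variants plus per-rule drop counts."""
    retained: list[int] = []
    drops = {"common": 0, "effect_class": 0}
    for j, v in enumerate(variants):
        if not _is_rare(v, spec):
            drops["common"] += 1
        elif v.effect_class not in spec.coding_classes_keep:
            drops["effect_class"] += 1
        else:
            retained.append(j)
    return retained, drops


def assign_to_sets(
    variants: Sequence[VariantRecord], maps: Sequence[EnhancerGeneMap]
) -> dict[str, list[int]]:
    """Map set_id -> indices of member variants.

    Membership: the variant's 0-based position lies inside any merged
    interval of the set. A variant may belong to several sets (enhancer
    intervals of different genes overlap).
    """
    out: dict[str, list[int]] = {m.set_id: [] for m in maps}
    for j, v in enumerate(variants):
        pos0 = v.pos0
        for m in maps:
            if m.contains(v.chrom, pos0):
                out[m.set_id].append(j)
    return out
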