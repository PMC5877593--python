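"""Variant selection cascade: depth/allele-ratio, functional effect, rarity.

The cascade reduces raw caller output to high-confidence, functionally
relevant, novel-or-rare candidates.  All comparators are strict, matching
the published thresholds: total depth > 10, alternate-allele ratio > 0.2,
and population frequency < 0.01 in every database that has observed the
variant.  Each filter is idempotent and the three commute, so the cascade
is a pure conjunction of per-record predicates applied in a fixed order
for reporting purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from gistflow.variants import AnnotatedVariant, IN_SCOPE_EFFECTS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the selection cascade (defaults as published)."""

    min_total_depth: int = 10
    min_ratio: float = 0.2
    max_freq: float = 0.01


def depth_vaf_filter(
    variants: Sequence[AnnotatedVariant],
    min_total_depth: int = 10,
    min_ratio: float = 0.2,
) -> list[AnnotatedVariant]:
    """Keep variants with total_depth > min_total_depth and ratio > min_ratio.

    Both comparisons are strict; boundary values are removed.  A record with
    total_depth == 0 has an undefined allele ratio and is removed.  Input
    order is preserved.
    """
    return [
        v
        for v in variants
        if v.total_depth > min_total_depth and v.ratio > min_ratio
    ]


def functional_filter(
    variants: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], int]:
    """Keep coding non-silent variants and splice-site (+/-3 bp) variants.

    Returns the kept records and the number of records rejected because
    their ``effect_class`` annotation was missing (those are warned about
    and counted separately rather than silently dropped into the
    out-of-scope bin).
    """
    kept: list[AnnotatedVariant] = []
    n_missing = 0
    for v in variants:
        if not v.effect_class:
            n_missing += 1
            logger.warning(
                "variant %s:%d %s>%s in %s has no effect_class annotation; rejected",
                v.chrom, v.pos, v.ref, v.alt, v.sample_id,
            )
            continue
        if v.effect_class in IN_SCOPE_EFFECTS:
            kept.append(v)
    return kept, n_missing


def rarity_filter(
    variants: Sequence[AnnotatedVariant], max_freq: float = 0.01
) -> list[AnnotatedVariant]:
    """Keep novel variants and variants rare in *every* population database.

    A variant with no frequency entry in any database is novel and kept.
    A variant is removed as a polymorphism as soon as one database reports
    a frequency >= ``max_freq`` (strict ``<`` keeps it).  Frequencies
    outside [0, 1] indicate a corrupt annotation and raise ``ValueError``.
    """
    kept: list[AnnotatedVariant] = []
    for v in variants:
        for db, freq in v.pop_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"population frequency {freq!r} from {db} outside [0, 1] "
                    f"at {v.chrom}:{v.pos} {v.ref}>{v.alt}"
                )
        if all(freq < max_freq for freq in v.pop_freqs.values()):
            kept.append(v)
    return kept


def run_cascade(
    variants: Iterable[AnnotatedVariant],
    params: FilterParams = FilterParams(),
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply depth/ratio -> functional -> rarity and report per-stage counts.

    Returns the surviving variants and a stage-count dictionary whose values
    are monotone non-increasing along the cascade (``missing_effect`` counts
    records rejected for an absent annotation at the functional stage).
    """
    variants = list(variants)
    counts: dict[str, int] = {"input": len(variants)}
    survivors = depth_vaf_filter(variants, params.min_total_depth, params.min_ratio)
    counts["depth_vaf"] = len(survivors)
    survivors, n_missing = functional_filter(survivors)
    counts["functional"] = len(survivors)
    counts["missing_effect"] = n_missing
    survivors = rarity_filter(survivors, params.max_freq)
    counts["rarity"] = len(survivors)
    return survivors, counts
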