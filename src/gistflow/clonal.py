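"""Clonal partitioning of somatic mutations across lesions of one patient.

Multi-region sequencing of geographically distinct metastases lets somatic
mutations be placed on the clonal tree by presence/absence alone: a variant
found in every lesion is truncal (acquired before dissemination), a variant
in exactly one lesion is private, and anything in between is partially
shared.  Variant identity across lesions is exact (chrom, pos, ref, alt) —
all lesions are called against the same reference.  Only variants
classified somatic should enter the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence, Set

import pandas as pd

VariantKey = Hashable  # canonically (chrom, pos, ref, alt)


@dataclass
class ClonalPartition:
    """Disjoint, exhaustive split of a patient's somatic variants.

    ``truncal`` holds variants present in all lesions; ``partial`` maps a
    variant to the (>1, <all) lesions carrying it; ``private`` maps a
    variant to its single lesion.
    """

    patient_id: str
    lesions: tuple[str, ...]
    truncal: set = field(default_factory=set)
    partial: dict = field(default_factory=dict)
    private: dict = field(default_factory=dict)

    @property
    def all_variants(self) -> set:
        return set(self.truncal) | set(self.partial) | set(self.private)


def partition_mutations(
    lesion_variant_sets: Mapping[str, Set[VariantKey]],
    patient_id: str = "",
) -> ClonalPartition:
    """Partition variants by the number of lesions carrying them.

    Requires >= 2 lesions (the partition is undefined for a single sample).
    Deterministic: lesion order follows the sorted sample ids.
    """
    if len(lesion_variant_sets) < 2:
        raise ValueError(
            f"clonal partition needs >= 2 lesions, got {len(lesion_variant_sets)}"
        )
    lesions = tuple(sorted(lesion_variant_sets))
    n = len(lesions)
    part = ClonalPartition(patient_id=patient_id, lesions=lesions)
    union = set().union(*(lesion_variant_sets[s] for s in lesions))
    for v in union:
        carriers = tuple(s for s in lesions if v in lesion_variant_sets[s])
        if len(carriers) == n:
            part.truncal.add(v)
        elif len(carriers) == 1:
            part.private[v] = carriers[0]
        else:
            part.partial[v] = carriers
    return part


def clonal_matrix(
    partition: ClonalPartition,
    gene_annotation: Mapping[VariantKey, str],
) -> pd.DataFrame:
    """Lesion x gene presence matrix (the filled-square plot as a table).

    A cell is True when the lesion carries >= 1 somatic variant in the gene.
    Columns are ordered truncal genes first, then by decreasing number of
    carrying lesions, ties alphabetical.  Variants without a gene symbol
    fall into an ``"(intergenic)"`` bucket.
    """
    carriers: dict[VariantKey, tuple[str, ...]] = {}
    for v in partition.truncal:
        carriers[v] = partition.lesions
    for v, subset in partition.partial.items():
        carriers[v] = tuple(subset)
    for v, lesion in partition.private.items():
        carriers[v] = (lesion,)

    gene_lesions: dict[str, set[str]] = {}
    gene_truncal: dict[str, bool] = {}
    for v, lesions in carriers.items():
        gene = gene_annotation.get(v) or "(intergenic)"
        gene_lesions.setdefault(gene, set()).update(lesions)
        gene_truncal[gene] = gene_truncal.get(gene, False) or (v in partition.truncal)

    order = sorted(
        gene_lesions,
        key=lambda g: (not gene_truncal[g], -len(gene_lesions[g]), g),
    )
    data = {
        g: [lesion in gene_lesions[g] for lesion in partition.lesions] for g in order
    }
    return pd.DataFrame(data, index=list(partition.lesions), columns=order)


def partition_report(partition: ClonalPartition) -> dict:
    """JSON-serialisable summary of a clonal partition."""
    return {
        "patient_id": partition.patient_id,
        "lesions": list(partition.lesions),
        "n_truncal": len(partition.truncal),
        "n_partial": len(partition.partial),
        "n_private": len(partition.private),
        "truncal": sorted(map(_key_str, partition.truncal)),
        "partial": {
            _key_str(v): list(les) for v, les in sorted(
                partition.partial.items(), key=lambda kv: _key_str(kv[0])
            )
        },
        "private": {
            _key_str(v): les for v, les in sorted(
                partition.private.items(), key=lambda kv: _key_str(kv[0])
            )
        },
    }


def _key_str(key: VariantKey) -> str:
    if isinstance(key, tuple):
        return ":".join(str(x) for x in key)
    return str(key)
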