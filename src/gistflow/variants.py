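"""The annotated-variant record consumed by every downstream stage.

One :class:`AnnotatedVariant` is a single (sample, locus, alt allele) call
as emitted by an SNV/InDel caller and annotated with a gene symbol, a
functional effect class and per-database population frequencies.
Multi-allelic VCF records are split into one record per alternate allele
before anything downstream sees them, because depth and allele-ratio rules
apply per alternate event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

#: Functional effect classes the pipeline distinguishes.  ``coding_nonsilent``
#: covers non-synonymous and nonsense SNVs plus frameshift and non-frameshift
#: InDels; ``splice_site_pm3`` covers variants within +/-3 bp of a splice
#: junction.  Silent and non-coding calls are removed by the functional filter.
EFFECT_CLASSES = ("coding_nonsilent", "splice_site_pm3", "silent", "noncoding")

#: Effect classes that count as functionally relevant (kept by the cascade
#: and counted in the mutational-burden numerator).
IN_SCOPE_EFFECTS = frozenset({"coding_nonsilent", "splice_site_pm3"})


@dataclass
class AnnotatedVariant:
    """One called variant in one tumor sample.

    Parameters
    ----------
    sample_id
        Tumor sample identifier.
    chrom, pos
        Chromosome name and 1-based position.
    ref, alt
        Reference and alternate allele strings (one alt per record).
    total_depth
        Total read depth at the locus in the tumor.
    alt_depth
        Reads supporting this alternate allele in the tumor.
    gene
        Gene symbol, or ``""`` for intergenic calls.
    effect_class
        One of :data:`EFFECT_CLASSES`, or ``""`` when the annotation is
        missing.
    pop_freqs
        Population frequency per database (e.g. dbSNP, 1000Genomes, EVS,
        ExAC).  A database in which the variant is unobserved is simply
        absent from the map; an empty map means the variant is novel.
    caller
        Identifier of the variant caller that produced the record.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    gene: str = ""
    effect_class: str = ""
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    caller: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} at {self.chrom}")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth must satisfy 0 <= alt_depth <= total_depth; got "
                f"alt_depth={self.alt_depth}, total_depth={self.total_depth} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def ratio(self) -> float:
        """Alternate-allele fraction: alt_depth / total_depth (0 when depth is 0)."""
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus/allele identity used to match variants across samples."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1
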