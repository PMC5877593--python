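"""Somatic/germline/undetermined classification from matched-normal pileups.

A filtered tumor variant is *somatic* when the matched normal is well
covered and essentially free of the alternate allele:

    normal total depth > 5 AND
      alt reads in normal == 0, or
      alt reads == 1 with total depth >= 15, or
      alt reads == 2 with total depth >= 30.

It is *undetermined* when the normal is too shallow to be informative
(total depth < 5; depth exactly 5 is treated as undetermined too, the
conservative reading of a rule stated with strict comparators on both
sides), and *germline* otherwise.  Only reads supporting the exact
alternate allele count against somatic status; other non-reference alleles
in the normal do not.

The module also derives the cohort summaries built on top of the somatic
set: per-gene recurrence across samples and patients, the fraction of
mutated genes that are actually expressed, and matching against a
user-supplied actionable-gene list.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gistflow.variants import AnnotatedVariant


class SomaticStatus(str, enum.Enum):
    """Tumor-vs-normal status of a variant; the three values partition the input."""

    SOMATIC = "somatic"
    GERMLINE = "germline"
    UNDETERMINED = "undetermined"


@dataclass
class NormalObservation:
    """Allele counts at one locus in the matched normal.

    ``allele_counts`` maps allele strings to supporting read counts; SNV
    alleles are single bases, and reads supporting any insertion/deletion
    at the locus may be pooled under the key ``"indel"``.  ``total_depth``
    must equal the sum of the counts.
    """

    chrom: str
    pos: int
    ref: str
    allele_counts: Mapping[str, int]
    total_depth: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError(f"negative allele count at {self.chrom}:{self.pos}")
        if self.total_depth != sum(self.allele_counts.values()):
            raise ValueError(
                f"total_depth {self.total_depth} != sum of allele counts "
                f"{sum(self.allele_counts.values())} at {self.chrom}:{self.pos}"
            )

    def alt_count(self, ref: str, alt: str) -> int:
        """Reads supporting the given alternate allele (indels pool under 'indel')."""
        if len(ref) != 1 or len(alt) != 1:
            return int(self.allele_counts.get("indel", 0))
        return int(self.allele_counts.get(alt, 0))


def classify_variant(v: AnnotatedVariant, n: NormalObservation) -> SomaticStatus:
    """Classify one tumor variant against its matched-normal observation.

    Raises ``ValueError`` when the normal observation refers to a different
    locus than the variant.
    """
    if (v.chrom, v.pos) != (n.chrom, n.pos):
        raise ValueError(
            f"locus mismatch: variant at {v.chrom}:{v.pos}, "
            f"normal observation at {n.chrom}:{n.pos}"
        )
    total = n.total_depth
    if total <= 5:
        # < 5 is explicitly uninformative; exactly 5 falls between the two
        # published strict comparators and is resolved conservatively.
        return SomaticStatus.UNDETERMINED
    alt = n.alt_count(v.ref, v.alt)
    if alt == 0 or (alt == 1 and total >= 15) or (alt == 2 and total >= 30):
        return SomaticStatus.SOMATIC
    return SomaticStatus.GERMLINE


PileupIndex = Mapping[str, Mapping[tuple[str, int], NormalObservation]]


def classify_cohort(
    variants: Sequence[AnnotatedVariant],
    pileups: PileupIndex,
    sample_map: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every variant of a cohort against its patient's normal pileup.

    Parameters
    ----------
    variants
        Filtered tumor variants from any number of samples.
    pileups
        Per-patient pileup index: patient id -> (chrom, pos) -> observation.
        One normal is sequenced per patient, so all lesions of a patient are
        classified against the same pileup.
    sample_map
        sample id -> patient id.

    Returns
    -------
    A DataFrame with one row per variant (sample_id, chrom, pos, ref, alt,
    gene, effect_class, total_depth, alt_depth, normal_depth, normal_alt,
    status) and a summary dict reporting the fraction of variants whose
    locus was missing from the pileup (those are classified undetermined).
    """
    rows = []
    n_missing = 0
    for v in variants:
        if v.sample_id not in sample_map:
            raise KeyError(f"sample {v.sample_id!r} missing from sample map")
        patient = sample_map[v.sample_id]
        obs = pileups.get(patient, {}).get((v.chrom, v.pos))
        if obs is None:
            n_missing += 1
            status = SomaticStatus.UNDETERMINED
            normal_depth, normal_alt = pd.NA, pd.NA
        else:
            status = classify_variant(v, obs)
            normal_depth = obs.total_depth
            normal_alt = obs.alt_count(v.ref, v.alt)
        rows.append(
            {
                "sample_id": v.sample_id,
                "patient_id": patient,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "effect_class": v.effect_class,
                "total_depth": v.total_depth,
                "alt_depth": v.alt_depth,
                "normal_depth": normal_depth,
                "normal_alt": normal_alt,
                "status": status.value,
            }
        )
    columns = [
        "sample_id", "patient_id", "chrom", "pos", "ref", "alt", "gene",
        "effect_class", "total_depth", "alt_depth", "normal_depth",
        "normal_alt", "status",
    ]
    df = pd.DataFrame(rows, columns=columns)
    summary = {
        "n_variants": float(len(df)),
        "missing_pileup_fraction": (n_missing / len(df)) if len(df) else 0.0,
    }
    return df, summary


@dataclass
class RecurrenceReport:
    """Per-gene recurrence across samples and patients."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "n_samples", "n_patients", "samples", "same_patient_only"]
        )
    )

    def recurrent(self, level: str = "patient") -> pd.DataFrame:
        """Genes mutated in >= 2 samples or >= 2 patients.

        Headline recurrence is at the patient level: a gene hit only in
        multiple lesions of one individual is recurrence within a tumor,
        not across the cohort.
        """
        col = "n_patients" if level == "patient" else "n_samples"
        return self.table[self.table[col] >= 2].reset_index(drop=True)


def recurrent_genes(
    somatic_variants: pd.DataFrame | Sequence[AnnotatedVariant],
    sample_to_patient: Mapping[str, str],
) -> RecurrenceReport:
    """Count, per gene, the distinct mutated samples and patients.

    ``same_patient_only`` flags genes whose apparent recurrence is confined
    to multiple lesions of a single individual.
    """
    df = _as_frame(somatic_variants)
    if df.empty:
        return RecurrenceReport()
    missing = set(df["sample_id"]) - set(sample_to_patient)
    if missing:
        raise KeyError(f"samples missing from sample map: {sorted(missing)}")
    df = df[df["gene"] != ""].copy()
    df["patient_id"] = df["sample_id"].map(sample_to_patient)
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        samples = sorted(grp["sample_id"].unique())
        patients = grp["patient_id"].unique()
        rows.append(
            {
                "gene": gene,
                "n_samples": len(samples),
                "n_patients": len(patients),
                "samples": ",".join(samples),
                "same_patient_only": len(samples) >= 2 and len(patients) == 1,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["n_patients", "n_samples", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return RecurrenceReport(table)


def expressed_fraction(
    somatic_variants: pd.DataFrame | Sequence[AnnotatedVariant],
    expression_table: pd.DataFrame,
    min_expr: float = 1.0,
) -> float:
    """Fraction of mutated (sample, gene) pairs expressed in that sample.

    ``expression_table`` is gene x sample (index = gene symbols).  A gene
    absent from the table counts as not expressed.  Returns 0.0 when there
    are no mutated genes.
    """
    df = _as_frame(somatic_variants)
    df = df[df["gene"] != ""]
    pairs = df[["sample_id", "gene"]].drop_duplicates()
    if pairs.empty:
        return 0.0
    n_expressed = 0
    for sample, gene in pairs.itertuples(index=False):
        try:
            value = float(expression_table.at[gene, sample])
        except (KeyError, ValueError):
            continue
        if value >= min_expr:
            n_expressed += 1
    return n_expressed / len(pairs)


def match_actionable(
    somatic_variants: pd.DataFrame | Sequence[AnnotatedVariant],
    actionable_genes: pd.DataFrame | Mapping[str, str] | Iterable[str],
) -> pd.DataFrame:
    """Variants whose gene is on an actionable-gene list.

    The list may be a DataFrame with columns ``gene`` and optionally
    ``annotation`` (e.g. therapy class), a mapping gene -> annotation, or a
    plain iterable of symbols.  Matching is case-insensitive and
    whitespace-stripped.
    """
    if isinstance(actionable_genes, pd.DataFrame):
        annot = {
            str(row.gene).strip().upper(): str(getattr(row, "annotation", ""))
            for row in actionable_genes.itertuples(index=False)
        }
    elif isinstance(actionable_genes, Mapping):
        annot = {str(g).strip().upper(): str(a) for g, a in actionable_genes.items()}
    else:
        annot = {str(g).strip().upper(): "" for g in actionable_genes}
    df = _as_frame(somatic_variants)
    if df.empty or not annot:
        return df.head(0).assign(actionable_annotation=pd.Series(dtype=str))
    norm = df["gene"].astype(str).str.strip().str.upper()
    matched = df[norm.isin(annot)].copy()
    matched["actionable_annotation"] = norm[norm.isin(annot)].map(annot)
    return matched.reset_index(drop=True)


def _as_frame(variants: pd.DataFrame | Sequence[AnnotatedVariant]) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    return pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "effect_class": v.effect_class,
            }
            for v in variants
        ],
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "effect_class"],
    )
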