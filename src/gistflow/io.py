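"""Readers and writers for the pipeline's file formats.

Variants travel as VCF v4.2 (via pysam) with annotations in INFO fields;
everything else is plain TSV/BED.  Conventions:

* VCF positions are 1-based (format-native).
* BED files (gene model, capture target, polymorphic regions) are 0-based
  half-open.
* CNV segment tables are 1-based inclusive as written by read-depth callers
  and are converted to 0-based half-open on read.
* Normal pileups are per-patient TSVs with per-base counts and a pooled
  indel count.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from gistflow.cnv import CnvSegment
from gistflow.fusion import FusionCall
from gistflow.somatic import NormalObservation
from gistflow.variants import AnnotatedVariant

#: Population-frequency databases carried in VCF INFO (order fixed for
#: deterministic output).
DATABASES = ("dbSNP", "1000Genomes", "EVS", "ExAC")
_DB_TO_INFO = {
    "dbSNP": "PF_DBSNP",
    "1000Genomes": "PF_1KG",
    "EVS": "PF_EVS",
    "ExAC": "PF_EXAC",
}
_INFO_TO_DB = {v: k for k, v in _DB_TO_INFO.items()}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add(
        "EFFECT", 1, "String",
        "Effect class: coding_nonsilent, splice_site_pm3, silent or noncoding",
    )
    header.info.add("TDP", 1, "Integer", "Total depth at locus in tumor")
    header.info.add("ADP", "A", "Integer", "Alt-supporting depth in tumor")
    header.info.add("CALLER", 1, "String", "Variant caller identifier")
    for db in DATABASES:
        header.info.add(
            _DB_TO_INFO[db], "A", "Float", f"Population frequency in {db}"
        )
    return header


def write_vcf(
    path: str | os.PathLike,
    variants: Sequence[AnnotatedVariant],
    contigs: Mapping[str, int],
) -> None:
    """Write one sample's variants as an uncompressed, sorted VCF v4.2."""
    header = _vcf_header(contigs)
    order = {name: i for i, name in enumerate(contigs)}
    variants = sorted(variants, key=lambda v: (order.get(v.chrom, 99), v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["EFFECT"] = v.effect_class or "."
            rec.info["TDP"] = v.total_depth
            rec.info["ADP"] = (v.alt_depth,)
            if v.caller:
                rec.info["CALLER"] = v.caller
            for db, freq in v.pop_freqs.items():
                rec.info[_DB_TO_INFO[db]] = (freq,)
            vcf.write(rec)


def read_vcf(path: str | os.PathLike, sample_id: str) -> list[AnnotatedVariant]:
    """Read a VCF into per-alt AnnotatedVariant records.

    Multi-allelic records are split: each alternate allele becomes its own
    record, taking the A-numbered ADP and frequency entries for its index.
    """
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = rec.info.get("GENE", ".")
            effect = rec.info.get("EFFECT", ".")
            tdp = int(rec.info.get("TDP", 0))
            adp = rec.info.get("ADP", (0,) * len(rec.alts or ()))
            caller = rec.info.get("CALLER", "")
            for i, alt in enumerate(rec.alts or ()):
                freqs = {}
                for db in DATABASES:
                    vals = rec.info.get(_DB_TO_INFO[db])
                    if vals is not None and vals[i] is not None:
                        freqs[db] = float(vals[i])
                out.append(
                    AnnotatedVariant(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        total_depth=tdp,
                        alt_depth=int(adp[i]),
                        gene="" if gene == "." else str(gene),
                        effect_class="" if effect == "." else str(effect),
                        pop_freqs=freqs,
                        caller=str(caller),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "indel", "total"]


def write_pileup(path: str | os.PathLike, observations: Sequence[NormalObservation]) -> None:
    rows = []
    for o in sorted(observations, key=lambda o: (o.chrom, o.pos)):
        rows.append(
            {
                "chrom": o.chrom,
                "pos": o.pos,
                "ref": o.ref,
                **{b: int(o.allele_counts.get(b, 0)) for b in "ACGT"},
                "indel": int(o.allele_counts.get("indel", 0)),
                "total": o.total_depth,
            }
        )
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup(path: str | os.PathLike) -> dict[tuple[str, int], NormalObservation]:
    """Read a pileup TSV into a locus-indexed map; duplicate loci are an error."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    index: dict[tuple[str, int], NormalObservation] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key in index:
            raise ValueError(f"duplicate pileup rows for locus {key[0]}:{key[1]} in {path}")
        counts = {b: int(getattr(row, b)) for b in "ACGT"}
        counts["indel"] = int(row.indel)
        index[key] = NormalObservation(
            chrom=key[0], pos=key[1], ref=str(row.ref),
            allele_counts=counts, total_depth=int(row.total),
        )
    return index


# ---------------------------------------------------------------------------
# BED-like tables
# ---------------------------------------------------------------------------

def write_bed(path: str | os.PathLike, df: pd.DataFrame, columns: Sequence[str]) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, columns=list(columns))


def read_gene_model(path: str | os.PathLike) -> pd.DataFrame:
    """BED6 gene model -> DataFrame(chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return df


def read_intervals(path: str | os.PathLike) -> pd.DataFrame:
    """BED3 intervals -> DataFrame(chrom, start, end), 0-based half-open."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end"],
        usecols=[0, 1, 2], dtype={"chrom": str},
    )


# ---------------------------------------------------------------------------
# CNV segment tables
# ---------------------------------------------------------------------------

def write_cnv_segments(path: str | os.PathLike, segments: Sequence[CnvSegment]) -> None:
    """Write segments 1-based inclusive; the uncertainty column only if any segment has one."""
    has_unc = any(s.uncertainty is not None for s in segments)
    rows = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start, s.end)):
        row = {"chrom": s.chrom, "start": s.start + 1, "end": s.end, "state": s.state}
        if has_unc:
            row["uncertainty"] = "" if s.uncertainty is None else f"{s.uncertainty:.2f}"
        rows.append(row)
    cols = ["chrom", "start", "end", "state"] + (["uncertainty"] if has_unc else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_cnv_segments(
    path: str | os.PathLike, sample_id: str, caller: str
) -> list[CnvSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str})
    segs = []
    for i, row in enumerate(df.itertuples(index=False)):
        unc = getattr(row, "uncertainty", None)
        unc = None if unc is None or pd.isna(unc) else float(unc)
        segs.append(
            CnvSegment(
                sample_id=sample_id,
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                state=str(row.state),
                uncertainty=unc,
                caller=caller,
                seg_id=f"{sample_id}:{caller}:{i}",
            )
        )
    return segs


# ---------------------------------------------------------------------------
# Fusion call tables
# ---------------------------------------------------------------------------

FUSION_COLUMNS = [
    "caller", "gene5", "gene3", "chrom5", "pos5", "chrom3", "pos3",
    "strand5", "strand3", "supporting_reads",
]


def write_fusion_calls(path: str | os.PathLike, calls: Sequence[FusionCall]) -> None:
    rows = [
        {k: getattr(c, k) for k in FUSION_COLUMNS}
        for c in sorted(calls, key=lambda c: (c.gene5, c.gene3, c.caller))
    ]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fusion_calls(path: str | os.PathLike, sample_id: str) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in
                     ("caller", "gene5", "gene3", "chrom5", "chrom3", "strand5", "strand3")})
    return [
        FusionCall(
            sample_id=sample_id, caller=row.caller,
            gene5=row.gene5, gene3=row.gene3,
            chrom5=row.chrom5, pos5=int(row.pos5),
            chrom3=row.chrom3, pos3=int(row.pos3),
            strand5=row.strand5, strand3=row.strand3,
            supporting_reads=int(row.supporting_reads),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Misc tables
# ---------------------------------------------------------------------------

def write_sample_map(path: str | os.PathLike, sample_to_patient: Mapping[str, str]) -> None:
    pd.DataFrame(
        sorted(sample_to_patient.items()), columns=["sample_id", "patient_id"]
    ).to_csv(path, sep="\t", index=False)


def read_sample_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["patient_id"]))


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x sample expression table, gene symbols as index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_actionable(path: str | os.PathLike) -> pd.DataFrame:
    """Actionable-gene TSV with columns gene[, annotation]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "annotation" not in df.columns:
        df["annotation"] = ""
    return df[["gene", "annotation"]]


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
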