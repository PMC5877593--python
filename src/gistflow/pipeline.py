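"""End-to-end orchestration: filter -> classify -> burden / CNV / fusion / clonal.

``run_all`` consumes a cohort directory in the layout the simulator writes
(per-sample VCFs, per-patient pileups, two CNV tables and four fusion
tables per sample, gene model / target / polymorphic BEDs, sample map,
optional expression and actionable-gene tables) and produces a consolidated
report: per-stage filter counts, per-variant somatic status, per-sample
burden, gene recurrence, CNV consensus and per-chromosome summary, fusion
consensus with structural categories, and clonal partitions for
multi-lesion patients.  Every threshold is visible in :class:`RunConfig`
and defaults to the published value.  The run is deterministic: the same
inputs and configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from gistflow import io as gio
from gistflow.burden import burden_table, compute_burden, target_size_mb
from gistflow.clonal import clonal_matrix, partition_mutations, partition_report
from gistflow.cnv import (
    chromosome_summary,
    consensus_segments,
    consensus_table,
    filter_polymorphic,
    focal_gene_deletion,
)
from gistflow.filtering import FilterParams, run_cascade
from gistflow.fusion import classify_all, consensus_fusions, fusion_table, recurrent_fusions
from gistflow.simulate import CNV_CALLERS, FUSION_CALLERS
from gistflow.somatic import classify_cohort, expressed_fraction, match_actionable, recurrent_genes
from gistflow.variants import IN_SCOPE_EFFECTS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds in one place (defaults as published)."""

    cohort_dir: str
    out_dir: str
    min_total_depth: int = 10
    min_ratio: float = 0.2
    max_freq: float = 0.01
    cnv_min_overlap: float = 0.80
    cnv_max_uncertainty: float = 80.0
    polymorphic_max_frac: float = 0.5
    fusion_min_callers: int = 2
    max_readthrough_gap: int = 100_000
    max_focal_len: int = 3_000_000
    focal_gene: str = "DMD"
    min_expr: float = 1.0
    seed: int = 0

    @property
    def cohort(self) -> Path:
        return Path(self.cohort_dir)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def validate_config(config: RunConfig) -> list[str]:
    """Range and existence checks; returns violations without mutating config."""
    v: list[str] = []
    if config.min_total_depth < 0:
        v.append(f"min_total_depth must be >= 0, got {config.min_total_depth}")
    if not 0.0 <= config.min_ratio <= 1.0:
        v.append(f"min_ratio must be in [0, 1], got {config.min_ratio}")
    if not 0.0 <= config.max_freq <= 1.0:
        v.append(f"max_freq must be in [0, 1], got {config.max_freq}")
    if not 0.0 < config.cnv_min_overlap <= 1.0:
        v.append(f"cnv_min_overlap must be in (0, 1], got {config.cnv_min_overlap}")
    if not 0.0 <= config.cnv_max_uncertainty <= 100.0:
        v.append(f"cnv_max_uncertainty must be in [0, 100], got {config.cnv_max_uncertainty}")
    if not 0.0 < config.polymorphic_max_frac <= 1.0:
        v.append(f"polymorphic_max_frac must be in (0, 1], got {config.polymorphic_max_frac}")
    if config.fusion_min_callers < 1:
        v.append(f"fusion_min_callers must be >= 1, got {config.fusion_min_callers}")
    if config.max_readthrough_gap < 0:
        v.append(f"max_readthrough_gap must be >= 0, got {config.max_readthrough_gap}")
    if config.max_focal_len <= 0:
        v.append(f"max_focal_len must be > 0, got {config.max_focal_len}")
    cohort = config.cohort
    for rel in (
        "sample_map.tsv",
        "genome/gene_model.bed",
        "genome/target.bed",
        "genome/polymorphic_regions.bed",
    ):
        if not (cohort / rel).exists():
            v.append(f"missing input file: {cohort / rel}")
    for rel in ("variants", "pileups", "cnv", "fusions"):
        if not (cohort / rel).is_dir():
            v.append(f"missing input directory: {cohort / rel}")
    return v


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the consolidated report under out_dir.

    Raises ``ValueError`` listing all violations when the configuration does
    not validate; stage errors propagate with the stage named in the log.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = gio.ensure_dir(config.out)
    cohort = config.cohort

    sample_map = gio.read_sample_map(cohort / "sample_map.tsv")
    samples = sorted(sample_map)
    patients = sorted(set(sample_map.values()))
    gene_model = gio.read_gene_model(cohort / "genome" / "gene_model.bed")
    target = gio.read_intervals(cohort / "genome" / "target.bed")
    polymorphic = gio.read_intervals(cohort / "genome" / "polymorphic_regions.bed")

    report: dict = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "n_samples": len(samples),
        "n_patients": len(patients),
    }

    # ---- filter cascade ------------------------------------------------
    logger.info("stage=filter params=%s", dataclasses.asdict(config))
    params = FilterParams(config.min_total_depth, config.min_ratio, config.max_freq)
    filtered = []
    totals: dict[str, int] = {}
    per_sample_counts: dict[str, dict[str, int]] = {}
    for sample in samples:
        variants = gio.read_vcf(cohort / "variants" / f"{sample}.vcf", sample)
        kept, counts = run_cascade(variants, params)
        filtered.extend(kept)
        per_sample_counts[sample] = counts
        for k, n in counts.items():
            totals[k] = totals.get(k, 0) + n
    report["filter_counts"] = totals
    report["filter_counts_per_sample"] = per_sample_counts
    logger.info("stage=filter counts=%s", totals)

    # ---- somatic classification ----------------------------------------
    pileups = {
        p: gio.read_pileup(cohort / "pileups" / f"{p}.pileup.tsv")
        for p in patients
        if (cohort / "pileups" / f"{p}.pileup.tsv").exists()
    }
    status_df, class_summary = classify_cohort(filtered, pileups, sample_map)
    status_df.to_csv(out / "variant_status.tsv", sep="\t", index=False)
    status_counts = status_df["status"].value_counts().to_dict()
    report["classification"] = {
        "n_classified": int(len(status_df)),
        "missing_pileup_fraction": class_summary["missing_pileup_fraction"],
        "status_counts": {k: int(v) for k, v in sorted(status_counts.items())},
    }
    somatic_df = status_df[
        (status_df["status"] == "somatic")
        & (status_df["effect_class"].isin(IN_SCOPE_EFFECTS))
    ]

    # ---- burden ---------------------------------------------------------
    results = compute_burden(status_df, target, samples=samples)
    bt = burden_table(results)
    bt.to_csv(out / "burden.tsv", sep="\t", index=False)
    report["burden"] = {
        "target_mb": target_size_mb(target),
        "mean_burden_per_mb": float(bt["burden_per_mb"].mean()),
        "per_sample": {r.sample_id: r.burden for r in results},
    }

    # ---- recurrence / expression / actionability ------------------------
    recurrence = recurrent_genes(somatic_df, sample_map)
    recurrence.table.to_csv(out / "recurrence.tsv", sep="\t", index=False)
    headline = recurrence.recurrent(level="patient")
    report["recurrence"] = {
        "n_genes_recurrent_across_patients": int(len(headline)),
        "n_genes_recurrent_same_patient_only": int(
            recurrence.table["same_patient_only"].sum()
        ),
    }

    expr_path = cohort / "expression.tsv"
    if expr_path.exists():
        expression = gio.read_expression(expr_path)
        report["expressed_fraction"] = expressed_fraction(
            somatic_df, expression, config.min_expr
        )

    actionable_path = cohort / "actionable_genes.tsv"
    if actionable_path.exists():
        actionable = match_actionable(somatic_df, gio.read_actionable(actionable_path))
        actionable.to_csv(out / "actionable.tsv", sep="\t", index=False)
        report["actionable"] = {
            "n_variants": int(len(actionable)),
            "genes": sorted(actionable["gene"].str.upper().unique().tolist()),
        }

    # ---- CNV consensus ---------------------------------------------------
    consensus_per_sample = {}
    all_consensus_rows = []
    for sample in samples:
        segs_a = gio.read_cnv_segments(cohort / "cnv" / f"{sample}.{CNV_CALLERS[0]}.tsv",
                                       sample, CNV_CALLERS[0])
        segs_b = gio.read_cnv_segments(cohort / "cnv" / f"{sample}.{CNV_CALLERS[1]}.tsv",
                                       sample, CNV_CALLERS[1])
        cons = consensus_segments(segs_a, segs_b, config.cnv_min_overlap,
                                  config.cnv_max_uncertainty)
        cons = filter_polymorphic(cons, polymorphic, config.polymorphic_max_frac)
        consensus_per_sample[sample] = cons
        all_consensus_rows.append(consensus_table(cons))
    pd.concat(all_consensus_rows, ignore_index=True).to_csv(
        out / "cnv_consensus.tsv", sep="\t", index=False
    )
    summary = chromosome_summary(consensus_per_sample, sample_universe=samples)
    summary.to_csv(out / "cnv_chromosome_summary.tsv", sep="\t", index=False)
    report["cnv"] = {
        "n_consensus_segments": int(sum(len(c) for c in consensus_per_sample.values())),
    }
    try:
        focal = focal_gene_deletion(consensus_per_sample, gene_model,
                                    config.focal_gene, config.max_focal_len)
        report["cnv"]["focal_deletion"] = {
            "gene": config.focal_gene,
            "samples": focal,
            "fraction_of_samples": len(focal) / len(samples),
        }
    except KeyError:
        logger.warning("stage=cnv focal gene %r absent from gene model", config.focal_gene)

    # ---- fusion consensus -------------------------------------------------
    all_calls = []
    for sample in samples:
        for caller in FUSION_CALLERS:
            path = cohort / "fusions" / f"{sample}.{caller}.tsv"
            if path.exists():
                all_calls.extend(gio.read_fusion_calls(path, sample))
    fusions = consensus_fusions(all_calls, config.fusion_min_callers,
                                known_callers=FUSION_CALLERS)
    fusions = classify_all(fusions, gene_model, config.max_readthrough_gap)
    ft = fusion_table(fusions)
    ft.to_csv(out / "fusion_consensus.tsv", sep="\t", index=False)
    rec_fus = recurrent_fusions(fusions)
    rec_fus.to_csv(out / "fusion_recurrent.tsv", sep="\t", index=False)
    n_rt = sum(f.category == "readthrough_or_conjoined" for f in fusions)
    report["fusions"] = {
        "n_input_calls": len(all_calls),
        "n_consensus": len(fusions),
        "n_readthrough_or_conjoined": n_rt,
        "readthrough_fraction": (n_rt / len(fusions)) if fusions else 0.0,
        "n_recurrent_pairs": int(len(rec_fus)),
    }

    # ---- clonal partitions -------------------------------------------------
    clonal_reports = {}
    gene_by_key = {}
    for row in somatic_df.itertuples(index=False):
        gene_by_key[(row.chrom, row.pos, row.ref, row.alt)] = row.gene
    for patient in patients:
        lesion_ids = sorted(s for s, p in sample_map.items() if p == patient)
        if len(lesion_ids) < 2:
            continue
        sets = {
            s: {
                (r.chrom, r.pos, r.ref, r.alt)
                for r in somatic_df[somatic_df["sample_id"] == s].itertuples(index=False)
            }
            for s in lesion_ids
        }
        part = partition_mutations(sets, patient_id=patient)
        clonal_reports[patient] = partition_report(part)
        matrix = clonal_matrix(part, gene_by_key)
        matrix.to_csv(out / f"clonal_matrix_{patient}.tsv", sep="\t")
    report["clonal"] = clonal_reports

    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable) + "\n"
    )
    return report


def _jsonable(x):
    if hasattr(x, "item"):
        return x.item()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
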