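#!/usr/bin/env python
"""Two-caller CNV consensus, polymorphism filtering and cohort summaries.

Reconciles the uncertainty-scoring caller with the second caller by
reciprocal 80% overlap (uncertainty < 80 where present), removes segments
mostly explained by known copy-number polymorphisms, summarises gain/loss
fractions per chromosome, and queries focal DMD deletions (loss <= 3 Mb
overlapping the gene).  Writes results/cnv_consensus.tsv and
results/cnv_chromosome_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from gistflow import io as gio
from gistflow.cnv import (
    chromosome_summary,
    consensus_segments,
    consensus_table,
    filter_polymorphic,
    focal_gene_deletion,
)
from gistflow.simulate import CNV_CALLERS

cohort = Path("results/cohort")
out = Path("results")
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")
gene_model = gio.read_gene_model(cohort / "genome" / "gene_model.bed")
polymorphic = gio.read_intervals(cohort / "genome" / "polymorphic_regions.bed")

per_sample, tables = {}, []
n_raw = n_cons = n_poly_removed = 0
for sample in sorted(sample_map):
    segs_a = gio.read_cnv_segments(cohort / "cnv" / f"{sample}.{CNV_CALLERS[0]}.tsv",
                                   sample, CNV_CALLERS[0])
    segs_b = gio.read_cnv_segments(cohort / "cnv" / f"{sample}.{CNV_CALLERS[1]}.tsv",
                                   sample, CNV_CALLERS[1])
    n_raw += len(segs_a) + len(segs_b)
    cons = consensus_segments(segs_a, segs_b)
    n_cons += len(cons)
    kept = filter_polymorphic(cons, polymorphic)
    n_poly_removed += len(cons) - len(kept)
    per_sample[sample] = kept
    tables.append(consensus_table(kept))

pd.concat(tables, ignore_index=True).to_csv(out / "cnv_consensus.tsv", sep="\t", index=False)
summary = chromosome_summary(per_sample, sample_universe=sorted(sample_map))
summary.to_csv(out / "cnv_chromosome_summary.tsv", sep="\t", index=False)

print(f"{n_raw} caller segments -> {n_cons} consensus -> "
      f"{n_cons - n_poly_removed} after polymorphism filter "
      f"({n_poly_removed} removed as polymorphic)")
busiest = summary.assign(any_frac=summary[["gain_fraction", "loss_fraction"]].max(axis=1)) \
    .nlargest(3, "any_frac")
for r in busiest.itertuples(index=False):
    print(f"  {r.chrom}: gains in {r.gain_fraction:.0%}, losses in {r.loss_fraction:.0%} of samples")

focal = focal_gene_deletion(per_sample, gene_model, "DMD")
patients = sorted({sample_map[s] for s in focal})
print(f"focal DMD deletion in {len(focal)}/{len(sample_map)} samples "
      f"({len(focal) / len(sample_map):.0%}; patients {', '.join(patients)})")
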