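#!/usr/bin/env python
"""Fusion consensus (>= 2 of 4 predictors) and structural triage.

Votes per ordered gene pair within each sample, then classifies each
consensus fusion against the gene model as read-through/conjoined,
intra-chromosomal or inter-chromosomal, and lists pairs recurring in
>= 2 samples.  Writes results/fusion_consensus.tsv and
results/fusion_recurrent.tsv.
"""

from pathlib import Path

from gistflow import io as gio
from gistflow.fusion import classify_all, consensus_fusions, fusion_table, recurrent_fusions
from gistflow.simulate import FUSION_CALLERS

cohort = Path("results/cohort")
out = Path("results")
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")
gene_model = gio.read_gene_model(cohort / "genome" / "gene_model.bed")

calls = []
for sample in sorted(sample_map):
    for caller in FUSION_CALLERS:
        calls.extend(gio.read_fusion_calls(cohort / "fusions" / f"{sample}.{caller}.tsv",
                                           sample))

fusions = classify_all(
    consensus_fusions(calls, min_callers=2, known_callers=FUSION_CALLERS), gene_model
)
ft = fusion_table(fusions)
ft.to_csv(out / "fusion_consensus.tsv", sep="\t", index=False)
recurrent = recurrent_fusions(fusions)
recurrent.to_csv(out / "fusion_recurrent.tsv", sep="\t", index=False)

n_rt = (ft["category"] == "readthrough_or_conjoined").sum()
print(f"{len(calls)} raw calls -> {len(fusions)} consensus fusions "
      f"(>= 2 of {len(FUSION_CALLERS)} predictors)")
print(f"  {n_rt}/{len(fusions)} ({n_rt / len(fusions):.0%}) are read-through/conjoined")
print("  categories:", ft["category"].value_counts().to_dict())
for r in recurrent.itertuples(index=False):
    print(f"  recurrent: {r.gene5}->{r.gene3} in {r.n_samples} samples ({r.categories})")
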