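#!/usr/bin/env python
"""Somatic mutational burden per Mb of captured coding exome, per sample.

Counts somatic, functionally in-scope variants against the merged capture
target.  Also reports gene recurrence across samples/patients, the fraction
of mutated genes expressed, and matches against the actionable-gene list.
Writes results/burden.tsv and results/recurrence.tsv.
"""

from pathlib import Path

import pandas as pd

from gistflow import io as gio
from gistflow.burden import burden_table, compute_burden, target_size_mb
from gistflow.somatic import expressed_fraction, match_actionable, recurrent_genes
from gistflow.variants import IN_SCOPE_EFFECTS

cohort = Path("results/cohort")
out = Path("results")
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")
status = pd.read_csv(out / "variant_status.tsv", sep="\t", dtype={"chrom": str})
target = gio.read_intervals(cohort / "genome" / "target.bed")

bt = burden_table(compute_burden(status, target, samples=sorted(sample_map)))
bt.to_csv(out / "burden.tsv", sep="\t", index=False)
mb = target_size_mb(target)
print(f"capture target: {mb:.2f} Mb (merged)")
print(f"mean burden {bt['burden_per_mb'].mean():.3f} somatic mutations/Mb "
      f"(range {bt['burden_per_mb'].min():.3f}-{bt['burden_per_mb'].max():.3f}; "
      f"mean count/sample {bt['n_somatic'].mean():.1f})")

somatic = status[(status["status"] == "somatic")
                 & status["effect_class"].isin(IN_SCOPE_EFFECTS)]
rep = recurrent_genes(somatic, sample_map)
rep.table.to_csv(out / "recurrence.tsv", sep="\t", index=False)
top = rep.table.iloc[0]
print(f"most recurrent gene: {top['gene']} "
      f"({top['n_samples']} samples, {top['n_patients']} patients)")
print(f"genes recurrent only within one patient's lesions: "
      f"{int(rep.table['same_patient_only'].sum())}")

expression = gio.read_expression(cohort / "expression.tsv")
print(f"fraction of mutated (gene, sample) pairs expressed: "
      f"{expressed_fraction(somatic, expression):.2f}")

actionable = match_actionable(somatic, gio.read_actionable(cohort / "actionable_genes.tsv"))
print(f"actionable-gene matches: {len(actionable)} variants in "
      f"{sorted(actionable['gene'].str.upper().unique())}")
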