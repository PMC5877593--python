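#!/usr/bin/env python
"""Filter raw calls and classify survivors somatic/germline/undetermined.

Applies the selection cascade (total depth > 10, allele ratio > 0.2,
non-silent or splice-site effect, population frequency < 0.01 in every
database) to each sample's VCF, then classifies every survivor against
the patient's normal pileup.  Writes results/variant_status.tsv and
results/filter_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from gistflow import io as gio
from gistflow.filtering import run_cascade
from gistflow.somatic import classify_cohort

cohort = Path("results/cohort")
out = Path("results")
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")

filtered, count_rows = [], []
for sample in sorted(sample_map):
    variants = gio.read_vcf(cohort / "variants" / f"{sample}.vcf", sample)
    kept, counts = run_cascade(variants)
    filtered.extend(kept)
    count_rows.append({"sample_id": sample, **counts})

counts_df = pd.DataFrame(count_rows)
counts_df.to_csv(out / "filter_counts.tsv", sep="\t", index=False)

pileups = {p: gio.read_pileup(cohort / "pileups" / f"{p}.pileup.tsv")
           for p in sorted(set(sample_map.values()))}
status, summary = classify_cohort(filtered, pileups, sample_map)
status.to_csv(out / "variant_status.tsv", sep="\t", index=False)

total = counts_df[["input", "depth_vaf", "functional", "rarity"]].sum()
print("filter cascade (all samples):")
print(f"  raw calls            {total['input']}")
print(f"  depth/ratio          {total['depth_vaf']}")
print(f"  functional effect    {total['functional']}")
print(f"  novel or rare        {total['rarity']}")
print("classification of survivors:", status["status"].value_counts().to_dict())
print(f"missing-pileup fraction: {summary['missing_pileup_fraction']:.3f}")
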