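#!/usr/bin/env python
"""Clonal partitioning for multi-lesion patients.

Splits each multi-lesion patient's somatic mutations into truncal
(all lesions), partially shared, and private sets, and writes the
lesion x gene presence matrix.  Writes results/clonal_<patient>.json and
results/clonal_matrix_<patient>.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from gistflow import io as gio
from gistflow.clonal import clonal_matrix, partition_mutations, partition_report
from gistflow.variants import IN_SCOPE_EFFECTS

cohort = Path("results/cohort")
out = Path("results")
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")
status = pd.read_csv(out / "variant_status.tsv", sep="\t", dtype={"chrom": str})
somatic = status[(status["status"] == "somatic")
                 & status["effect_class"].isin(IN_SCOPE_EFFECTS)]
gene_by_key = {(r.chrom, r.pos, r.ref, r.alt): r.gene
               for r in somatic.itertuples(index=False)}

patients = sorted({p for p in sample_map.values()
                   if sum(v == p for v in sample_map.values()) >= 2})
for patient in patients:
    lesions = sorted(s for s, p in sample_map.items() if p == patient)
    sets = {s: {(r.chrom, r.pos, r.ref, r.alt)
                for r in somatic[somatic["sample_id"] == s].itertuples(index=False)}
            for s in lesions}
    part = partition_mutations(sets, patient_id=patient)
    (out / f"clonal_{patient}.json").write_text(
        json.dumps(partition_report(part), indent=1) + "\n")
    matrix = clonal_matrix(part, gene_by_key)
    matrix.to_csv(out / f"clonal_matrix_{patient}.tsv", sep="\t")
    truncal_genes = sorted({gene_by_key.get(v, "?") for v in part.truncal})
    print(f"{patient} ({len(lesions)} lesions): {len(part.truncal)} truncal, "
          f"{len(part.partial)} partially shared, {len(part.private)} private")
    print(f"  truncal genes: {', '.join(truncal_genes)}")
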