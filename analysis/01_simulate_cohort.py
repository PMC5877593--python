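#!/usr/bin/env python
"""Generate the default synthetic cohort under results/cohort.

14 patients, 19 tumor samples (one patient with five metastatic lesions,
one with two), ~60x tumor and normal depth, 0.5 somatic mutations/Mb over
a ~30 Mb capture target, a truncal PDGFRA driver in every lesion, 13 true
fusions and a focal DMD deletion in 4 patients.
"""

import argparse
from pathlib import Path

from gistflow import io as gio
from gistflow.simulate import SimConfig, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

config = SimConfig(seed=args.seed)
cohort, truth = generate_cohort(config, args.out)
sample_map = gio.read_sample_map(cohort / "sample_map.tsv")

n_labeled = sum(len(v) for v in truth.variant_labels.values())
print(f"cohort written to {cohort}")
print(f"  {len(set(sample_map.values()))} patients, {len(sample_map)} tumor samples")
print(f"  {n_labeled} labeled variant records "
      f"({sum(len(a) for a in truth.artifacts.values())} designated artifacts on top)")
print(f"  driver locus {truth.driver['gene']} {truth.driver['chrom']}:{truth.driver['pos']} "
      f"{truth.driver['ref']}>{truth.driver['alt']}, truncal in every lesion")
print(f"  {len(truth.true_cnvs)} true CNV segments, {len(truth.true_fusions)} true fusions")
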