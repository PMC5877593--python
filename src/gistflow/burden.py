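"""Somatic mutational burden per megabase of captured coding exome.

Burden is the count of somatic, functionally in-scope variants divided by
the merged length of the capture target in Mb.  The numerator is restricted
to coding non-silent and splice-site (+/-3 bp) variants with status
``somatic``; undetermined variants are excluded.  The denominator is the
union of the capture intervals, so overlapping target regions are not
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

from gistflow.variants import AnnotatedVariant, IN_SCOPE_EFFECTS


@dataclass(frozen=True)
class BurdenResult:
    sample_id: str
    n_somatic: int
    target_mb: float
    burden: float  # somatic mutations per Mb


def target_size_mb(target_intervals: pd.DataFrame) -> float:
    """Merged (union) length of capture intervals in megabases.

    ``target_intervals`` must carry columns ``chrom``, ``start``, ``end``
    in 0-based half-open coordinates (BED convention).  Intervals may
    overlap; the union is measured.  An interval with end <= start is an
    error.
    """
    if target_intervals.empty:
        raise ValueError("empty capture target")
    bad = target_intervals[target_intervals["end"] <= target_intervals["start"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"invalid interval {row['chrom']}:{row['start']}-{row['end']} (end <= start)"
        )
    ranges = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": target_intervals["chrom"].astype(str),
                "Start": target_intervals["start"].astype(int),
                "End": target_intervals["end"].astype(int),
            }
        )
    ).merge()
    total_bp = int((ranges.End - ranges.Start).sum())
    return total_bp / 1e6


def compute_burden(
    somatic_variants: pd.DataFrame | Sequence[AnnotatedVariant],
    target_intervals: pd.DataFrame,
    samples: Iterable[str] | None = None,
) -> list[BurdenResult]:
    """Per-sample somatic mutational burden.

    ``somatic_variants`` is either the classifier's status table (rows with
    ``status == "somatic"`` and an in-scope ``effect_class`` are counted) or
    a sequence of variants already restricted to the somatic set.  Passing
    ``samples`` ensures zero-burden samples appear in the output.
    """
    mb = target_size_mb(target_intervals)
    if isinstance(somatic_variants, pd.DataFrame):
        df = somatic_variants
        if "status" in df.columns:
            df = df[df["status"] == "somatic"]
        df = df[df["effect_class"].isin(IN_SCOPE_EFFECTS)]
        counts = df.groupby("sample_id").size().to_dict()
    else:
        counts = {}
        for v in somatic_variants:
            if v.effect_class in IN_SCOPE_EFFECTS:
                counts[v.sample_id] = counts.get(v.sample_id, 0) + 1
    universe = sorted(set(counts) | set(samples or []))
    return [
        BurdenResult(sample_id=s, n_somatic=counts.get(s, 0), target_mb=mb,
                     burden=counts.get(s, 0) / mb)
        for s in universe
    ]


def burden_table(results: Sequence[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_somatic": r.n_somatic,
                "target_mb": r.target_mb,
                "burden_per_mb": r.burden,
            }
            for r in results
        ]
    )
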