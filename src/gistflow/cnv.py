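"""Two-caller copy-number consensus, polymorphism filtering and summaries.

Copy-number segments from two read-depth callers (an uncertainty-scoring
caller "A", Control-FREEC-like, and a caller "B" without an uncertainty
score, ADTEX-like) are reconciled by reciprocal overlap: a pair of
same-state segments on the same chromosome contributes its intersection to
the consensus when the intersection covers at least ``min_overlap`` (80%)
of *each* segment and the uncertainty, where present, is strictly below
``max_uncertainty`` (80).  Overlapping same-state intersections are merged.
Consensus segments mostly covered by known copy-number polymorphisms are
then discarded, mirroring the Database of Genomic Variants filter.

Coordinates: segment files are 1-based inclusive (caller convention);
everything in memory is 0-based half-open.  The conversion is
``start0 = start1 - 1, end0 = end1`` and round-trips exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

STATES = ("gain", "loss")


@dataclass(frozen=True)
class CnvSegment:
    """One caller's copy-number segment, 0-based half-open."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str  # "gain" or "loss"
    uncertainty: float | None = None  # percentage in [0, 100]; caller A only
    caller: str = ""
    seg_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end} has end <= start"
            )
        if self.state not in STATES:
            raise ValueError(f"unknown CNV state {self.state!r}")
        if self.uncertainty is not None and not 0 <= self.uncertainty <= 100:
            raise ValueError(f"uncertainty {self.uncertainty} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsensusSegment:
    """A region agreed by both callers; never extends outside either source."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    sources: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start


def _qualifying_pairs(
    segs_a: Sequence[CnvSegment],
    segs_b: Sequence[CnvSegment],
    min_overlap: float,
    max_uncertainty: float,
) -> Iterable[tuple[CnvSegment, CnvSegment, int, int]]:
    for a, b in itertools.product(segs_a, segs_b):
        if a.chrom != b.chrom or a.state != b.state:
            continue
        lo, hi = max(a.start, b.start), min(a.end, b.end)
        if hi <= lo:
            continue
        inter = hi - lo
        if inter < min_overlap * a.length or inter < min_overlap * b.length:
            continue
        if a.uncertainty is not None and not a.uncertainty < max_uncertainty:
            continue
        if b.uncertainty is not None and not b.uncertainty < max_uncertainty:
            continue
        yield a, b, lo, hi


def consensus_segments(
    segs_a: Sequence[CnvSegment],
    segs_b: Sequence[CnvSegment],
    min_overlap: float = 0.80,
    max_uncertainty: float = 80.0,
) -> list[ConsensusSegment]:
    """Consensus regions of one sample from two callers' segment lists.

    The overlap requirement is reciprocal (the stricter, symmetric reading):
    the intersection must cover >= ``min_overlap`` of caller A's segment AND
    of caller B's.  The uncertainty threshold is strict (< 80) and applied
    only to segments that carry the field.  A segment may pair with several
    segments of the other caller; every qualifying intersection is emitted
    and overlapping same-state intersections are merged.  Output is sorted
    and duplicate-free.
    """
    all_segs = list(segs_a) + list(segs_b)
    samples = {s.sample_id for s in all_segs}
    if len(samples) > 1:
        raise ValueError(f"segments from multiple samples in one call: {sorted(samples)}")
    if not all_segs:
        return []
    sample = all_segs[0].sample_id

    raw: dict[tuple[str, str], list[tuple[int, int, tuple[str, ...]]]] = {}
    for a, b, lo, hi in _qualifying_pairs(segs_a, segs_b, min_overlap, max_uncertainty):
        raw.setdefault((a.chrom, a.state), []).append((lo, hi, (a.seg_id, b.seg_id)))

    out: list[ConsensusSegment] = []
    for (chrom, state), pieces in raw.items():
        pieces.sort()
        merged: list[list] = []
        for lo, hi, src in pieces:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].update(src)
            else:
                merged.append([lo, hi, set(src)])
        for lo, hi, src in merged:
            out.append(
                ConsensusSegment(
                    sample_id=sample, chrom=chrom, start=lo, end=hi, state=state,
                    sources=tuple(sorted(s for s in src if s)),
                )
            )
    out.sort(key=lambda s: (s.chrom, s.start, s.end, s.state))
    return out


def filter_polymorphic(
    consensus: Sequence[ConsensusSegment],
    polymorphic_regions: pd.DataFrame,
    max_frac: float = 0.5,
) -> list[ConsensusSegment]:
    """Drop consensus segments mostly explained by copy-number polymorphisms.

    ``polymorphic_regions`` has columns ``chrom``, ``start``, ``end``
    (0-based half-open).  A segment is removed when its overlap with any
    single polymorphic region reaches ``max_frac`` of the segment length.
    """
    if polymorphic_regions.empty:
        return list(consensus)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in polymorphic_regions.itertuples(index=False):
        by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    kept = []
    for seg in consensus:
        frac = 0.0
        for lo, hi in by_chrom.get(seg.chrom, ()):
            inter = max(0, min(seg.end, hi) - max(seg.start, lo))
            frac = max(frac, inter / seg.length)
        if frac < max_frac:
            kept.append(seg)
    return kept


def chromosome_summary(
    consensus_per_sample: Mapping[str, Sequence[ConsensusSegment]],
    sample_universe: Iterable[str] | None = None,
    chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome fraction of samples carrying >= 1 gain / >= 1 loss.

    A sample counts at most once per (chromosome, state) however many
    segments it has there.  ``sample_universe`` fixes the denominator
    (samples with no consensus segments still count in it).
    """
    universe = sorted(set(sample_universe or consensus_per_sample.keys()))
    if not universe:
        raise ValueError("empty sample universe")
    chroms = set(chromosomes or ())
    hits: dict[tuple[str, str], set[str]] = {}
    for sample, segs in consensus_per_sample.items():
        for seg in segs:
            chroms.add(seg.chrom)
            hits.setdefault((seg.chrom, seg.state), set()).add(sample)
    rows = []
    for chrom in sorted(chroms):
        rows.append(
            {
                "chrom": chrom,
                "gain_fraction": len(hits.get((chrom, "gain"), ())) / len(universe),
                "loss_fraction": len(hits.get((chrom, "loss"), ())) / len(universe),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "gain_fraction", "loss_fraction"])


def focal_gene_deletion(
    consensus_per_sample: Mapping[str, Sequence[ConsensusSegment]],
    gene_model: pd.DataFrame,
    gene: str,
    max_focal_len: int = 3_000_000,
) -> list[str]:
    """Samples carrying a focal deletion of ``gene``.

    A deletion is focal when the loss segment is no longer than
    ``max_focal_len`` (default 3 Mb; whole-chromosome losses are not focal)
    and overlaps the gene body.  Gene lookup is case-insensitive; an unknown
    gene raises ``KeyError``.
    """
    names = gene_model["name"].astype(str).str.upper()
    match = gene_model[names == gene.strip().upper()]
    if match.empty:
        raise KeyError(f"gene {gene!r} not in gene model")
    g = match.iloc[0]
    g_chrom, g_start, g_end = str(g["chrom"]), int(g["start"]), int(g["end"])
    found = []
    for sample in sorted(consensus_per_sample):
        for seg in consensus_per_sample[sample]:
            if (
                seg.state == "loss"
                and seg.chrom == g_chrom
                and seg.length <= max_focal_len
                and max(seg.start, g_start) < min(seg.end, g_end)
            ):
                found.append(sample)
                break
    return found


def consensus_table(segments: Sequence[ConsensusSegment]) -> pd.DataFrame:
    """Consensus segments as a 1-based inclusive table for writing."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start + 1,
                "end": s.end,
                "state": s.state,
                "sources": ";".join(s.sources),
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "state", "sources"],
    )
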