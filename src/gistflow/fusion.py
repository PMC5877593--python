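"""Fusion-call consensus across four predictors and structural triage.

Chimeric-transcript predictors disagree wildly on exact breakpoints but
agree on partner genes, so calls are matched by ordered (5', 3') gene pair
within a sample.  A fusion enters the consensus when at least two of the
four predictors report it (duplicates within one predictor count once).
Consensus fusions are then triaged structurally against a gene model:
two same-strand neighbours read in transcriptional order are a
read-through/conjoined transcript (no genomic rearrangement implied);
other same-chromosome pairs are intra-chromosomal rearrangements; pairs on
different chromosomes are inter-chromosomal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = ("readthrough_or_conjoined", "intra_chromosomal", "inter_chromosomal")


@dataclass(frozen=True)
class FusionCall:
    """One predictor's chimeric-transcript call (breakpoints 1-based)."""

    sample_id: str
    caller: str
    gene5: str
    gene3: str
    chrom5: str = ""
    pos5: int = 0
    chrom3: str = ""
    pos3: int = 0
    strand5: str = "+"
    strand3: str = "+"
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3:
            raise ValueError(f"fusion partners are the same gene: {self.gene5}")
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")


@dataclass(frozen=True)
class ConsensusFusion:
    """A fusion supported by >= 2 distinct predictors in one sample."""

    sample_id: str
    gene5: str
    gene3: str
    callers: tuple[str, ...]
    chrom5: str = ""
    pos5: int = 0
    chrom3: str = ""
    pos3: int = 0
    category: str = ""


def match_calls(x: FusionCall, y: FusionCall) -> bool:
    """True when two calls describe the same fusion.

    Matching is by ordered gene pair only — 5'/3' orientation matters (the
    read-through interpretation depends on it), breakpoint coordinates do
    not (predictors use different breakpoint conventions).  Symmetric and
    deterministic.
    """
    return (
        x.sample_id == y.sample_id
        and x.gene5 == y.gene5
        and x.gene3 == y.gene3
    )


def consensus_fusions(
    calls: Sequence[FusionCall],
    min_callers: int = 2,
    known_callers: Iterable[str] | None = None,
) -> list[ConsensusFusion]:
    """Fusions reported by at least ``min_callers`` distinct predictors.

    Within-predictor duplicates collapse before voting.  Representative
    breakpoints are taken from the call with most supporting reads (ties
    broken by predictor name, so results do not depend on input order).
    Raises ``ValueError`` for a caller id outside ``known_callers`` when a
    caller universe is given.
    """
    if known_callers is not None:
        known = set(known_callers)
        for c in calls:
            if c.caller not in known:
                raise ValueError(f"unknown caller id {c.caller!r}")
    groups: dict[tuple[str, str, str], list[FusionCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample_id, c.gene5, c.gene3)].append(c)
    out = []
    for (sample, g5, g3), grp in groups.items():
        callers = sorted({c.caller for c in grp})
        if len(callers) < min_callers:
            continue
        rep = max(grp, key=lambda c: (c.supporting_reads, c.caller))
        out.append(
            ConsensusFusion(
                sample_id=sample, gene5=g5, gene3=g3, callers=tuple(callers),
                chrom5=rep.chrom5, pos5=rep.pos5, chrom3=rep.chrom3, pos3=rep.pos3,
            )
        )
    out.sort(key=lambda f: (f.sample_id, f.gene5, f.gene3))
    return out


def _gene_row(gene_model: pd.DataFrame, gene: str) -> pd.Series:
    match = gene_model[gene_model["name"] == gene]
    if match.empty:
        raise KeyError(f"gene {gene!r} not in gene model")
    return match.iloc[0]


def classify_fusion(
    f: ConsensusFusion,
    gene_model: pd.DataFrame,
    max_readthrough_gap: int = 100_000,
) -> str:
    """Structural category of a consensus fusion.

    ``readthrough_or_conjoined``: both genes on the same chromosome and
    strand, the 3' partner lying downstream of the 5' partner in
    transcriptional orientation, and either being the next same-strand gene
    or starting within ``max_readthrough_gap`` of the 5' gene's
    transcriptional end (overlapping neighbours — conjoined genes — also
    qualify).  Same chromosome otherwise: ``intra_chromosomal``.  Different
    chromosomes: ``inter_chromosomal``.
    """
    g5 = _gene_row(gene_model, f.gene5)
    g3 = _gene_row(gene_model, f.gene3)
    if str(g5["chrom"]) != str(g3["chrom"]):
        return "inter_chromosomal"
    if str(g5["strand"]) == str(g3["strand"]):
        strand = str(g5["strand"])
        if strand == "+":
            downstream = int(g3["start"]) > int(g5["start"])
            gap = int(g3["start"]) - int(g5["end"])
        else:
            downstream = int(g3["end"]) < int(g5["end"])
            gap = int(g5["start"]) - int(g3["end"])
        if downstream and (
            gap <= max_readthrough_gap
            or _is_next_same_strand(gene_model, g5, g3, strand)
        ):
            return "readthrough_or_conjoined"
    return "intra_chromosomal"


def _is_next_same_strand(
    gene_model: pd.DataFrame, g5: pd.Series, g3: pd.Series, strand: str
) -> bool:
    same = gene_model[
        (gene_model["chrom"].astype(str) == str(g5["chrom"]))
        & (gene_model["strand"].astype(str) == strand)
    ].sort_values("start")
    names = list(same["name"])
    try:
        i5, i3 = names.index(g5["name"]), names.index(g3["name"])
    except ValueError:
        return False
    return (i3 - i5 == 1) if strand == "+" else (i5 - i3 == 1)


def classify_all(
    fusions: Sequence[ConsensusFusion],
    gene_model: pd.DataFrame,
    max_readthrough_gap: int = 100_000,
) -> list[ConsensusFusion]:
    """Return the consensus list with the ``category`` field filled in."""
    return [
        ConsensusFusion(
            sample_id=f.sample_id, gene5=f.gene5, gene3=f.gene3, callers=f.callers,
            chrom5=f.chrom5, pos5=f.pos5, chrom3=f.chrom3, pos3=f.pos3,
            category=classify_fusion(f, gene_model, max_readthrough_gap),
        )
        for f in fusions
    ]


def recurrent_fusions(consensus: Sequence[ConsensusFusion]) -> pd.DataFrame:
    """Gene pairs seen in >= 2 distinct samples, with their categories."""
    groups: dict[tuple[str, str], list[ConsensusFusion]] = defaultdict(list)
    for f in consensus:
        groups[(f.gene5, f.gene3)].append(f)
    rows = []
    for (g5, g3), grp in sorted(groups.items()):
        samples = sorted({f.sample_id for f in grp})
        if len(samples) < 2:
            continue
        cats = sorted({f.category for f in grp if f.category})
        rows.append(
            {
                "gene5": g5,
                "gene3": g3,
                "n_samples": len(samples),
                "samples": ",".join(samples),
                "categories": ";".join(cats),
            }
        )
    return pd.DataFrame(rows, columns=["gene5", "gene3", "n_samples", "samples", "categories"])


def fusion_table(fusions: Sequence[ConsensusFusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "gene5": f.gene5,
                "gene3": f.gene3,
                "n_callers": len(f.callers),
                "callers": ";".join(f.callers),
                "chrom5": f.chrom5,
                "pos5": f.pos5,
                "chrom3": f.chrom3,
                "pos3": f.pos3,
                "category": f.category,
            }
            for f in fusions
        ],
        columns=[
            "sample_id", "gene5", "gene3", "n_callers", "callers",
            "chrom5", "pos5", "chrom3", "pos3", "category",
        ],
    )
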