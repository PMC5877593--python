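"""CNV consensus: reciprocal overlap, uncertainty, polymorphism filter, queries."""

import numpy as np
import pandas as pd
import pytest

from gistflow.cnv import (
    CnvSegment,
    chromosome_summary,
    consensus_segments,
    filter_polymorphic,
    focal_gene_deletion,
)


def seg(start, end, state="loss", caller="A", unc=None, sample="T01", chrom="chr1", sid=""):
    return CnvSegment(sample_id=sample, chrom=chrom, start=start, end=end,
                      state=state, uncertainty=unc, caller=caller,
                      seg_id=sid or f"{caller}:{start}-{end}")


def test_worked_example_intersection():
    # 1000 bp and 1000 bp segments, 900 bp intersection: 0.9 >= 0.8 for both
    out = consensus_segments([seg(1000, 2000, unc=10)], [seg(1100, 2100, caller="B")])
    assert len(out) == 1
    assert (out[0].start, out[0].end, out[0].state) == (1100, 2000, "loss")


def test_state_must_agree():
    out = consensus_segments([seg(1000, 2000, state="gain", unc=10)],
                             [seg(1000, 2000, state="loss", caller="B")])
    assert out == []


def test_uncertainty_at_or_above_80_excludes_pair():
    a, b = seg(1000, 2000, unc=85), seg(1000, 2000, caller="B")
    assert consensus_segments([a], [b]) == []
    a80 = seg(1000, 2000, unc=80.0)
    assert consensus_segments([a80], [b]) == []  # strict '<'
    a79 = seg(1000, 2000, unc=79.9)
    assert len(consensus_segments([a79], [b])) == 1


def test_identical_segments_give_identity_consensus():
    (out,) = consensus_segments([seg(5000, 9000, unc=5)], [seg(5000, 9000, caller="B")])
    assert (out.start, out.end) == (5000, 9000)


def test_reciprocal_overlap_required_on_both_segments():
    # intersection covers all of A (0.9 of it) but only half of B
    a, b = seg(1000, 2000, unc=5), seg(1000, 3000, caller="B")
    assert consensus_segments([a], [b]) == []


def test_mixed_samples_rejected():
    with pytest.raises(ValueError, match="multiple samples"):
        consensus_segments([seg(0, 10, sample="T01")], [seg(0, 10, sample="T02", caller="B")])


def _rand_interval(rng):
    lo = int(rng.integers(0, 9_999))
    hi = int(rng.integers(lo + 1, 10_001))
    return lo, hi


def test_consensus_never_extends_outside_sources():
    rng = np.random.default_rng(0)
    for _ in range(50):
        sa = [seg(*_rand_interval(rng), unc=float(rng.uniform(0, 100))) for _ in range(3)]
        sb = [seg(*_rand_interval(rng), caller="B") for _ in range(3)]
        for c in consensus_segments(sa, sb):
            assert any(c.start >= s.start and c.end <= s.end for s in sa)
            assert any(c.start >= s.start and c.end <= s.end for s in sb)


def _random_config(rng):
    def rand_segs(caller, with_unc):
        return [
            seg(*_rand_interval(rng), state=str(rng.choice(["gain", "loss"])),
                caller=caller, unc=float(rng.uniform(0, 100)) if with_unc else None)
            for _ in range(int(rng.integers(1, 5)))
        ]
    return rand_segs("A", True), rand_segs("B", False)


def brute_force_base_set(segs_a, segs_b, min_overlap=0.8, max_unc=80.0):
    """A base is consensus iff covered by a qualifying same-state pair."""
    bases = {"gain": set(), "loss": set()}
    for a in segs_a:
        for b in segs_b:
            if a.state != b.state or a.chrom != b.chrom:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            inter = hi - lo
            if inter <= 0:
                continue
            if inter < min_overlap * a.length or inter < min_overlap * b.length:
                continue
            if a.uncertainty is not None and a.uncertainty >= max_unc:
                continue
            bases[a.state].update(range(lo, hi))
    return bases


def test_consensus_matches_per_base_brute_force_on_toy_chromosomes():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        segs_a, segs_b = _random_config(rng)
        expected = brute_force_base_set(segs_a, segs_b)
        got = {"gain": set(), "loss": set()}
        for c in consensus_segments(segs_a, segs_b):
            got[c.state].update(range(c.start, c.end))
        assert got == expected


def test_swapping_caller_labels_leaves_consensus_unchanged():
    rng = np.random.default_rng(77)
    for _ in range(25):
        segs_a, segs_b = _random_config(rng)
        fwd = consensus_segments(segs_a, segs_b)
        swapped = consensus_segments(segs_b, segs_a)
        assert [(c.chrom, c.start, c.end, c.state) for c in fwd] == \
               [(c.chrom, c.start, c.end, c.state) for c in swapped]


def poly_bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_polymorphic_filter():
    cons = consensus_segments([seg(1000, 2000, unc=5)], [seg(1000, 2000, caller="B")])
    # fully inside a polymorphic region: removed
    assert filter_polymorphic(cons, poly_bed([("chr1", 0, 5000)])) == []
    # empty list: identity
    assert filter_polymorphic(cons, poly_bed([])) == cons
    # 40% covered with threshold 0.5: kept
    assert filter_polymorphic(cons, poly_bed([("chr1", 1000, 1400)])) == cons
    # exactly 50% covered: removed (>= threshold)
    assert filter_polymorphic(cons, poly_bed([("chr1", 1000, 1500)])) == []


def consensus(sample, chrom, state, start=0, end=1000):
    from gistflow.cnv import ConsensusSegment
    return ConsensusSegment(sample_id=sample, chrom=chrom, start=start, end=end, state=state)


def test_chromosome_summary_fractions():
    per_sample = {f"T{i:02d}": [] for i in range(1, 20)}  # 19 samples
    for i in range(1, 9):  # 8 samples with a chrX loss
        per_sample[f"T{i:02d}"] = [consensus(f"T{i:02d}", "chrX", "loss"),
                                   consensus(f"T{i:02d}", "chrX", "loss", 5000, 9000)]
    summary = chromosome_summary(per_sample)
    row = summary[summary["chrom"] == "chrX"].iloc[0]
    assert row["loss_fraction"] == pytest.approx(8 / 19)
    assert row["gain_fraction"] == 0.0


def test_chromosome_summary_all_samples_hit():
    per_sample = {s: [consensus(s, "chr14", "loss")] for s in ("T01", "T02", "T03")}
    summary = chromosome_summary(per_sample)
    assert summary.set_index("chrom").at["chr14", "loss_fraction"] == 1.0
    empty = chromosome_summary({s: [] for s in ("T01", "T02")}, chromosomes=["chr1"])
    assert (empty[["gain_fraction", "loss_fraction"]] == 0).all().all()


def test_focal_gene_deletion(toy_gene_model):
    # GC spans chr1:2,300,000-2,400,000
    per_sample = {
        "T01": [consensus("T01", "chr1", "loss", 2_000_000, 2_500_000)],   # 500 kb focal
        "T02": [consensus("T02", "chr1", "loss", 0, 5_000_000)],           # 5 Mb: not focal
        "T03": [consensus("T03", "chr1", "loss", 0, 10_000)],              # elsewhere
        "T04": [consensus("T04", "chr1", "gain", 2_000_000, 2_500_000)],   # gain, not loss
    }
    assert focal_gene_deletion(per_sample, toy_gene_model, "GC") == ["T01"]
    assert focal_gene_deletion(per_sample, toy_gene_model, "gc") == ["T01"]  # case-insensitive
    with pytest.raises(KeyError, match="NOSUCH"):
        focal_gene_deletion(per_sample, toy_gene_model, "NOSUCH")


def test_synthetic_cohort_cnvs_recovered_exactly(default_cohort, default_run):
    """True jittered CNVs survive consensus + polymorphism filter; nothing else does."""
    _, truth = default_cohort
    _, out = default_run
    cons = pd.read_csv(out / "cnv_consensus.tsv", sep="\t", dtype={"chrom": str})
    jitter = 2 * 5_000  # both callers jittered independently
    matched = set()
    for t in truth.true_cnvs:
        sub = cons[(cons["sample_id"] == t["sample_id"])
                   & (cons["chrom"] == t["chrom"]) & (cons["state"] == t["state"])]
        hits = [
            i for i, r in sub.iterrows()
            if abs((r["start"] - 1) - t["start"]) <= jitter and abs(r["end"] - t["end"]) <= jitter
        ]
        assert hits, f"true CNV not recovered: {t}"
        matched.update(hits)
    assert len(matched) == len(cons), "consensus contains segments beyond the true CNVs"
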