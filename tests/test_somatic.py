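"""Somatic classifier rule, cohort classification, recurrence and summaries."""

import pandas as pd
import pytest

from gistflow.somatic import (
    NormalObservation,
    SomaticStatus,
    classify_cohort,
    classify_variant,
    expressed_fraction,
    match_actionable,
    recurrent_genes,
)
from gistflow.variants import AnnotatedVariant


def tumor_variant(chrom="chr1", pos=100, ref="A", alt="G", sample="T01", gene="GENE0001"):
    return AnnotatedVariant(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        total_depth=40, alt_depth=16, gene=gene, effect_class="coding_nonsilent",
    )


def normal_obs(total, alt, chrom="chr1", pos=100, ref="A", alt_base="G"):
    counts = {ref: total - alt, alt_base: alt}
    return NormalObservation(chrom=chrom, pos=pos, ref=ref,
                             allele_counts=counts, total_depth=total)


@pytest.mark.parametrize(
    "total,alt,expected",
    [
        (20, 0, SomaticStatus.SOMATIC),       # clean, well-covered normal
        (16, 1, SomaticStatus.SOMATIC),       # one stray read tolerated at >= 15x
        (30, 2, SomaticStatus.SOMATIC),       # two stray reads tolerated at >= 30x
        (14, 1, SomaticStatus.GERMLINE),      # one read, but normal too shallow for the allowance
        (29, 2, SomaticStatus.GERMLINE),      # two reads below the 30x allowance
        (30, 3, SomaticStatus.GERMLINE),      # three alt reads: always germline
        (4, 0, SomaticStatus.UNDETERMINED),   # normal not informative
        (5, 0, SomaticStatus.UNDETERMINED),   # depth exactly 5: conservative bin
        (6, 0, SomaticStatus.SOMATIC),        # just above the informativeness bound
    ],
)
def test_classifier_rule(total, alt, expected):
    assert classify_variant(tumor_variant(), normal_obs(total, alt)) is expected


def test_classifier_agrees_with_truth_table():
    """Exhaustive check against a literal transcription of the decision rule."""
    v = tumor_variant()
    for total in range(0, 41):
        for alt in range(0, total + 1):
            got = classify_variant(v, normal_obs(total, alt))
            if total < 5 or total == 5:
                want = SomaticStatus.UNDETERMINED
            elif alt == 0:
                want = SomaticStatus.SOMATIC
            elif alt == 1 and total >= 15:
                want = SomaticStatus.SOMATIC
            elif alt == 2 and total >= 30:
                want = SomaticStatus.SOMATIC
            else:
                want = SomaticStatus.GERMLINE
            assert got is want, (total, alt)


def test_more_alt_reads_never_turn_germline_into_somatic():
    v = tumor_variant()
    rank = {SomaticStatus.SOMATIC: 0, SomaticStatus.GERMLINE: 1}
    for total in range(6, 41):
        statuses = [classify_variant(v, normal_obs(total, alt)) for alt in range(total + 1)]
        ranks = [rank[s] for s in statuses]
        assert ranks == sorted(ranks), f"non-monotone at total={total}"


def test_only_exact_alt_allele_counts_against_somatic():
    v = tumor_variant(alt="G")
    n = NormalObservation(chrom="chr1", pos=100, ref="A",
                          allele_counts={"A": 15, "T": 5}, total_depth=20)
    assert classify_variant(v, n) is SomaticStatus.SOMATIC


def test_locus_mismatch_raises_with_both_loci_named():
    v = tumor_variant(pos=100)
    n = normal_obs(20, 0, pos=101)
    with pytest.raises(ValueError, match="chr1:100.*chr1:101"):
        classify_variant(v, n)


def test_classify_cohort_empty_pileup_means_all_undetermined():
    variants = [tumor_variant(pos=p) for p in (10, 20, 30)]
    df, summary = classify_cohort(variants, {"P01": {}}, {"T01": "P01"})
    assert (df["status"] == "undetermined").all()
    assert summary["missing_pileup_fraction"] == 1.0


def test_classify_cohort_statuses_partition_the_input(default_cohort, default_run):
    report, out = default_run
    status = pd.read_csv(out / "variant_status.tsv", sep="\t")
    assert status["status"].isin(["somatic", "germline", "undetermined"]).all()
    counts = report["classification"]["status_counts"]
    assert sum(counts.values()) == len(status)


def test_classification_recovers_truth_labels(default_cohort, default_run):
    """Somatic-vs-germline sensitivity and specificity on the labeled cohort."""
    _, truth = default_cohort
    _, out = default_run
    status = pd.read_csv(out / "variant_status.tsv", sep="\t", dtype={"chrom": str})
    tp = fn = tn = fp = 0
    for r in status.itertuples(index=False):
        key = f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
        label = truth.variant_labels.get(r.sample_id, {}).get(key)
        if label is None or r.status == "undetermined":
            continue
        if label == "somatic":
            tp += r.status == "somatic"
            fn += r.status != "somatic"
        else:
            tn += r.status == "germline"
            fp += r.status != "germline"
    assert tp + fn > 50 and tn + fp > 50  # both classes well represented
    assert tp / (tp + fn) >= 0.95
    assert tn / (tn + fp) >= 0.95


def test_shallow_normal_drives_undetermined_fraction_up(tmp_path):
    """Degrading the normal to ~4x makes most loci uninformative."""
    from gistflow import io as gio
    from gistflow.filtering import run_cascade
    from gistflow.simulate import SimConfig, generate_cohort

    cfg = SimConfig(n_patients=4, lesions_per_patient={}, normal_depth_mean=4.0, seed=5)
    cohort, _ = generate_cohort(cfg, tmp_path / "c")
    smap = gio.read_sample_map(cohort / "sample_map.tsv")
    variants = []
    for s in smap:
        kept, _ = run_cascade(gio.read_vcf(cohort / "variants" / f"{s}.vcf", s))
        variants.extend(kept)
    pileups = {p: gio.read_pileup(cohort / "pileups" / f"{p}.pileup.tsv")
               for p in set(smap.values())}
    df, _ = classify_cohort(variants, pileups, smap)
    assert (df["status"] == "undetermined").mean() > 0.5


def test_contaminated_normal_exercises_one_and_two_read_allowances(tmp_path):
    from gistflow import io as gio
    from gistflow.filtering import run_cascade
    from gistflow.simulate import SimConfig, generate_cohort

    cfg = SimConfig(n_patients=6, lesions_per_patient={},
                    normal_contamination_fraction=0.5, seed=9)
    cohort, truth = generate_cohort(cfg, tmp_path / "c")
    smap = gio.read_sample_map(cohort / "sample_map.tsv")
    variants = []
    for s in smap:
        kept, _ = run_cascade(gio.read_vcf(cohort / "variants" / f"{s}.vcf", s))
        variants.extend(kept)
    pileups = {p: gio.read_pileup(cohort / "pileups" / f"{p}.pileup.tsv")
               for p in set(smap.values())}
    df, _ = classify_cohort(variants, pileups, smap)
    contaminated = df[df["normal_alt"].isin([1, 2])]
    assert len(contaminated) > 0
    # a truth-somatic locus with 1-2 normal reads is somatic iff depth allows
    for r in contaminated.itertuples(index=False):
        key = f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
        if truth.variant_labels.get(r.sample_id, {}).get(key) != "somatic":
            continue
        allowed = (r.normal_alt == 1 and r.normal_depth >= 15) or (
            r.normal_alt == 2 and r.normal_depth >= 30)
        if r.normal_depth > 5:
            assert (r.status == "somatic") == allowed


def test_recurrence_counts_samples_and_patients():
    variants = [tumor_variant(sample=s, gene="TMEM140", pos=500) for s in
                ("T07", "T08", "T09", "T10", "T11")]
    smap = {f"T{i:02d}": "P06" for i in range(7, 12)}
    rep = recurrent_genes(variants, smap)
    row = rep.table.iloc[0]
    assert row["gene"] == "TMEM140"
    assert row["n_samples"] == 5
    assert row["n_patients"] == 1
    assert bool(row["same_patient_only"]) is True
    assert rep.recurrent(level="patient").empty
    assert len(rep.recurrent(level="sample")) == 1


def test_recurrence_empty_and_missing_sample():
    assert recurrent_genes([], {}).table.empty
    with pytest.raises(KeyError, match="T99"):
        recurrent_genes([tumor_variant(sample="T99")], {"T01": "P01"})


def test_driver_gene_recurrent_in_every_patient(default_cohort, default_run):
    path, truth = default_cohort
    _, out = default_run
    from gistflow import io as gio
    status = pd.read_csv(out / "variant_status.tsv", sep="\t", dtype={"chrom": str})
    somatic = status[status["status"] == "somatic"]
    smap = gio.read_sample_map(path / "sample_map.tsv")
    rep = recurrent_genes(somatic, smap)
    driver_row = rep.table[rep.table["gene"] == truth.driver["gene"]].iloc[0]
    assert driver_row["n_patients"] == len(set(smap.values()))
    assert driver_row["n_samples"] == len(smap)


def test_expressed_fraction_counts_mutated_gene_sample_pairs():
    variants = [
        tumor_variant(gene="G1", pos=1),
        tumor_variant(gene="G2", pos=2),
        tumor_variant(gene="G3", pos=3),
    ]
    expr = pd.DataFrame({"T01": [5.0, 0.0, 0.5]}, index=["G1", "G2", "G3"])
    assert expressed_fraction(variants, expr, min_expr=1.0) == pytest.approx(1 / 3)
    assert expressed_fraction(variants, expr.head(0)) == 0.0  # empty table
    expr_all = pd.DataFrame({"T01": [5.0, 5.0, 5.0]}, index=["G1", "G2", "G3"])
    assert expressed_fraction(variants, expr_all) == 1.0


def test_actionable_matching_is_case_insensitive():
    variants = [tumor_variant(gene="tp53", pos=1), tumor_variant(gene="KRAS", pos=2)]
    matched = match_actionable(variants, {"TP53": "tumor suppressor"})
    assert list(matched["gene"]) == ["tp53"]
    assert list(matched["actionable_annotation"]) == ["tumor suppressor"]
    assert match_actionable(variants, []).empty
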