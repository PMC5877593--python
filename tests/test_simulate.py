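"""Generator contracts: determinism, truth-label coverage, rate calibration."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from gistflow import io as gio
from gistflow.burden import target_size_mb
from gistflow.simulate import (
    SimConfig,
    build_genome,
    generate_cohort,
    generate_patient_lesions,
)


def tree_digest(root):
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_file_trees(tmp_path):
    cfg = SimConfig(n_patients=4, lesions_per_patient={"P02": 2}, seed=3)
    generate_cohort(cfg, tmp_path / "a")
    generate_cohort(cfg, tmp_path / "b")
    assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")
    cfg2 = SimConfig(n_patients=4, lesions_per_patient={"P02": 2}, seed=4)
    generate_cohort(cfg2, tmp_path / "c")
    assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "c")


def test_zero_rates_emit_only_the_driver(tmp_path):
    cfg = SimConfig(
        n_patients=3, lesions_per_patient={}, somatic_rate_per_mb=0.0,
        germline_rate_per_mb=0.0, common_variant_rate_per_mb=0.0,
        artifact_rate_per_sample=0.0, seed=1,
    )
    cohort, truth = generate_cohort(cfg, tmp_path / "c")
    for sample in gio.read_sample_map(cohort / "sample_map.tsv"):
        variants = gio.read_vcf(cohort / "variants" / f"{sample}.vcf", sample)
        assert len(variants) == 1
        v = variants[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == (
            truth.driver["chrom"], truth.driver["pos"],
            truth.driver["ref"], truth.driver["alt"],
        )
        assert v.gene == "PDGFRA"


def test_invalid_config_rejected_with_field_name():
    with pytest.raises(ValueError, match="truncal_fraction"):
        SimConfig(truncal_fraction=1.5).validate()
    with pytest.raises(ValueError, match="somatic_rate_per_mb"):
        SimConfig(somatic_rate_per_mb=-1).validate()
    with pytest.raises(ValueError, match="lesions_per_patient"):
        SimConfig(lesions_per_patient={"P01": 0}).validate()
    with pytest.raises(ValueError, match="n_readthrough_events"):
        SimConfig(n_true_fusions=2, n_readthrough_events=5,
                  n_recurrent_fusion_pairs=0).validate()


def test_every_emitted_variant_is_labeled_or_designated_artifact(default_cohort):
    cohort, truth = default_cohort
    for sample in gio.read_sample_map(cohort / "sample_map.tsv"):
        labels = truth.variant_labels[sample]
        artifacts = set(truth.artifacts[sample])
        for v in gio.read_vcf(cohort / "variants" / f"{sample}.vcf", sample):
            key = f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
            assert key in labels or key in artifacts, key
        assert not artifacts & set(labels)


def test_lesion_structure_follows_truncal_fraction():
    cfg = SimConfig(seed=8)
    rng = np.random.default_rng(8)
    genome = build_genome(cfg, rng)

    # truncal_fraction = 1: all lesions share the full somatic set
    cfg_all = SimConfig(truncal_fraction=1.0, seed=8)
    lesions, clonal = generate_patient_lesions("P01", 4, cfg_all, genome=genome, rng=rng)
    sets = [
        {(v["chrom"], v["pos"]) for v in lst} for lst in lesions.values()
    ]
    assert all(s == sets[0] for s in sets)
    assert set(clonal.values()) == {"truncal"}

    # truncal_fraction = 0: only the driver is shared by every lesion
    cfg_none = SimConfig(truncal_fraction=0.0, partial_fraction=0.0, seed=8)
    lesions, clonal = generate_patient_lesions("P02", 4, cfg_none, genome=genome, rng=rng)
    truncal = [k for k, v in clonal.items() if v == "truncal"]
    assert len(truncal) == 1
    chrom, pos, ref, alt = truncal[0].split(":")
    driver = genome.gene_row("PDGFRA")
    assert chrom == driver["chrom"]
    assert driver["start"] < int(pos) <= driver["end"]


def test_patient_lesions_require_at_least_one_lesion():
    with pytest.raises(ValueError, match="n_lesions"):
        generate_patient_lesions("P01", 0, SimConfig())


def test_somatic_rate_calibration_over_many_samples():
    """Mean somatic count per lesion converges to rate x target_mb (3 SE)."""
    cfg = SimConfig(seed=21)
    rng = np.random.default_rng(21)
    genome = build_genome(cfg, rng)
    lam = cfg.somatic_rate_per_mb * genome.target_mb
    counts = []
    for i in range(250):
        lesions, _ = generate_patient_lesions(
            f"P{i:03d}", 1, cfg, genome=genome, rng=rng
        )
        counts.extend(len(v) for v in lesions.values())
    counts = np.asarray(counts, dtype=float)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - lam) <= 3 * se


def test_target_bed_matches_configured_capture_size(default_cohort):
    cohort, _ = default_cohort
    target = gio.read_intervals(cohort / "genome" / "target.bed")
    assert target_size_mb(target) == pytest.approx(30.0, rel=0.01)


def test_default_cohort_shape(default_cohort):
    cohort, truth = default_cohort
    smap = gio.read_sample_map(cohort / "sample_map.tsv")
    assert len(smap) == 19
    assert len(set(smap.values())) == 14
    lesions = {}
    for s, p in smap.items():
        lesions.setdefault(p, []).append(s)
    assert sorted(len(v) for v in lesions.values())[-2:] == [2, 5]
    assert len(truth.true_fusions) == 13
    # designated DMD-deletion patients cover 8 of 19 samples (42%)
    dmd_samples = [s for s, p in smap.items() if p in ("P03", "P06", "P07", "P08")]
    assert len(dmd_samples) == 8
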