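"""Synthetic matched tumor/normal caller output with known ground truth.

The generator emulates the *output* of an exome/transcriptome calling stack
for a cohort of D842V-like GIST patients — not reads or alignments.  It
writes, per sample: an annotated VCF of tumor variant calls, two
copy-number segment tables (an uncertainty-scoring caller and one without),
and four fusion-call tables; per patient: a normal-counterpart pileup; and
cohort-wide: a gene model, a capture-target BED, a polymorphic-CNV BED, a
sample-to-patient map, an expression matrix and an actionable-gene list.
Every non-artifact record carries a ground-truth label, so each downstream
stage can be scored.

What it emulates
----------------
* a shared truncal driver — one designated locus (in the gene named
  PDGFRA of the synthetic gene model) somatic and truncal in every lesion
  of every patient;
* per-lesion somatic burden calibrated to ``somatic_rate_per_mb`` over the
  actual merged capture target, split into truncal / partially shared /
  private variants for multi-lesion patients;
* rare and common germline variants shared by all lesions of a patient
  (one normal genome per patient);
* over-dispersed sequencing depth (negative binomial) and Beta-distributed
  allele fractions (tumor somatic mean below 0.5, reflecting purity < 1);
* caller noise: per-sample artifact calls that fail the depth/ratio or
  functional filters, caller-private CNV and fusion false positives,
  high-uncertainty CNV pairs, and CNVs inside polymorphic regions.

Variants are emitted only when detectable (tumor depth > 10, allele ratio
> 0.2 with >= 1 supporting read), mirroring the fact that callers do not
report events without read support; sub-threshold behaviour of the filter
cascade is exercised by the dedicated artifact records instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gistflow import io as gio
from gistflow.cnv import CnvSegment
from gistflow.fusion import FusionCall
from gistflow.somatic import NormalObservation
from gistflow.variants import AnnotatedVariant

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
AUTOSOMES = CHROMOSOMES[:22]
CNV_CALLERS = ("freec", "adtex")
FUSION_CALLERS = ("tophatfusion", "defuse", "chimerascan", "fusionmap")
BASES = ("A", "C", "G", "T")


def _default_lesions() -> dict[str, int]:
    # Cohort structure: 14 patients, two of them multi-lesion (2 and 5
    # geographically distinct metastases), 19 tumor samples in total.
    return {"P04": 2, "P06": 5}


def _default_dmd_patients() -> tuple[str, ...]:
    # Patients carrying the focal dystrophin (DMD) deletion; with the default
    # lesion structure these contribute 8 of 19 samples (42%).
    return ("P03", "P06", "P07", "P08")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort the pipeline was built around: 14
    patients (19 samples), ~60x tumor and normal depth, ~0.5 somatic
    mutations per Mb over a ~30 Mb capture target, a truncal driver shared
    by every lesion, 13 true fusions of which 12 are read-throughs, and a
    focal DMD deletion in 4 patients.
    """

    n_patients: int = 14
    lesions_per_patient: dict[str, int] = field(default_factory=_default_lesions)
    target_size_mb: float = 30.0
    somatic_rate_per_mb: float = 0.5
    germline_rate_per_mb: float = 1.0
    common_variant_rate_per_mb: float = 2.0
    truncal_fraction: float = 0.6
    partial_fraction: float = 0.1
    tumor_depth_mean: float = 60.0
    normal_depth_mean: float = 60.0
    tumor_vaf_mean: float = 0.4
    depth_dispersion: float = 8.0
    vaf_concentration: float = 25.0
    normal_contamination_fraction: float = 0.0
    low_normal_depth_fraction: float = 0.0
    low_normal_depth_mean: float = 4.0
    artifact_rate_per_sample: float = 10.0
    n_genes: int = 300
    n_true_cnvs: int = 4
    cnv_boundary_jitter_bp: int = 5_000
    polymorphic_cnv_rate: float = 1.0
    cnv_artifact_rate: float = 0.5
    n_true_fusions: int = 13
    n_readthrough_events: int = 12
    n_recurrent_fusion_pairs: int = 2
    caller_fp_rate: float = 2.0
    expressed_gene_fraction: float = 1 / 3
    dmd_deletion_patients: tuple[str, ...] = field(default_factory=_default_dmd_patients)
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "target_size_mb", "somatic_rate_per_mb", "germline_rate_per_mb",
            "common_variant_rate_per_mb", "tumor_depth_mean", "normal_depth_mean",
            "depth_dispersion", "vaf_concentration", "artifact_rate_per_sample",
            "polymorphic_cnv_rate", "cnv_artifact_rate", "caller_fp_rate",
            "low_normal_depth_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.target_size_mb <= 0:
            raise ValueError("target_size_mb must be > 0")
        for name in (
            "truncal_fraction", "partial_fraction", "tumor_vaf_mean",
            "normal_contamination_fraction", "low_normal_depth_fraction",
            "expressed_gene_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        for patient, n in self.lesions_per_patient.items():
            if n < 1:
                raise ValueError(f"lesions_per_patient[{patient!r}] must be >= 1, got {n}")
        if self.n_genes < 30:
            raise ValueError("n_genes must be >= 30")
        if self.n_true_cnvs < 0:
            raise ValueError("n_true_cnvs must be >= 0")
        if self.cnv_boundary_jitter_bp < 0:
            raise ValueError("cnv_boundary_jitter_bp must be >= 0")
        if self.n_true_fusions < 0:
            raise ValueError("n_true_fusions must be >= 0")
        if self.n_readthrough_events > self.n_true_fusions:
            raise ValueError("n_readthrough_events must be <= n_true_fusions")
        if 2 * self.n_recurrent_fusion_pairs > self.n_readthrough_events:
            raise ValueError(
                "n_recurrent_fusion_pairs needs 2 samples each; "
                "2 * n_recurrent_fusion_pairs must be <= n_readthrough_events"
            )

    @property
    def patients(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_patients + 1)]

    def lesion_count(self, patient: str) -> int:
        return self.lesions_per_patient.get(patient, 1)


def _key_str(key: tuple) -> str:
    return ":".join(str(x) for x in key)


@dataclass
class CohortTruth:
    """Ground truth for every labeled record the generator emits.

    Variant keys are ``"chrom:pos:ref:alt"`` strings.  ``variant_labels``
    covers every emitted variant record except the designated caller
    artifacts (listed in ``artifacts``).  ``clonal_assignment`` covers the
    somatic variants of multi-lesion patients: ``"truncal"``,
    ``"partial:T07,T08"`` or ``"private:T07"``.  CNV coordinates are
    0-based half-open.
    """

    driver: dict = field(default_factory=dict)
    variant_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    clonal_assignment: dict[str, dict[str, str]] = field(default_factory=dict)
    artifacts: dict[str, list[str]] = field(default_factory=dict)
    true_cnvs: list[dict] = field(default_factory=list)
    polymorphic_cnvs: list[dict] = field(default_factory=list)
    cnv_artifact_pairs: list[dict] = field(default_factory=list)
    true_fusions: list[dict] = field(default_factory=list)

    @property
    def driver_key(self) -> str:
        d = self.driver
        return _key_str((d["chrom"], d["pos"], d["ref"], d["alt"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CohortTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    genes: pd.DataFrame  # chrom, start, end, name, score, strand (0-based half-open)
    chrom_lengths: dict[str, int]
    target: pd.DataFrame  # chrom, start, end
    polymorphic: pd.DataFrame  # chrom, start, end

    @property
    def target_mb(self) -> float:
        return float((self.target["end"] - self.target["start"]).sum()) / 1e6

    def gene_row(self, name: str) -> pd.Series:
        return self.genes[self.genes["name"] == name].iloc[0]


def build_genome(config: SimConfig, rng: np.random.Generator) -> SyntheticGenome:
    """A few hundred genes on 24 named chromosomes; the target is the gene bodies.

    Gene lengths are lognormal, scaled so the merged target equals the
    configured capture size; intergenic gaps of 20-400 kb leave room for
    both read-through-adjacent pairs (< 100 kb) and well-separated ones.
    """
    n = config.n_genes
    raw = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    lengths = np.maximum((raw / raw.sum() * config.target_size_mb * 1e6).astype(int), 2_000)
    chrom_of = [CHROMOSOMES[i % len(CHROMOSOMES)] for i in range(n)]
    strands = rng.choice(["+", "-"], size=n)

    rows = []
    cursor = {c: 10_000 for c in CHROMOSOMES}
    idx_on_chrom: dict[str, int] = {c: 0 for c in CHROMOSOMES}
    for i in range(n):
        chrom = chrom_of[i]
        gap = int(rng.integers(20_000, 400_000))
        start = cursor[chrom] + gap
        end = start + int(lengths[i])
        cursor[chrom] = end
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": f"GENE{i + 1:04d}",
                "score": 0,
                "strand": strands[i],
                "_ord": idx_on_chrom[chrom],
            }
        )
        idx_on_chrom[chrom] += 1
    genes = pd.DataFrame(rows)

    # Name a handful of genes after their real counterparts so cohort-level
    # queries (driver recurrence, actionable matching, DMD focal deletion)
    # read naturally.  DMD gets the longest chrX gene.
    def rename(chrom: str, new_name: str, pick_longest: bool = False) -> None:
        cand = genes[(genes["chrom"] == chrom) & (~genes["name"].str.startswith(tuple(SPECIAL)))]
        if cand.empty:
            raise ValueError(f"no gene available on {chrom} for {new_name}")
        if pick_longest:
            i = (cand["end"] - cand["start"]).idxmax()
        else:
            i = cand.index[len(cand) // 2]
        genes.loc[i, "name"] = new_name

    SPECIAL = ("PDGFRA", "DMD", "TP53", "IDH1", "FBXW7", "SDHB")
    rename("chr4", "PDGFRA")
    rename("chrX", "DMD", pick_longest=True)
    rename("chr17", "TP53")
    rename("chr2", "IDH1")
    rename("chr4", "FBXW7")
    rename("chr1", "SDHB")

    chrom_lengths = {
        c: int(genes[genes["chrom"] == c]["end"].max()) + 50_000 for c in CHROMOSOMES
    }
    target = genes[["chrom", "start", "end"]].copy()

    # Fixed catalogue of copy-number polymorphic regions on autosomes.
    poly_rows = []
    for _ in range(12):
        chrom = str(rng.choice(AUTOSOMES))
        length = int(rng.integers(200_000, 600_000))
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
        poly_rows.append({"chrom": chrom, "start": start, "end": start + length})
    polymorphic = pd.DataFrame(poly_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    genes = genes.drop(columns="_ord")
    return SyntheticGenome(genes=genes, chrom_lengths=chrom_lengths,
                           target=target, polymorphic=polymorphic)


# ---------------------------------------------------------------------------
# Distributional helpers
# ---------------------------------------------------------------------------

def _nb_depth(rng: np.random.Generator, mean: float, k: float) -> int:
    """Negative-binomial depth with the given mean and dispersion k."""
    if mean <= 0:
        return 0
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def _beta_vaf(rng: np.random.Generator, mean: float, conc: float) -> float:
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    return float(rng.beta(mean * conc, (1 - mean) * conc))


def _detectable_depths(
    rng: np.random.Generator, config: SimConfig, vaf_mean: float
) -> tuple[int, int]:
    """(total_depth, alt_depth) conditioned on caller detectability.

    Callers only emit events with read support above their reporting
    thresholds, so emitted records are drawn from the depth/VAF model
    truncated to total depth > 10 and allele ratio > 0.2.
    """
    for _ in range(1_000):
        depth = _nb_depth(rng, config.tumor_depth_mean, config.depth_dispersion)
        if depth <= 10:
            continue
        vaf = _beta_vaf(rng, vaf_mean, config.vaf_concentration)
        alt = int(rng.binomial(depth, vaf))
        if alt >= 1 and alt / depth > 0.2:
            return depth, alt
    # Pathological configurations (e.g. mean depth ~0) cannot satisfy the
    # truncation; emit a minimal detectable record rather than loop forever.
    return 12, 5


class _LocusSampler:
    """Draws unique variant loci, length-weighted across genes."""

    def __init__(self, genome: SyntheticGenome, rng: np.random.Generator):
        self.genes = genome.genes.reset_index(drop=True)
        lengths = (self.genes["end"] - self.genes["start"]).to_numpy(float)
        self.weights = lengths / lengths.sum()
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, effect_pool: Sequence[str], indel_prob: float = 0.08) -> dict:
        for _ in range(10_000):
            gi = int(self.rng.choice(len(self.genes), p=self.weights))
            g = self.genes.iloc[gi]
            pos = int(self.rng.integers(g["start"] + 1, g["end"] + 1))  # 1-based
            if (g["chrom"], pos) in self.used:
                continue
            self.used.add((g["chrom"], pos))
            ref = str(self.rng.choice(BASES))
            if self.rng.random() < indel_prob:
                alt = ref + str(self.rng.choice(BASES))
            else:
                alt = str(self.rng.choice([b for b in BASES if b != ref]))
            effect = str(self.rng.choice(effect_pool))
            return {
                "chrom": str(g["chrom"]), "pos": pos, "ref": ref, "alt": alt,
                "gene": str(g["name"]), "effect_class": effect,
            }
        raise RuntimeError("could not draw a unique locus; gene model too small")

    def reserve(self, chrom: str, pos: int) -> None:
        self.used.add((chrom, pos))


# ---------------------------------------------------------------------------
# Patient-level variant generation
# ---------------------------------------------------------------------------

SOMATIC_EFFECTS = ["coding_nonsilent"] * 9 + ["splice_site_pm3"]


def _rare_freqs(rng: np.random.Generator) -> dict[str, float]:
    freqs = {}
    for db in gio.DATABASES:
        if rng.random() < 0.5:
            freqs[db] = round(float(rng.uniform(0.0, 0.0095)), 6)
    return freqs


def _common_freqs(rng: np.random.Generator) -> dict[str, float]:
    freqs = {}
    n_db = int(rng.integers(1, len(gio.DATABASES) + 1))
    for db in rng.choice(gio.DATABASES, size=n_db, replace=False):
        freqs[str(db)] = round(float(rng.uniform(0.02, 0.5)), 6)
    return freqs


def generate_patient_lesions(
    patient_id: str,
    n_lesions: int,
    config: SimConfig,
    genome: SyntheticGenome | None = None,
    rng: np.random.Generator | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict[str, list[dict]], dict[str, str]]:
    """Somatic variant content of one patient's lesions, plus clonal truth.

    Returns ``(lesion_variants, clonal_truth)`` where ``lesion_variants``
    maps each sample id to its somatic variant dicts (locus, gene, effect)
    and ``clonal_truth`` maps variant keys to ``truncal`` /
    ``partial:S1,S2`` / ``private:S``.  The designated driver locus is the
    first truncal variant of every patient.  Expected somatic count per
    lesion is ``somatic_rate_per_mb * target_mb`` regardless of the
    truncal/partial/private split.
    """
    if n_lesions < 1:
        raise ValueError(f"n_lesions must be >= 1, got {n_lesions}")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = build_genome(config, rng)
    if sample_ids is None:
        sample_ids = [f"{patient_id}_L{i + 1}" for i in range(n_lesions)]
    sampler = _LocusSampler(genome, rng)
    return _patient_lesions(patient_id, list(sample_ids), config, genome, sampler, rng)


def _driver_variant(genome: SyntheticGenome) -> dict:
    g = genome.gene_row("PDGFRA")
    pos = int((g["start"] + g["end"]) // 2)
    return {
        "chrom": str(g["chrom"]), "pos": pos, "ref": "A", "alt": "T",
        "gene": "PDGFRA", "effect_class": "coding_nonsilent",
    }


def _patient_lesions(
    patient_id: str,
    samples: list[str],
    config: SimConfig,
    genome: SyntheticGenome,
    sampler: _LocusSampler,
    rng: np.random.Generator,
) -> tuple[dict[str, list[dict]], dict[str, str]]:
    n_lesions = len(samples)
    lam = config.somatic_rate_per_mb * genome.target_mb
    tf = config.truncal_fraction
    pf = min(config.partial_fraction, 1.0 - tf) if n_lesions >= 3 else 0.0

    driver = _driver_variant(genome)
    sampler.reserve(driver["chrom"], driver["pos"])

    n_truncal = max(int(rng.poisson(tf * lam)), 1)
    truncal = [driver] + [sampler.draw(SOMATIC_EFFECTS) for _ in range(n_truncal - 1)]

    partial: list[tuple[dict, tuple[str, ...]]] = []
    mean_subset = (2 + (n_lesions - 1)) / 2 if n_lesions >= 3 else 0.0
    if pf > 0:
        for _ in range(int(rng.poisson(pf * lam))):
            v = sampler.draw(SOMATIC_EFFECTS)
            size = int(rng.integers(2, n_lesions))  # 2 .. n_lesions-1
            subset = tuple(sorted(rng.choice(samples, size=size, replace=False)))
            partial.append((v, subset))

    # Private rate keeps the per-lesion expectation at lam exactly.
    partial_per_lesion = pf * lam * (mean_subset / n_lesions) if n_lesions >= 3 else 0.0
    private_rate = max(lam - tf * lam - partial_per_lesion, 0.0)
    private: list[tuple[dict, str]] = []
    for s in samples:
        for _ in range(int(rng.poisson(private_rate))):
            private.append((sampler.draw(SOMATIC_EFFECTS), s))

    lesion_variants: dict[str, list[dict]] = {s: [] for s in samples}
    clonal: dict[str, str] = {}
    for v in truncal:
        key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
        clonal[key] = "truncal"
        for s in samples:
            lesion_variants[s].append(v)
    for v, subset in partial:
        key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
        clonal[key] = "partial:" + ",".join(subset)
        for s in subset:
            lesion_variants[s].append(v)
    for v, s in private:
        key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
        clonal[key] = f"private:{s}"
        lesion_variants[s].append(v)
    return lesion_variants, clonal


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimConfig, out_dir: str | Path
) -> tuple[Path, CohortTruth]:
    """Write a full synthetic cohort under ``out_dir`` and return its truth.

    Identical configurations (including the seed) produce byte-identical
    file trees.  Raises ``ValueError`` for an invalid configuration and
    ``OSError`` if the output directory cannot be written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    truth = CohortTruth()

    genome = build_genome(config, rng)
    sampler = _LocusSampler(genome, rng)
    driver = _driver_variant(genome)
    truth.driver = dict(driver)

    # Directory layout
    gio.ensure_dir(out / "genome")
    gio.ensure_dir(out / "variants")
    gio.ensure_dir(out / "pileups")
    gio.ensure_dir(out / "cnv")
    gio.ensure_dir(out / "fusions")

    gio.write_bed(out / "genome" / "gene_model.bed", genome.genes,
                  ["chrom", "start", "end", "name", "score", "strand"])
    gio.write_bed(out / "genome" / "target.bed", genome.target, ["chrom", "start", "end"])
    gio.write_bed(out / "genome" / "polymorphic_regions.bed", genome.polymorphic,
                  ["chrom", "start", "end"])

    # Samples: sequential tumor ids in patient order (T01, T02, ...).
    sample_map: dict[str, str] = {}
    patient_samples: dict[str, list[str]] = {}
    t = 1
    for patient in config.patients:
        samples = [f"T{t + i:02d}" for i in range(config.lesion_count(patient))]
        t += len(samples)
        patient_samples[patient] = samples
        for s in samples:
            sample_map[s] = patient
    gio.write_sample_map(out / "sample_map.tsv", sample_map)

    all_samples = [s for p in config.patients for s in patient_samples[p]]

    # ---------------- variants + pileups ----------------
    for patient in config.patients:
        samples = patient_samples[patient]
        lesion_somatic, clonal = _patient_lesions(
            patient, samples, config, genome, sampler, rng
        )
        if len(samples) >= 2:
            truth.clonal_assignment[patient] = clonal

        n_germ = int(rng.poisson(config.germline_rate_per_mb * genome.target_mb))
        germline = []
        for _ in range(n_germ):
            v = sampler.draw(SOMATIC_EFFECTS)
            v["pop_freqs"] = _rare_freqs(rng)
            germline.append(v)
        n_common = int(rng.poisson(config.common_variant_rate_per_mb * genome.target_mb))
        common = []
        for _ in range(n_common):
            v = sampler.draw(["coding_nonsilent"] * 6 + ["silent"] * 3 + ["noncoding"])
            v["pop_freqs"] = _common_freqs(rng)
            common.append(v)

        patient_loci: dict[tuple[str, int], dict] = {}

        for sample in samples:
            records: list[AnnotatedVariant] = []
            truth.variant_labels[sample] = {}
            truth.artifacts[sample] = []

            for v in lesion_somatic[sample]:
                depth, alt = _detectable_depths(rng, config, config.tumor_vaf_mean)
                records.append(AnnotatedVariant(
                    sample_id=sample, chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                    alt=v["alt"], total_depth=depth, alt_depth=alt, gene=v["gene"],
                    effect_class=v["effect_class"], pop_freqs={}, caller="mutect",
                ))
                key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
                truth.variant_labels[sample][key] = "somatic"
                patient_loci.setdefault((v["chrom"], v["pos"]), {**v, "label": "somatic"})

            for v in germline + common:
                depth, alt = _detectable_depths(rng, config, 0.5)
                records.append(AnnotatedVariant(
                    sample_id=sample, chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                    alt=v["alt"], total_depth=depth, alt_depth=alt, gene=v["gene"],
                    effect_class=v["effect_class"], pop_freqs=dict(v["pop_freqs"]),
                    caller="haplotypecaller",
                ))
                key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
                truth.variant_labels[sample][key] = "germline"
                patient_loci.setdefault((v["chrom"], v["pos"]), {**v, "label": "germline"})

            for _ in range(int(rng.poisson(config.artifact_rate_per_sample))):
                kind = str(rng.choice(["low_depth", "low_ratio"]))
                v = sampler.draw(SOMATIC_EFFECTS)
                if kind == "low_depth":
                    depth = int(rng.integers(1, 11))
                    alt = int(rng.integers(1, depth + 1))
                else:
                    depth = max(_nb_depth(rng, config.tumor_depth_mean,
                                          config.depth_dispersion), 15)
                    alt = max(int(depth * rng.uniform(0.01, 0.19)), 0)
                records.append(AnnotatedVariant(
                    sample_id=sample, chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                    alt=v["alt"], total_depth=depth, alt_depth=alt, gene=v["gene"],
                    effect_class=v["effect_class"], pop_freqs={}, caller="mutect",
                ))
                key = _key_str((v["chrom"], v["pos"], v["ref"], v["alt"]))
                truth.artifacts[sample].append(key)
                patient_loci.setdefault((v["chrom"], v["pos"]), {**v, "label": "artifact"})

            gio.write_vcf(out / "variants" / f"{sample}.vcf", records, genome.chrom_lengths)

        # One normal per patient: pileup over every locus seen in any lesion.
        observations = []
        for (chrom, pos), v in sorted(patient_loci.items()):
            if (
                config.low_normal_depth_fraction > 0
                and rng.random() < config.low_normal_depth_fraction
            ):
                depth = _nb_depth(rng, config.low_normal_depth_mean, config.depth_dispersion)
            else:
                depth = _nb_depth(rng, config.normal_depth_mean, config.depth_dispersion)
            alt_n = 0
            if v["label"] == "germline":
                vaf = _beta_vaf(rng, 0.5, 30.0)
                alt_n = int(rng.binomial(depth, vaf))
            elif v["label"] == "somatic" and config.normal_contamination_fraction > 0:
                if rng.random() < config.normal_contamination_fraction:
                    alt_n = min(int(rng.integers(1, 3)), depth)
            counts = {b: 0 for b in BASES}
            counts["indel"] = 0
            ref, alt = v["ref"], v["alt"]
            alt_key = alt if (len(ref) == 1 and len(alt) == 1) else "indel"
            counts[alt_key] = alt_n
            counts[ref if len(ref) == 1 else ref[0]] += depth - alt_n
            observations.append(NormalObservation(
                chrom=chrom, pos=pos, ref=ref, allele_counts=counts, total_depth=depth,
            ))
        gio.write_pileup(out / "pileups" / f"{patient}.pileup.tsv", observations)

    # ---------------- CNVs ----------------
    _generate_cnvs(config, genome, all_samples, sample_map, rng, out, truth)

    # ---------------- fusions ----------------
    _generate_fusions(config, genome, all_samples, rng, out, truth)

    # ---------------- expression + actionable list ----------------
    _write_expression(config, genome, all_samples, rng, out)
    pd.DataFrame(
        [
            {"gene": "PDGFRA", "annotation": "TKI target; D842V confers type-II inhibitor resistance"},
            {"gene": "TP53", "annotation": "tumor suppressor; prognostic"},
            {"gene": "IDH1", "annotation": "IDH inhibitor target"},
            {"gene": "FBXW7", "annotation": "ubiquitin ligase; therapy response modifier"},
            {"gene": "SDHB", "annotation": "SDH-deficiency syndrome gene"},
            {"gene": "BRAF", "annotation": "kinase inhibitor target"},
        ]
    ).to_csv(out / "actionable_genes.tsv", sep="\t", index=False)

    truth.save(out / "truth.json")
    return out, truth


def _sample_interval(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    polymorphic: pd.DataFrame,
    min_len: int = 500_000,
    max_len: int = 2_500_000,
    max_poly_frac: float = 0.2,
) -> tuple[str, int, int]:
    """A random autosomal interval clear of occupied intervals and mostly
    clear of the polymorphic catalogue."""
    for _ in range(500):
        chrom = str(rng.choice(AUTOSOMES))
        clen = chrom_lengths[chrom]
        length = int(rng.integers(min_len, max_len + 1))
        if length >= clen - 1:
            continue
        start = int(rng.integers(0, clen - length))
        end = start + length
        if any(max(start, lo) < min(end, hi) for lo, hi in occupied.get(chrom, ())):
            continue
        poly = polymorphic[polymorphic["chrom"] == chrom]
        cover = sum(
            max(0, min(end, int(r.end)) - max(start, int(r.start)))
            for r in poly.itertuples(index=False)
        )
        if cover >= max_poly_frac * length:
            continue
        occupied.setdefault(chrom, []).append((start, end))
        return chrom, start, end
    raise RuntimeError("could not place a CNV interval; genome too crowded")


def _jitter(rng: np.random.Generator, x: int, j: int, lo: int = 0) -> int:
    if j <= 0:
        return max(x, lo)
    return max(int(x + rng.integers(-j, j + 1)), lo)


def _generate_cnvs(config, genome, all_samples, sample_map, rng, out, truth) -> None:
    j = config.cnv_boundary_jitter_bp
    dmd = genome.gene_row("DMD")
    for sample in all_samples:
        segs_a: list[CnvSegment] = []
        segs_b: list[CnvSegment] = []
        occupied: dict[str, list[tuple[int, int]]] = {}

        events: list[tuple[str, int, int, str, str]] = []  # chrom, start, end, state, kind
        if sample_map[sample] in config.dmd_deletion_patients:
            start = max(int(dmd["start"]) - int(rng.integers(50_000, 150_000)), 0)
            end = int(dmd["end"]) + int(rng.integers(50_000, 150_000))
            events.append((str(dmd["chrom"]), start, end, "loss", "true"))
            occupied.setdefault(str(dmd["chrom"]), []).append((start, end))
        for _ in range(config.n_true_cnvs):
            chrom, start, end = _sample_interval(
                rng, genome.chrom_lengths, occupied, genome.polymorphic
            )
            state = str(rng.choice(["gain", "loss"]))
            events.append((chrom, start, end, state, "true"))
        for _ in range(int(rng.poisson(config.polymorphic_cnv_rate))):
            region = genome.polymorphic.iloc[int(rng.integers(0, len(genome.polymorphic)))]
            chrom, lo, hi = str(region["chrom"]), int(region["start"]), int(region["end"])
            if any(max(lo, a) < min(hi, b) for a, b in occupied.get(chrom, ())):
                continue
            occupied.setdefault(chrom, []).append((lo, hi))
            events.append((chrom, lo, hi, str(rng.choice(["gain", "loss"])), "polymorphic"))
        for _ in range(int(rng.poisson(config.cnv_artifact_rate))):
            chrom, start, end = _sample_interval(
                rng, genome.chrom_lengths, occupied, genome.polymorphic
            )
            events.append((chrom, start, end, str(rng.choice(["gain", "loss"])), "artifact"))

        for chrom, start, end, state, kind in events:
            rec = {"sample_id": sample, "chrom": chrom, "start": start,
                   "end": end, "state": state}
            if kind == "true":
                truth.true_cnvs.append(rec)
                unc = float(rng.uniform(5, 60))
            elif kind == "polymorphic":
                truth.polymorphic_cnvs.append(rec)
                unc = float(rng.uniform(5, 60))
            else:
                truth.cnv_artifact_pairs.append(rec)
                unc = float(rng.uniform(80, 100))
            sa = _jitter(rng, start, j)
            ea = max(_jitter(rng, end, j), sa + 1_000)
            sb = _jitter(rng, start, j)
            eb = max(_jitter(rng, end, j), sb + 1_000)
            segs_a.append(CnvSegment(sample_id=sample, chrom=chrom, start=sa, end=ea,
                                     state=state, uncertainty=unc, caller="freec"))
            segs_b.append(CnvSegment(sample_id=sample, chrom=chrom, start=sb, end=eb,
                                     state=state, uncertainty=None, caller="adtex"))

        # Caller-private false segments (no counterpart in the other caller).
        for caller, bucket in (("freec", segs_a), ("adtex", segs_b)):
            for _ in range(int(rng.poisson(config.caller_fp_rate))):
                chrom, start, end = _sample_interval(
                    rng, genome.chrom_lengths, occupied, genome.polymorphic
                )
                bucket.append(CnvSegment(
                    sample_id=sample, chrom=chrom, start=start, end=end,
                    state=str(rng.choice(["gain", "loss"])),
                    uncertainty=float(rng.uniform(5, 60)) if caller == "freec" else None,
                    caller=caller,
                ))

        gio.write_cnv_segments(out / "cnv" / f"{sample}.freec.tsv", segs_a)
        gio.write_cnv_segments(out / "cnv" / f"{sample}.adtex.tsv", segs_b)


def _readthrough_pairs(genes: pd.DataFrame) -> list[tuple[str, str]]:
    """Ordered 5'->3' pairs of adjacent same-strand genes (read-through candidates)."""
    pairs = []
    for chrom in CHROMOSOMES:
        for strand in "+-":
            sub = genes[(genes["chrom"] == chrom) & (genes["strand"] == strand)]
            names = list(sub.sort_values("start")["name"])
            for a, b in zip(names, names[1:]):
                pairs.append((a, b) if strand == "+" else (b, a))
    return pairs


def _distant_same_chrom_pair(
    genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[str, str]:
    """A same-chromosome, opposite-strand gene pair (a genuine rearrangement)."""
    for _ in range(1_000):
        chrom = str(rng.choice(AUTOSOMES))
        sub = genes[genes["chrom"] == chrom]
        plus = sub[sub["strand"] == "+"]
        minus = sub[sub["strand"] == "-"]
        if plus.empty or minus.empty:
            continue
        g5 = plus.iloc[int(rng.integers(0, len(plus)))]
        g3 = minus.iloc[int(rng.integers(0, len(minus)))]
        return str(g5["name"]), str(g3["name"])
    raise RuntimeError("no opposite-strand pair available")


def _inter_chrom_pair(genes: pd.DataFrame, rng: np.random.Generator) -> tuple[str, str]:
    while True:
        g5 = genes.iloc[int(rng.integers(0, len(genes)))]
        g3 = genes.iloc[int(rng.integers(0, len(genes)))]
        if str(g5["chrom"]) != str(g3["chrom"]):
            return str(g5["name"]), str(g3["name"])


def _generate_fusions(config, genome, all_samples, rng, out, truth) -> None:
    genes = genome.genes
    rt_pairs = _readthrough_pairs(genes)
    rng.shuffle(rt_pairs)
    rt_iter = iter(rt_pairs)

    events: list[tuple[str, str, str, str]] = []  # sample, gene5, gene3, category
    n_rt_singles = config.n_readthrough_events - 2 * config.n_recurrent_fusion_pairs
    for _ in range(config.n_recurrent_fusion_pairs):
        g5, g3 = next(rt_iter)
        for sample in rng.choice(all_samples, size=min(2, len(all_samples)), replace=False):
            events.append((str(sample), g5, g3, "readthrough_or_conjoined"))
    for _ in range(n_rt_singles):
        g5, g3 = next(rt_iter)
        events.append((str(rng.choice(all_samples)), g5, g3, "readthrough_or_conjoined"))
    n_rearranged = config.n_true_fusions - config.n_readthrough_events
    for i in range(n_rearranged):
        if i % 2 == 0:
            g5, g3 = _distant_same_chrom_pair(genes, rng)
            cat = "intra_chromosomal"
        else:
            g5, g3 = _inter_chrom_pair(genes, rng)
            cat = "inter_chromosomal"
        events.append((str(rng.choice(all_samples)), g5, g3, cat))

    calls_by_sample_caller: dict[tuple[str, str], list[FusionCall]] = {
        (s, c): [] for s in all_samples for c in FUSION_CALLERS
    }
    true_pairs_by_sample: dict[str, set[tuple[str, str]]] = {s: set() for s in all_samples}

    def breakpoints(g5name: str, g3name: str) -> tuple[str, int, str, int, str, str]:
        g5 = genome.gene_row(g5name)
        g3 = genome.gene_row(g3name)
        pos5 = int(g5["end"]) if g5["strand"] == "+" else int(g5["start"]) + 1
        pos3 = int(g3["start"]) + 1 if g3["strand"] == "+" else int(g3["end"])
        return (str(g5["chrom"]), pos5, str(g3["chrom"]), pos3,
                str(g5["strand"]), str(g3["strand"]))

    for sample, g5, g3, category in events:
        truth.true_fusions.append(
            {"sample_id": sample, "gene5": g5, "gene3": g3, "category": category}
        )
        true_pairs_by_sample[sample].add((g5, g3))
        chrom5, pos5, chrom3, pos3, s5, s3 = breakpoints(g5, g3)
        n_sup = int(rng.integers(2, len(FUSION_CALLERS) + 1))
        callers = rng.choice(FUSION_CALLERS, size=n_sup, replace=False)
        for caller in sorted(str(c) for c in callers):
            calls_by_sample_caller[(sample, caller)].append(FusionCall(
                sample_id=sample, caller=caller, gene5=g5, gene3=g3,
                chrom5=chrom5, pos5=_jitter(rng, pos5, 500, lo=1),
                chrom3=chrom3, pos3=_jitter(rng, pos3, 500, lo=1),
                strand5=s5, strand3=s3,
                supporting_reads=int(rng.poisson(20)) + 2,
            ))

    # Caller-private false positives: unique to one predictor by construction.
    names = list(genes["name"])
    for sample in all_samples:
        fp_used: set[tuple[str, str]] = set(true_pairs_by_sample[sample])
        for caller in FUSION_CALLERS:
            for _ in range(int(rng.poisson(config.caller_fp_rate))):
                for _ in range(100):
                    g5, g3 = rng.choice(names, size=2, replace=False)
                    pair = (str(g5), str(g3))
                    if pair not in fp_used:
                        break
                fp_used.add(pair)
                chrom5, pos5, chrom3, pos3, s5, s3 = breakpoints(*pair)
                calls_by_sample_caller[(sample, caller)].append(FusionCall(
                    sample_id=sample, caller=caller, gene5=pair[0], gene3=pair[1],
                    chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
                    strand5=s5, strand3=s3,
                    supporting_reads=int(rng.poisson(4)) + 1,
                ))

    for sample in all_samples:
        for caller in FUSION_CALLERS:
            gio.write_fusion_calls(
                out / "fusions" / f"{sample}.{caller}.tsv",
                calls_by_sample_caller[(sample, caller)],
            )


def _write_expression(config, genome, all_samples, rng, out) -> None:
    genes = list(genome.genes["name"])
    expressed = rng.random(len(genes)) < config.expressed_gene_fraction
    base = np.where(expressed, rng.lognormal(mean=3.0, sigma=1.0, size=len(genes)), 0.0)
    data = {}
    for sample in all_samples:
        noise = rng.lognormal(mean=0.0, sigma=0.2, size=len(genes))
        data[sample] = np.round(base * noise, 3)
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    df.to_csv(out / "expression.tsv", sep="\t")
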