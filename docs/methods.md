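# Methods

## Scope and model

gistflow covers the *downstream* half of a matched tumor/normal exome +
transcriptome study: it consumes annotated caller output (variant calls
with gene/effect/population-frequency annotations, normal pileups, CNV
segment tables, fusion call tables) and produces the integrated results —
filtered variant sets, somatic/germline status, mutational burden, CNV and
fusion consensus, clonal partitions. Alignment, variant calling,
annotation and segmentation are upstream tools' jobs and are out of scope;
the synthetic generator emulates their output directly.

## Decision rules and their edge cases

**Selection cascade.** All comparators are strict (`> 10`, `> 0.2`,
`< 0.01`), so boundary records are removed; a record with zero total depth
has an undefined allele ratio and is removed. A variant counts as rare only
if it is rare in every database that has observed it — the rarity filter
exists to discard polymorphisms, and one confident database report of a
common allele is sufficient evidence. Multi-allelic VCF records are split
per alternate allele before filtering, since depth and ratio are per-alt
quantities. Records with a missing effect annotation are rejected with a
warning and counted separately rather than silently binned.

**Somatic rule.** The published rule covers normal total depth > 5
(somatic-eligible) and < 5 (undetermined); depth exactly 5 falls between
two strict comparators and is assigned *undetermined*, the conservative
choice — a 5-read normal cannot distinguish a germline heterozygote from
noise with any confidence. Only reads supporting the exact alternate
allele count against somatic status; other non-reference alleles in the
normal (sequencing noise, unrelated variation) do not. The rule is
monotone: at fixed normal depth, more alt reads never move a call from
germline to somatic (verified exhaustively in tests).

**Burden.** Numerator: status = somatic and effect in {coding non-silent,
splice ±3} — the same variant universe the cascade defines; undetermined
variants are excluded, since an uninformative normal supports no somatic
claim. Denominator: merged capture target, not the genome, so overlapping
target intervals are not double-counted.

**CNV consensus.** The 80% overlap requirement is applied reciprocally
(intersection ≥ 80% of *each* caller's segment): the symmetric reading is
stricter and makes the operation invariant to swapping caller labels. The
consensus region is the intersection of the pair, never the union, so no
consensus base lies outside either source segment. One segment may pair
with several segments of the other caller; each qualifying pair contributes
its intersection and overlapping same-state intersections are merged
afterwards (the per-base consensus set is unchanged by merging, which the
brute-force oracle test exploits). The uncertainty cut (< 80, strict) is
applied to whichever segment carries the field — in practice only the
FREEC-like caller does. Segment files are 1-based inclusive as callers
write them; all arithmetic is 0-based half-open and the conversion
round-trips exactly. The polymorphism filter removes a consensus segment
when a single catalogued region covers ≥ 50% of it. "Focal" deletion
means loss length ≤ 3 Mb — a declared, configurable default chosen to
exclude arm- and chromosome-scale losses; no published definition exists.

**Fusion consensus.** Cross-caller matching is by ordered (5′, 3′) gene
pair only: predictors disagree on breakpoint conventions but agree on
partner identity, and orientation matters because the read-through
interpretation depends on it. Within-caller duplicates collapse before
voting, so "≥ 2 callers" always means distinct predictors. Read-through/
conjoined requires same chromosome and strand with the 3′ gene downstream
in transcriptional orientation, and either next-same-strand adjacency or a
gap ≤ 100 kb (default; configurable). Overlapping same-strand neighbours —
conjoined genes — qualify via a negative gap.

**Clonal partition.** Variant identity across lesions is exact
(chrom, pos, ref, alt); all lesions are called against the same reference,
so fuzzy matching would only introduce false sharing. Only
somatic-classified, in-scope variants enter the partition. The partition
is a function of presence/absence counts alone: present in all lesions →
truncal, in one → private, otherwise partially shared. No phylogeny or
cancer-cell-fraction deconvolution is attempted.

## Synthetic cohort: what it emulates and what it does not

The generator's defaults are the study conditions: 14 patients, 19
samples (lesion structure {P04: 2, P06: 5}, all others single), tumor and
normal depth mean 60× (negative binomial, dispersion 8 — capture data are
over-dispersed relative to Poisson, and the wider depth distribution
exercises the classifier's depth branches), somatic rate 0.5/Mb over a
~30 Mb target of ~300 gene bodies on 24 chromosomes, truncal fraction 0.6
with 10% partially shared variants in patients with ≥ 3 lesions, somatic
VAF ~ Beta(mean 0.4, concentration 25) reflecting purity < 1, germline
VAF ~ Beta(mean 0.5, concentration 30). Per-lesion somatic counts are
calibrated exactly: truncal, partial and private draws are independent
Poissons whose per-lesion expectations sum to rate × target Mb, so burden
recovery is a real check of the pipeline, not of the split. One locus in
the synthetic PDGFRA is the designated driver, somatic and truncal in
every lesion of every patient. Four designated patients (8/19 samples,
42%) carry a focal deletion spanning the synthetic DMD gene. Thirteen
true fusions are planted (12 read-throughs — two of them recurrent pairs
in two samples each — and one intra-chromosomal rearrangement), each
emitted by 2–4 of the four pseudo-predictors; every predictor adds
caller-private false calls (Poisson, mean 2/sample), every CNV caller adds
private false segments, and both CNV callers jointly emit high-uncertainty
artifact pairs and segments inside the polymorphic catalogue.

Labeled variants are drawn *conditional on detectability* (tumor depth
> 10, allele ratio > 0.2 with ≥ 1 supporting read): real callers do not
report events without read support, so emitting undetectable "true"
variants would model caller behaviour wrongly and conflate generator and
filter effects. Sub-threshold behaviour of the cascade is exercised
instead by dedicated artifact records (low depth or low ratio, designated
as caller false positives in the truth) and by common polymorphisms
(germline-labeled, removed by the rarity filter).

By default the normal has zero alternate reads at somatic loci and ~60×
depth everywhere. Two knobs degrade it: `normal_contamination_fraction`
injects 1–2 alt reads at somatic loci (exercising the depth-conditional
allowances), and `low_normal_depth_fraction` / `normal_depth_mean` produce
shallow normals (driving variants into *undetermined*). Both default to 0
— with a clean 60× normal, classification is nearly error-free, which is
what the recovery checks measure: that the *rules* are implemented
correctly under favourable data, not that they are robust to arbitrary
noise.

Not emulated: read-level data (no FASTQ/BAM), sequencing-error base
calls, FFPE artifacts, subclonal VAF structure, tumor-in-normal
contamination beyond the 1–2-read knob, caller-specific biases, or a
realistic exome (the gene model is a few hundred synthetic genes, with a
handful named after real counterparts — PDGFRA, DMD, TP53, IDH1, FBXW7,
SDHB — so cohort queries read naturally). Passing tests therefore show
the decision rules and consensus logic are implemented exactly and
recover planted structure at realistic depths and rates; they do not show
robustness to the full noise spectrum of real capture data.

## Numerical and design choices

- Gene-level quantities (actionable matching, focal-deletion lookup) match
  symbols case-insensitively after whitespace stripping.
- Recurrence is reported at sample and patient level; the headline uses
  patients, with `same_patient_only` flagging genes whose recurrence is
  confined to one individual's lesions.
- The expressed fraction counts distinct (sample, gene) mutated pairs with
  expression ≥ 1 (table units) in that sample; genes absent from the table
  count as not expressed. The expression threshold is a declared default.
- Representative breakpoints of a consensus fusion come from the
  supporting call with most reads, ties broken by predictor name, so
  output is independent of file order.
- Consensus output is sorted (chrom, start, end); clonal lesion order is
  sorted sample id; all reports are written with sorted keys — a rerun on
  the same inputs is byte-identical.
- All randomness flows from one `numpy` Generator seeded by the config;
  identical configuration implies byte-identical output trees.
- Problem sizes in tests and in `scripts/acceptance.py` are the default
  cohort (19 samples, ~2,000 labeled records) plus oracle sweeps (861
  rule-table cells, 1,000 random records, 100 random segment
  configurations on 10 kb toy chromosomes, 500 random fusion calls) —
  large enough for stable recovery estimates while keeping a full run in
  seconds.

## Known limitations

- The truncal fraction parameter controls the expected *per-lesion* share
  of truncal variants, not the patient-level fraction; for highly
  asymmetric lesion counts the two differ.
- The per-pair-then-merge CNV consensus can merge intersections arising
  from distinct biological events if callers place same-state segments
  within jitter distance; the generator avoids planting such collisions,
  and real data would need manual review there.
- Gene-pair fusion matching cannot separate two distinct breakpoints
  between the same partners in one sample; they collapse to one consensus
  record.
- With ~300 synthetic genes, chance gene-level recurrence across patients
  is common (unlike a 20,000-gene exome); recurrence summaries on
  synthetic cohorts are meaningful for the driver contract, not as a
  background model.
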