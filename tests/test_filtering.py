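"""Filter cascade: strict thresholds, idempotence, commutation, oracle equality."""

import numpy as np
import pytest

from gistflow.filtering import (
    FilterParams,
    depth_vaf_filter,
    functional_filter,
    rarity_filter,
    run_cascade,
)
from gistflow.variants import AnnotatedVariant


def make_variant(
    total_depth=30,
    alt_depth=15,
    effect_class="coding_nonsilent",
    pop_freqs=None,
    pos=100,
):
    return AnnotatedVariant(
        sample_id="T01", chrom="chr1", pos=pos, ref="A", alt="G",
        total_depth=total_depth, alt_depth=alt_depth,
        gene="GENE0001", effect_class=effect_class, pop_freqs=pop_freqs or {},
    )


@pytest.mark.parametrize(
    "total,alt,kept",
    [
        (11, 3, True),    # depth 11, ratio 0.27: just above both thresholds
        (10, 9, False),   # ratio 0.9 but depth exactly 10: strict '>' removes
        (50, 10, False),  # ratio exactly 0.2: strict '>' removes
        (0, 0, False),    # undefined ratio at zero depth
        (11, 2, False),   # ratio 0.18 below threshold
    ],
)
def test_depth_ratio_thresholds_are_strict(total, alt, kept):
    v = make_variant(total_depth=total, alt_depth=alt)
    assert (depth_vaf_filter([v]) == [v]) is kept


def test_depth_filter_on_empty_input_returns_empty():
    assert depth_vaf_filter([]) == []


@pytest.mark.parametrize(
    "effect,kept",
    [
        ("coding_nonsilent", True),
        ("splice_site_pm3", True),
        ("silent", False),
        ("noncoding", False),
    ],
)
def test_functional_filter_keeps_nonsilent_and_splice(effect, kept):
    v = make_variant(effect_class=effect)
    result, n_missing = functional_filter([v])
    assert (result == [v]) is kept
    assert n_missing == 0


def test_functional_filter_counts_missing_annotation_separately():
    v = make_variant(effect_class="")
    result, n_missing = functional_filter([v])
    assert result == [] and n_missing == 1


@pytest.mark.parametrize(
    "freqs,kept",
    [
        ({}, True),                                   # novel in all databases
        ({"dbSNP": 0.05}, False),                     # common in one database
        ({"dbSNP": 0.009, "ExAC": 0.0001}, True),     # rare everywhere
        ({"dbSNP": 0.001, "ExAC": 0.011}, False),     # rare in one, not the other
        ({"dbSNP": 0.01}, False),                     # boundary: strict '<'
    ],
)
def test_rarity_requires_rare_in_every_database(freqs, kept):
    v = make_variant(pop_freqs=freqs)
    assert (rarity_filter([v]) == [v]) is kept


def test_rarity_filter_rejects_corrupt_frequency():
    v = make_variant(pop_freqs={"dbSNP": 1.5})
    with pytest.raises(ValueError, match="outside"):
        rarity_filter([v])


def _random_variants(n, seed):
    rng = np.random.default_rng(seed)
    effects = ["coding_nonsilent", "splice_site_pm3", "silent", "noncoding"]
    out = []
    for i in range(n):
        total = int(rng.integers(0, 60))
        alt = int(rng.integers(0, total + 1))
        freqs = {}
        for db in ("dbSNP", "ExAC"):
            if rng.random() < 0.5:
                freqs[db] = float(rng.uniform(0, 0.05))
        out.append(
            make_variant(
                total_depth=total, alt_depth=alt,
                effect_class=str(rng.choice(effects)), pop_freqs=freqs, pos=i + 1,
            )
        )
    return out


def brute_force_predicate(v, params=FilterParams()):
    """Independent per-record evaluation of the full selection rule."""
    if not (v.total_depth > params.min_total_depth):
        return False
    if not (v.total_depth and v.alt_depth / v.total_depth > params.min_ratio):
        return False
    if v.effect_class not in ("coding_nonsilent", "splice_site_pm3"):
        return False
    return all(f < params.max_freq for f in v.pop_freqs.values())


def test_cascade_equals_brute_force_on_random_variants():
    variants = _random_variants(1_000, seed=42)
    survivors, counts = run_cascade(variants)
    expected = [v for v in variants if brute_force_predicate(v)]
    assert survivors == expected
    assert counts["rarity"] == len(expected)


def test_cascade_counts_monotone_non_increasing():
    variants = _random_variants(500, seed=7)
    _, counts = run_cascade(variants)
    assert counts["input"] >= counts["depth_vaf"] >= counts["functional"] >= counts["rarity"]


def test_cascade_passes_through_all_passing_input():
    variants = [make_variant(pos=i + 1) for i in range(10)]
    survivors, counts = run_cascade(variants)
    assert survivors == variants
    assert counts == {"input": 10, "depth_vaf": 10, "functional": 10,
                      "missing_effect": 0, "rarity": 10}


def test_one_failure_per_stage_leaves_single_survivor():
    variants = [
        make_variant(pos=1, total_depth=10, alt_depth=9),          # fails depth
        make_variant(pos=2, total_depth=30, alt_depth=3),          # fails ratio
        make_variant(pos=3, effect_class="silent"),                # fails functional
        make_variant(pos=4, effect_class="noncoding"),             # fails functional
        make_variant(pos=5, pop_freqs={"dbSNP": 0.2}),             # fails rarity
        make_variant(pos=6),                                       # passes all
    ]
    survivors, counts = run_cascade(variants)
    assert [v.pos for v in survivors] == [6]
    assert counts == {"input": 6, "depth_vaf": 4, "functional": 2,
                      "missing_effect": 0, "rarity": 1}


def test_filters_idempotent_and_commute():
    variants = _random_variants(300, seed=3)
    once = depth_vaf_filter(variants)
    assert depth_vaf_filter(once) == once
    kept_f, _ = functional_filter(variants)
    assert functional_filter(kept_f)[0] == kept_f
    kept_r = rarity_filter(variants)
    assert rarity_filter(kept_r) == kept_r

    # order independence: rarity then functional == functional then rarity
    a = rarity_filter(functional_filter(variants)[0])
    b, _ = functional_filter(rarity_filter(variants))
    assert a == b
    # depth/ratio commutes with both
    c = depth_vaf_filter(rarity_filter(variants))
    d = rarity_filter(depth_vaf_filter(variants))
    assert c == d
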