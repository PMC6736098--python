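import warnings

import numpy as np
import pandas as pd
import pytest

from ploidyhic.domains import CSD, LSD, MASKED, StructureDomainSet, TransitionMap
from ploidyhic.expression import (
    apply_de_thresholds,
    classify_region_genes,
    de_overlap_bootstrap,
    expression_by_domain,
    gene_bin_assignment,
    promoter_intervals,
    regulatory_bin_frequencies,
)
from ploidyhic.contacts import BALANCED, ContactMatrix
from ploidyhic.genome import GenomeLayout, GenomicInterval


def _layout(n_bins):
    return GenomeLayout([("chr1", n_bins * 50_000)], bin_size=50_000)


def _genes(tss_list, **kw):
    n = len(tss_list)
    base = {
        "gene": [f"g{i}" for i in range(n)],
        "chrom": ["chr1"] * n,
        "tss": tss_list,
        "strand": ["+"] * n,
        "category": ["coding"] * n,
        "expr_a": [1.0] * n,
        "expr_b": [1.0] * n,
        "log2fc": [0.0] * n,
        "de_status": ["none"] * n,
    }
    base.update(kw)
    return pd.DataFrame(base)


# -- gene->bin -------------------------------------------------------------


def test_tss_bin_assignment_half_open():
    layout = _layout(3)
    genes = _genes([49_999, 50_000, 120_000])
    assert gene_bin_assignment(genes, layout).tolist() == [0, 1, 2]


def test_assignment_matches_floor_division_oracle():
    layout = _layout(20)
    rng = np.random.default_rng(2)
    tss = rng.integers(0, 10**6, 10).tolist()
    got = gene_bin_assignment(_genes(tss), layout)
    assert got.tolist() == [t // 50_000 for t in tss]


def test_tss_outside_layout_names_gene():
    with pytest.raises(ValueError, match="g0"):
        gene_bin_assignment(_genes([10**7]), _layout(3))


# -- bootstrap -------------------------------------------------------------


def test_all_bins_flagged_is_degenerate_not_confident():
    layout = _layout(4)
    genes = _genes(
        [10_000, 60_000, 110_000, 160_000] * 3,
        de_status=["up", "down", "none", "none"] * 3,
    )
    flags = np.ones(4, bool)
    with pytest.warns(UserWarning, match="ties the top"):
        res = de_overlap_bootstrap(genes, flags, layout, n_draws=50, seed=0)
    assert res.observed_fraction == 1.0
    assert not res.confident  # strict inequality against the null's 95th pct


def test_no_bins_flagged_gives_zero_and_not_confident():
    layout = _layout(4)
    genes = _genes(
        [10_000, 60_000, 110_000, 160_000] * 3,
        de_status=["up", "down", "none", "none"] * 3,
    )
    res = de_overlap_bootstrap(genes, np.zeros(4, bool), layout, n_draws=50, seed=0)
    assert res.observed_fraction == 0.0
    assert not res.confident


def test_pool_smaller_than_de_count_raises():
    layout = _layout(2)
    genes = _genes([10, 20, 30], de_status=["up", "up", "none"])
    with pytest.raises(ValueError, match="pool"):
        de_overlap_bootstrap(genes, np.ones(2, bool), layout, n_draws=10, seed=0)


def test_observed_invariant_to_pool_relabeling(default_dataset):
    ds = default_dataset
    res1 = de_overlap_bootstrap(
        ds.genes, ds.intended_differential, ds.layout, n_draws=400, seed=5
    )
    shuffled = ds.genes.sample(frac=1.0, random_state=99).reset_index(drop=True)
    res2 = de_overlap_bootstrap(
        shuffled, ds.intended_differential, ds.layout, n_draws=400, seed=5
    )
    assert res1.observed_fraction == pytest.approx(res2.observed_fraction)
    # the null is exchangeable over pool order; quantiles agree statistically
    assert res1.null_95th == pytest.approx(res2.null_95th, abs=0.05)


# -- expression by domain / transitions ------------------------------------


def test_eight_gene_toy_direction_counts():
    layout = _layout(4)
    genes = _genes(
        [10_000, 20_000, 60_000, 70_000, 110_000, 120_000, 160_000, 170_000],
        de_status=["up", "up", "down", "none", "up", "none", "down", "down"],
        log2fc=[2.0, 1.5, -2.0, 0.1, 1.2, -0.2, -1.1, -3.0],
    )
    cats = np.array(["CSD->LSD", "LSD->CSD", "LSD->LSD", "CSD->CSD"], dtype=object)
    tm = TransitionMap(layout, cats, {}, pd.DataFrame())
    out = expression_by_domain(genes, layout, transitions=tm)
    assert out["CSD->LSD"]["n_up"] == 2 and out["CSD->LSD"]["n_down"] == 0
    assert out["LSD->CSD"]["n_up"] == 0 and out["LSD->CSD"]["n_down"] == 1
    assert out["LSD->LSD"]["n_up"] == 1
    assert out["CSD->CSD"]["n_down"] == 2


def test_all_non_de_gives_zero_direction_counts():
    layout = _layout(2)
    genes = _genes([10_000, 60_000])
    cats = np.array(["LSD->LSD", "CSD->CSD"], dtype=object)
    tm = TransitionMap(layout, cats, {}, pd.DataFrame())
    out = expression_by_domain(genes, layout, transitions=tm)
    assert all(v["n_up"] == 0 and v["n_down"] == 0 for v in out.values())


def test_lsd_genes_express_higher_in_simulation(default_dataset):
    from ploidyhic.compare import rank_sum_test

    ds = default_dataset
    labels = np.where(ds.profiles["diploid"] > 0, LSD, CSD).astype(object)
    sd = StructureDomainSet(ds.layout, ds.profiles["diploid"].astype(float), labels)
    out = expression_by_domain(ds.genes, ds.layout, sd=sd)
    res = rank_sum_test(out[LSD]["expr_a"], out[CSD]["expr_a"])
    assert np.median(out[LSD]["expr_a"]) > np.median(out[CSD]["expr_a"])
    assert res.p_greater < 0.01


# -- gene-category tallies -------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected_pct",
    [
        ((1749, 310, 48), (83.0, 14.7, 2.3)),
        ((939, 160, 28), (83.3, 14.2, 2.5)),
    ],
)
def test_switched_region_category_percentages(counts, expected_pct):
    n = sum(counts)
    layout = GenomeLayout([("chr1", 200_000_000)], bin_size=50_000)
    cats = (
        ["coding"] * counts[0] + ["non-coding"] * counts[1] + ["pseudogene"] * counts[2]
    )
    genes = _genes(list(range(10_000, 10_000 + n)), category=cats)
    regions = [GenomicInterval("chr1", 0, 1_000_000)]
    df = classify_region_genes(genes, regions, layout)
    assert df["count"].tolist() == list(counts)
    assert tuple(df["percentage"]) == expected_pct
    assert df["percentage"].sum() == pytest.approx(100.0, abs=0.1)


def test_empty_region_set_gives_na_percentages():
    layout = _layout(4)
    df = classify_region_genes(_genes([10_000]), [], layout)
    assert df["count"].sum() == 0
    assert df["percentage"].isna().all()


# -- DE threshold helper ---------------------------------------------------


def test_apply_de_thresholds_benjamini_hochberg():
    table = pd.DataFrame(
        {
            "gene": list("abcde"),
            "log2fc": [2.0, -1.5, 0.2, 3.0, -2.0],
            "pvalue": [0.001, 0.01, 0.001, 0.04, 0.3],
        }
    )
    out = apply_de_thresholds(table)
    # BH adjusted: sorted p (0.001, 0.001, 0.01, 0.04, 0.3) * 5/rank
    expect_padj = {0.001: 0.0025, 0.01: 5 * 0.01 / 3, 0.04: 0.05, 0.3: 0.3}
    for p, adj in expect_padj.items():
        got = out.loc[out["pvalue"] == p, "padj"].iloc[0]
        assert got == pytest.approx(adj)
    assert out.loc[out["gene"] == "a", "de_status"].iloc[0] == "up"
    assert out.loc[out["gene"] == "c", "de_status"].iloc[0] == "none"  # |lfc| < 1
    assert out.loc[out["gene"] == "e", "de_status"].iloc[0] == "none"  # padj > 0.05


# -- promoter/enhancer enrichment -----------------------------------------


def test_promoter_median_rule_counts():
    layout = _layout(4)
    # promoter counts per bin: 0, 1, 2, 3 -> median 1.5 -> two enriched bins
    tss = [60_000] + [110_000, 120_000] + [160_000, 170_000, 180_000]
    genes = _genes(tss)
    M = np.ones((4, 4))
    cm = ContactMatrix(layout, M, state=BALANCED)
    # enhancer counts per bin: 1, 1, 0, 0 -> median 0.5 -> bins 0 and 1 enriched
    enh = [GenomicInterval("chr1", 10_000, 10_500), GenomicInterval("chr1", 60_000, 60_500)]
    out = regulatory_bin_frequencies(cm, genes, enh)
    assert out["promoter_bins"].tolist() == [2, 3]
    assert out["enhancer_bins"].tolist() == [0, 1]
    # P-P pairs among bins {2,3} incl. diagonal: (2,2),(2,3),(3,3)
    assert out["promoter_promoter"].size == 3
    # E-P pairs: {0,1} x {2,3}
    assert out["enhancer_promoter"].size == 4


def test_equal_promoter_counts_degenerate_median_raises():
    layout = _layout(4)
    genes = _genes([10_000, 60_000, 110_000, 160_000])  # one promoter per bin
    cm = ContactMatrix(layout, np.ones((4, 4)), state=BALANCED)
    enh = [GenomicInterval("chr1", 10_000, 10_500)]
    with pytest.raises(ValueError, match="median"):
        regulatory_bin_frequencies(cm, genes, enh)


def test_minus_strand_promoter_is_downstream_half_open():
    layout = _layout(3)
    genes = _genes([100_000], strand=["-"])
    ivs = promoter_intervals(genes, layout)
    assert (ivs[0].start, ivs[0].end) == (100_001, 102_001)


def test_doubled_condition_has_higher_regulatory_contact_frequency(
    default_dataset, balanced_pair
):
    from ploidyhic.expression import compare_regulatory_frequencies

    ds = default_dataset
    res = compare_regulatory_frequencies(
        balanced_pair["diploid"], balanced_pair["tetraploid"], ds.genes, ds.enhancers
    )
    assert res["promoter_promoter"].p_less < 0.01
    assert res["enhancer_promoter"].p_less < 0.01
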