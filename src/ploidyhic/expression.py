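"""Transcription vs chromatin structure: DE-gene/differential-bin overlap with a
bootstrap null, expression by domain and transition, gene-category tallies in
switched regions, and promoter/enhancer-enriched-bin contact statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import RankSumResult, rank_sum_test
from .contacts import ContactMatrix
from .domains import CSD, LSD, MASKED, StructureDomainSet, TransitionMap
from .genome import GenomeLayout, GenomicInterval, interval_to_bins

GENE_COLUMNS = [
    "gene", "chrom", "tss", "strand", "category",
    "expr_a", "expr_b", "log2fc", "de_status",
]
CATEGORIES = ("coding", "non-coding", "pseudogene")


@dataclass
class BootstrapResult:
    observed_fraction: float
    null_fractions: np.ndarray
    draw_size: int
    observed_percentile: float
    null_95th: float
    confident: bool


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene TSV with the documented columns (see GENE_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "chrom", "tss") if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    return df


def apply_de_thresholds(
    results: pd.DataFrame,
    p_cutoff: float = 0.05,
    fdr_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Derive up/down/none DE status from a differential-expression table.

    Expects ``log2fc`` plus ``pvalue`` and/or ``padj`` columns; when ``padj``
    is absent it is computed from ``pvalue`` by Benjamini–Hochberg.
    """
    df = results.copy()
    if "padj" not in df.columns:
        if "pvalue" not in df.columns:
            raise ValueError("need a pvalue or padj column")
        p = df["pvalue"].to_numpy(float)
        order = np.argsort(p)
        n = len(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        padj = np.empty(n)
        padj[order] = np.minimum(adj, 1.0)
        df["padj"] = padj
    sig = (df["padj"] <= fdr_cutoff) & (np.abs(df["log2fc"]) >= lfc_cutoff)
    if "pvalue" in df.columns:
        sig &= df["pvalue"] <= p_cutoff
    df["de_status"] = "none"
    df.loc[sig & (df["log2fc"] > 0), "de_status"] = "up"
    df.loc[sig & (df["log2fc"] < 0), "de_status"] = "down"
    return df


def gene_bin_assignment(genes: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Genome-wide bin id containing each gene's TSS."""
    out = np.empty(len(genes), dtype=np.int64)
    for pos, row in enumerate(genes.itertuples()):
        try:
            out[pos] = layout.bin_index(row.chrom, int(row.tss))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"gene {row.gene}: {exc}") from exc
    return out


def de_overlap_bootstrap(
    genes: pd.DataFrame,
    differential_flags: np.ndarray,
    layout: GenomeLayout,
    n_draws: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test of DE-gene enrichment in differential-interaction bins.

    Observed statistic: fraction of DE genes whose TSS bin is flagged.  Null:
    ``n_draws`` equal-size groups of non-regulated genes sampled without
    replacement; the verdict is confident iff the observed fraction is strictly
    above the null's 95th percentile.
    """
    bins = gene_bin_assignment(genes, layout)
    in_flagged = differential_flags[bins]
    de = genes["de_status"].isin(["up", "down"]).to_numpy()
    n_de = int(de.sum())
    if n_de == 0:
        raise ValueError("no DE genes in the table")
    pool = np.where(~de)[0]
    if pool.size < n_de:
        raise ValueError(
            f"non-regulated pool ({pool.size}) smaller than DE count ({n_de})"
        )
    observed = float(in_flagged[de].mean())
    rng = np.random.default_rng(seed)
    pool_flags = in_flagged[pool].astype(float)
    # vectorized without-replacement draws: the n_de smallest of i.i.d. uniforms
    # per row are a uniform random subset of the pool
    u = rng.random((n_draws, pool.size))
    picks = np.argpartition(u, n_de - 1, axis=1)[:, :n_de]
    null = pool_flags[picks].mean(axis=1)
    null_95 = float(np.percentile(null, 95))
    confident = observed > null_95
    if not confident and observed >= null.max():
        warnings.warn(
            "observed fraction ties the top of the null distribution; "
            "strict-inequality rule gives a non-confident verdict"
        )
    percentile = float((null < observed).mean() * 100)
    return BootstrapResult(observed, null, n_de, percentile, null_95, confident)


def expression_by_domain(
    genes: pd.DataFrame,
    layout: GenomeLayout,
    sd: StructureDomainSet | None = None,
    transitions: TransitionMap | None = None,
) -> dict:
    """Expression distributions per SD label and DE directions per transition.

    With ``sd``: per-label (LSD/CSD) expression value distributions for each
    condition.  With ``transitions``: per-category log2FC distributions and
    up/down DE-gene counts.
    """
    if (sd is None) == (transitions is None):
        raise ValueError("provide exactly one of sd or transitions")
    bins = gene_bin_assignment(genes, layout)
    out: dict = {}
    if sd is not None:
        for lab in (LSD, CSD):
            sel = sd.labels[bins] == lab
            if not sel.any():
                warnings.warn(f"no genes in {lab} bins; category dropped")
                continue
            out[lab] = {
                "expr_a": genes.loc[sel, "expr_a"].to_numpy(float),
                "expr_b": genes.loc[sel, "expr_b"].to_numpy(float),
            }
        return out
    cats = transitions.categories[bins]
    for cat in ("LSD->LSD", "CSD->CSD", "CSD->LSD", "LSD->CSD"):
        sel = cats == cat
        if not sel.any():
            warnings.warn(f"no genes in {cat} bins; category dropped")
            continue
        sub = genes.loc[sel]
        out[cat] = {
            "log2fc": sub["log2fc"].to_numpy(float),
            "n_up": int((sub["de_status"] == "up").sum()),
            "n_down": int((sub["de_status"] == "down").sum()),
        }
    return out


def classify_region_genes(
    genes: pd.DataFrame, regions: list[GenomicInterval], layout: GenomeLayout
) -> pd.DataFrame:
    """Tally gene categories for genes whose TSS lies in the given regions.

    Percentages are count/total*100 rounded to one decimal; with zero genes the
    percentages are NA.
    """
    in_region = np.zeros(len(genes), dtype=bool)
    for pos, row in enumerate(genes.itertuples()):
        for iv in regions:
            if iv.chrom == row.chrom and iv.start <= row.tss < iv.end:
                in_region[pos] = True
                break
    sub = genes.loc[in_region]
    counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
    total = sum(counts.values())
    rows = []
    for c in CATEGORIES:
        pct = round(100.0 * counts[c] / total, 1) if total else np.nan
        rows.append({"category": c, "count": counts[c], "percentage": pct})
    return pd.DataFrame(rows)


# -- promoter / enhancer contact statistics --------------------------------


def promoter_intervals(genes: pd.DataFrame, layout: GenomeLayout,
                       upstream: int = 2000) -> list[GenomicInterval]:
    """Strand-aware promoters: the 2-kb window upstream of each TSS (half-open)."""
    out = []
    lengths = layout.chrom_lengths
    for row in genes.itertuples():
        tss = int(row.tss)
        if getattr(row, "strand", "+") == "-":
            s, e = tss + 1, tss + 1 + upstream
        else:
            s, e = tss - upstream, tss
        s = max(0, s)
        e = min(e, lengths[row.chrom])
        if s < e:
            out.append(GenomicInterval(row.chrom, s, e, name=str(row.gene)))
    return out


def _enriched_bins(
    intervals: list[GenomicInterval], layout: GenomeLayout, mask: np.ndarray
) -> np.ndarray:
    """Bins containing strictly more elements (by midpoint) than the median bin."""
    counts = np.zeros(layout.n_bins)
    for iv in intervals:
        mid = (iv.start + iv.end) // 2
        mid = min(mid, layout.chrom_lengths[iv.chrom] - 1)
        counts[layout.bin_index(iv.chrom, mid)] += 1
    med = np.median(counts[mask])
    enriched = mask & (counts > med)
    if not enriched.any():
        raise ValueError(
            "median enrichment rule degenerated: no bin exceeds the median count"
        )
    return enriched


def regulatory_bin_frequencies(
    M: ContactMatrix,
    genes: pd.DataFrame,
    enhancers: list[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Contact-value distributions among promoter- and enhancer-enriched bins.

    Promoter-enriched bins hold more promoters than the median over unmasked
    bins (strict), likewise enhancer-enriched bins.  Returns the
    promoter-promoter values (all unordered pairs of promoter-enriched bins)
    and enhancer-promoter values (pairs of one enhancer- and one
    promoter-enriched bin).
    """
    layout = M.layout
    proms = promoter_intervals(genes, layout)
    p_bins = _enriched_bins(proms, layout, M.mask)
    e_bins = _enriched_bins(enhancers, layout, M.mask)
    p_idx = np.where(p_bins)[0]
    e_idx = np.where(e_bins)[0]
    iu, ju = np.triu_indices(layout.n_bins)
    both_p = p_bins[iu] & p_bins[ju]
    pp = M.matrix[iu[both_p], ju[both_p]]
    ep_pairs = set()
    for e in e_idx:
        for p in p_idx:
            if e != p:
                ep_pairs.add((min(e, p), max(e, p)))
    ep = np.array([M.matrix[i, j] for i, j in sorted(ep_pairs)])
    return {"promoter_promoter": pp, "enhancer_promoter": ep,
            "promoter_bins": p_idx, "enhancer_bins": e_idx}


def compare_regulatory_frequencies(
    M_a: ContactMatrix,
    M_b: ContactMatrix,
    genes: pd.DataFrame,
    enhancers: list[GenomicInterval],
) -> dict[str, RankSumResult]:
    """Rank-sum comparison of P-P and E-P contact values between two conditions."""
    fa = regulatory_bin_frequencies(M_a, genes, enhancers)
    fb = regulatory_bin_frequencies(M_b, genes, enhancers)
    return {
        "promoter_promoter": rank_sum_test(fa["promoter_promoter"], fb["promoter_promoter"]),
        "enhancer_promoter": rank_sum_test(fa["enhancer_promoter"], fb["enhancer_promoter"]),
    }
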