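"""Between-condition comparison of balanced contact maps.

The central object is the standardized log2 difference matrix Z: balanced map A
is divided elementwise by balanced map B after patching zeros with each matrix's
1st-percentile non-zero value, log2-transformed, and median-centred.  Per-bin
scores over Z flag differential-interaction bins; companion statistics cover
trans/cis ratios, region-class contact distributions, rank-sum tests and the
observed/expected inter-chromosome log-ratio map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contacts import BALANCED, ContactMatrix
from .genome import ARM_LEFT, ARM_RIGHT, PERICENTROMERE, GenomeLayout, build_bins, telomere_bins

REGION_CLASSES = (
    "intra_arm",
    "inter_arm_same_chrom",
    "inter_chrom",
    "intra_pericentromere",
    "inter_pericentromere",
    "intra_telomere",
    "inter_telomere",
)


@dataclass
class DifferenceMatrix:
    layout: GenomeLayout
    Z: np.ndarray
    mask: np.ndarray  # per-bin usable flag (unmasked in both inputs)
    patch_quantile: float
    bin_score: np.ndarray | None = None
    differential: np.ndarray | None = None
    rule: str | None = None


@dataclass
class RankSumResult:
    statistic: float
    p_two_sided: float
    p_less: float
    p_greater: float
    n1: int
    n2: int


def _patch_zeros(M: np.ndarray, q: float) -> np.ndarray:
    nz = M[M > 0]
    if nz.size == 0:
        raise ValueError("matrix has no non-zero entries; cannot patch zeros")
    fill = np.quantile(nz, q)
    out = M.copy()
    out[out == 0] = fill
    return out


def difference_matrix(
    A: ContactMatrix, B: ContactMatrix, patch_quantile: float = 0.01
) -> DifferenceMatrix:
    """Standardized log2 ratio of two balanced maps (A over B).

    Zeros in each map are replaced by that map's ``patch_quantile`` quantile of
    its non-zero entries; the elementwise log2 ratio is then centred by
    subtracting its median over unmasked entries.
    """
    if A.state != BALANCED or B.state != BALANCED:
        raise ValueError("difference_matrix expects balanced matrices")
    if A.layout.n_bins != B.layout.n_bins:
        raise ValueError("layout mismatch")
    mask = A.mask & B.mask
    sub = np.ix_(mask, mask)
    Ma = _patch_zeros(A.matrix[sub], patch_quantile)
    Mb = _patch_zeros(B.matrix[sub], patch_quantile)
    L = np.log2(Ma / Mb)
    L -= np.median(L)
    n = A.layout.n_bins
    Z = np.zeros((n, n))
    Z[sub] = L
    return DifferenceMatrix(A.layout, Z, mask=mask, patch_quantile=patch_quantile)


def distance_normalized(D: DifferenceMatrix) -> np.ndarray:
    """Z residuals after removing the per-distance cis median and trans median.

    A genome-wide change of decay exponent or trans level shifts whole
    diagonals of Z; centring each cis diagonal (and the trans field) on its
    median leaves the bin-specific differences a differential-*bin* score
    should see.
    """
    n = D.layout.n_bins
    ci = D.layout.bin_chrom_index()
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :])
    same = ci[:, None] == ci[None, :]
    mm = D.mask[:, None] & D.mask[None, :]
    Zr = D.Z.copy()
    for d in range(n):
        sel = same & (s == d) & mm
        if sel.any():
            Zr[sel] -= np.median(D.Z[sel])
    trans = ~same & mm
    if trans.any():
        Zr[trans] -= np.median(D.Z[trans])
    return Zr


def call_differential_bins(
    D: DifferenceMatrix,
    stat: str = "mean_abs",
    threshold: float | None = None,
    top_fraction: float | None = 0.25,
    scope: str = "all",
    distance_normalize: bool = True,
) -> np.ndarray:
    """Score each bin on |Z| over its row and flag differential-interaction bins.

    By default the score is the mean of |Z| over the bin's whole unmasked row
    after per-distance median centring (see :func:`distance_normalized`), so
    that a genome-wide decay or trans-level shift does not dominate every bin's
    score.  ``stat`` may be ``mean_abs`` (default: sensitive to changes
    confined to part of the row, e.g. a cis-only compartment flip) or
    ``median_abs``; ``scope`` is ``all`` (default) or ``cis``.  Exactly one of
    ``threshold`` (absolute score cutoff) and ``top_fraction`` (flag the top
    fraction of bins by score) applies; flags, scores and the rule are stored
    on ``D`` and returned.
    """
    if stat not in ("median_abs", "mean_abs"):
        raise ValueError(f"unknown stat {stat!r}")
    if scope not in ("cis", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold is None:
        if top_fraction is None or not (0 < top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1] when no threshold given")
    n = D.layout.n_bins
    ci = D.layout.bin_chrom_index()
    Z = distance_normalized(D) if distance_normalize else D.Z
    absZ = np.abs(Z)
    score = np.zeros(n)
    fn = np.median if stat == "median_abs" else np.mean
    for i in range(n):
        if not D.mask[i]:
            continue
        cols = D.mask.copy()
        if scope == "cis":
            cols &= ci == ci[i]
        vals = absZ[i, cols]
        if vals.size:
            score[i] = fn(vals)
    flags = np.zeros(n, dtype=bool)
    idx = np.where(D.mask)[0]
    if threshold is not None:
        flags[idx] = score[idx] >= threshold
        rule = (
            f"stat={stat},scope={scope},threshold={threshold},"
            f"distance_normalize={distance_normalize}"
        )
    else:
        k = int(np.ceil(top_fraction * idx.size))
        order = idx[np.argsort(score[idx])[::-1]]
        chosen = order[:k]
        # a zero score never qualifies under a relative rule
        flags[chosen[score[chosen] > 0]] = True
        rule = (
            f"stat={stat},scope={scope},top_fraction={top_fraction},"
            f"distance_normalize={distance_normalize}"
        )
    D.bin_score, D.differential, D.rule = score, flags, rule
    return flags


# -- interaction-frequency statistics --------------------------------------


def trans_cis_ratio(M: ContactMatrix) -> tuple[dict[str, float], float]:
    """Per-chromosome and genome-wide trans/cis contact ratios.

    Cis sums include the diagonal; each off-diagonal pair is counted once.
    """
    layout = M.layout
    ci = layout.bin_chrom_index()
    mask = M.mask
    per_chrom: dict[str, float] = {}
    tot_cis = tot_trans = 0.0
    iu, ju = np.triu_indices(layout.n_bins)
    keep = mask[iu] & mask[ju]
    iu, ju = iu[keep], ju[keep]
    vals = M.matrix[iu, ju]
    same = ci[iu] == ci[ju]
    for k, name in enumerate(layout.chrom_names):
        on_c = (ci[iu] == k) | (ci[ju] == k)
        cis = vals[on_c & same].sum()
        trans = vals[on_c & ~same].sum()
        if cis == 0:
            raise ValueError(f"zero cis sum on chromosome {name}")
        per_chrom[name] = float(trans / cis)
    tot_cis = vals[same].sum()
    tot_trans = vals[~same].sum()
    if tot_cis == 0:
        raise ValueError("zero genome-wide cis sum")
    return per_chrom, float(tot_trans / tot_cis)


def _region_class_of_bins(layout: GenomeLayout) -> np.ndarray:
    return np.array([b.region_class for b in build_bins(layout)])


def region_pair_frequencies(
    M: ContactMatrix, class_pair: str, include_diagonal: bool = True
) -> np.ndarray:
    """Balanced contact values for every bin pair in a genomic region class.

    Classes: intra_arm (both bins in the same arm of the same chromosome),
    inter_arm_same_chrom, inter_chrom, intra/inter_pericentromere and
    intra/inter_telomere (telomeric ends per the layout's telomere fraction).
    """
    if class_pair not in REGION_CLASSES:
        raise ValueError(f"unknown class {class_pair!r}; choose from {REGION_CLASSES}")
    layout = M.layout
    n = layout.n_bins
    ci = layout.bin_chrom_index()
    rc = _region_class_of_bins(layout)
    iu, ju = np.triu_indices(n, k=0 if include_diagonal else 1)
    keep = M.mask[iu] & M.mask[ju]
    iu, ju = iu[keep], ju[keep]
    same_chrom = ci[iu] == ci[ju]
    is_arm_i = np.isin(rc[iu], (ARM_LEFT, ARM_RIGHT))
    is_arm_j = np.isin(rc[ju], (ARM_LEFT, ARM_RIGHT))

    if class_pair == "intra_arm":
        sel = same_chrom & is_arm_i & is_arm_j & (rc[iu] == rc[ju])
    elif class_pair == "inter_arm_same_chrom":
        sel = same_chrom & is_arm_i & is_arm_j & (rc[iu] != rc[ju])
    elif class_pair == "inter_chrom":
        sel = ~same_chrom
    elif class_pair == "intra_pericentromere":
        sel = same_chrom & (rc[iu] == PERICENTROMERE) & (rc[ju] == PERICENTROMERE)
    elif class_pair == "inter_pericentromere":
        sel = ~same_chrom & (rc[iu] == PERICENTROMERE) & (rc[ju] == PERICENTROMERE)
    else:
        tel = telomere_bins(layout)
        end_id = np.full(n, -1)
        for k, ids in enumerate(tel.values()):
            end_id[np.asarray(ids, dtype=int)] = k
        in_tel_i, in_tel_j = end_id[iu] >= 0, end_id[ju] >= 0
        if class_pair == "intra_telomere":
            sel = in_tel_i & in_tel_j & (end_id[iu] == end_id[ju])
        else:  # inter_telomere: pairs spanning two different telomeric ends
            sel = in_tel_i & in_tel_j & (end_id[iu] != end_id[ju])
    vals = M.matrix[iu[sel], ju[sel]]
    if vals.size == 0:
        raise ValueError(f"region class {class_pair!r} is empty on this layout")
    return vals


def rank_sum_test(x, y) -> RankSumResult:
    """Wilcoxon/Mann–Whitney rank-sum test.

    Exact enumeration for small tie-free samples (n1+n2 <= 12), tie-corrected
    normal approximation otherwise.  Identical constant samples give p = 1 with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        u = x.size * y.size / 2
        return RankSumResult(u, 1.0, 1.0, 1.0, x.size, y.size)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res_two = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    res_less = stats.mannwhitneyu(x, y, alternative="less", method=method)
    res_greater = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return RankSumResult(
        float(res_two.statistic),
        float(res_two.pvalue),
        float(res_less.pvalue),
        float(res_greater.pvalue),
        x.size,
        y.size,
    )


def obs_exp_interchrom(M: ContactMatrix) -> np.ndarray:
    """log2(observed/expected) inter-chromosome contact map (chrom x chrom).

    Expected contacts for a chromosome pair are proportional to the product of
    the two chromosomes' trans-marginal shares, normalized so total expected
    trans equals total observed trans; a perfectly uniform trans field gives a
    zero log-ratio everywhere.  Cells with zero expected are NaN.
    """
    layout = M.layout
    names = layout.chrom_names
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 chromosomes for inter-chromosome statistics")
    ci = layout.bin_chrom_index()
    mask = M.mask
    T = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            sub = M.matrix[np.ix_(mask & (ci == a), mask & (ci == b))]
            T[a, b] = T[b, a] = sub.sum()
    total = T.sum() / 2
    marg = T.sum(axis=1)
    share = marg / marg.sum()
    denom = sum(share[a] * share[b] for a in range(k) for b in range(a + 1, k))
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            exp = total * share[a] * share[b] / denom
            if exp > 0 and T[a, b] > 0:
                out[a, b] = np.log2(T[a, b] / exp)
    return out
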