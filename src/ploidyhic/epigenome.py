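"""Histone-mark quantification over bins and structure domains.

Covers projecting bedGraph coverage or peak intervals onto the bin grid,
per-category mark summaries and condition ratios, K-means noise removal within
domain labels, and interval-set Jaccard indices between mark peaks and domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .compare import RankSumResult, rank_sum_test
from .domains import CSD, LSD, MASKED, StructureDomainSet, TransitionMap
from .genome import GenomeLayout, GenomicInterval, build_bins

RATIO_EPS = 1e-6  # pseudocount for between-condition bin ratios


@dataclass
class SignalTrack:
    layout: GenomeLayout
    values: np.ndarray  # per-bin signal (RPKM-like)
    mark: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (self.layout.n_bins,):
            raise ValueError("track length must equal the number of bins")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite and non-negative")


def bin_signal(
    intervals: list[GenomicInterval],
    layout: GenomeLayout,
    mark: str = "",
    condition: str = "",
    library_size: float | None = None,
) -> SignalTrack:
    """Length-weighted mean coverage per bin from scored intervals (bedGraph).

    If ``library_size`` (mapped reads) is given, values are scaled to RPKM:
    value * 1e9 / (library_size * bin_length) would apply for raw read counts;
    here coverage is treated as read density, so the scale factor is
    1e6 / library_size.  Without it, raw length-weighted means are returned.
    """
    n = layout.n_bins
    acc = np.zeros(n)
    offsets = layout.chrom_offsets()
    lengths = layout.chrom_lengths
    for iv in intervals:
        if iv.chrom not in lengths:
            raise KeyError(f"unknown chromosome {iv.chrom!r} in signal interval")
        val = iv.score if iv.score is not None else 1.0
        if val < 0:
            raise ValueError(f"negative coverage at {iv.chrom}:{iv.start}-{iv.end}")
        off = offsets[iv.chrom]
        first = iv.start // layout.bin_size
        last = (min(iv.end, lengths[iv.chrom]) - 1) // layout.bin_size
        for b in range(first, last + 1):
            bs = b * layout.bin_size
            be = min(bs + layout.bin_size, lengths[iv.chrom])
            ov = min(iv.end, be) - max(iv.start, bs)
            if ov > 0:
                acc[off + b] += val * ov
    widths = np.array([b.end - b.start for b in build_bins(layout)], dtype=float)
    values = acc / widths
    if library_size is not None:
        values = values * 1e6 / library_size
    return SignalTrack(layout, values, mark=mark, condition=condition)


def read_bedgraph(path, layout: GenomeLayout, **kw) -> SignalTrack:
    """Read a 4-column bedGraph and project it onto the bin grid."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), score=float(r.value))
        for r in df.itertuples()
    ]
    return bin_signal(ivs, layout, **kw)


# -- domain summaries ------------------------------------------------------


def domain_mark_summary(
    track: SignalTrack, sd: StructureDomainSet
) -> dict[str, np.ndarray]:
    """Per-label (LSD/CSD) distributions of bin mark values."""
    out = {}
    for lab in (LSD, CSD):
        vals = track.values[sd.labels == lab]
        if vals.size == 0:
            warnings.warn(f"no bins labelled {lab}; category dropped")
            continue
        out[lab] = vals
    return out


def transition_ratio_summary(
    track_a: SignalTrack,
    track_b: SignalTrack,
    transitions: TransitionMap,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], RankSumResult]]:
    """Per-bin condition-B/condition-A mark ratios grouped by transition category.

    Returns the ratio distributions and rank-sum comparisons between each
    converted category and its unconverted counterpart (CSD->LSD vs CSD->CSD,
    LSD->CSD vs LSD->LSD).
    """
    ratios = (track_b.values + RATIO_EPS) / (track_a.values + RATIO_EPS)
    groups: dict[str, np.ndarray] = {}
    for cat in ("LSD->LSD", "CSD->CSD", "CSD->LSD", "LSD->CSD"):
        vals = ratios[transitions.categories == cat]
        if vals.size == 0:
            warnings.warn(f"no bins in transition category {cat}; dropped")
            continue
        groups[cat] = vals
    tests: dict[tuple[str, str], RankSumResult] = {}
    for conv, ref in (("CSD->LSD", "CSD->CSD"), ("LSD->CSD", "LSD->LSD")):
        if conv in groups and ref in groups:
            tests[(conv, ref)] = rank_sum_test(groups[conv], groups[ref])
    return groups, tests


def kmeans_denoise(
    track: SignalTrack,
    sd: StructureDomainSet,
    k: int = 10,
    seed: int = 0,
    n_init: int = 20,
) -> tuple[SignalTrack, np.ndarray]:
    """Zero out the lowest K-means cluster of bin values within each SD label.

    1-D K-means (k clusters) is fit separately on the LSD and the CSD bins;
    bins falling in the cluster with the lowest centroid are treated as noise
    and set to 0.  Returns the filtered track and per-bin cluster assignments
    (-1 for masked bins).
    """
    values = track.values.copy()
    assign = np.full(track.layout.n_bins, -1, dtype=int)
    for lab in (LSD, CSD):
        idx = np.where(sd.labels == lab)[0]
        if idx.size == 0:
            continue
        vals = track.values[idx]
        k_eff = min(k, np.unique(vals).size)
        if k_eff < k:
            warnings.warn(
                f"{lab}: only {np.unique(vals).size} distinct values; k reduced to {k_eff}"
            )
        if k_eff < 2:
            warnings.warn(f"{lab}: all values identical; noise rule skipped")
            assign[idx] = 0
            continue
        km = KMeans(n_clusters=k_eff, n_init=n_init, random_state=seed)
        lab_assign = km.fit_predict(vals.reshape(-1, 1))
        lowest = int(np.argmin(km.cluster_centers_.ravel()))
        values[idx[lab_assign == lowest]] = 0.0
        assign[idx] = lab_assign
    return SignalTrack(track.layout, values, mark=track.mark, condition=track.condition), assign


# -- interval Jaccard ------------------------------------------------------


def merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for iv in sorted(by_chrom[chrom], key=lambda v: (v.start, v.end)):
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def _total_bp(ivs: list[GenomicInterval]) -> int:
    return sum(iv.length for iv in ivs)


def _intersect_bp(a: list[GenomicInterval], b: list[GenomicInterval]) -> int:
    total = 0
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, []):
            total += max(0, min(iv.end, jv.end) - max(iv.start, jv.start))
    return total


def jaccard_mark_sd(
    peaks: list[GenomicInterval], sd_intervals: list[GenomicInterval]
) -> float:
    """Jaccard index (intersection bp / union bp) of two merged interval sets."""
    a = merge_intervals(peaks)
    b = merge_intervals(sd_intervals)
    if not a and not b:
        raise ValueError("both interval sets are empty; Jaccard undefined")
    inter = _intersect_bp(a, b)
    union = _total_bp(a) + _total_bp(b) - inter
    return inter / union if union else 0.0
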