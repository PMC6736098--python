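"""LSD/CSD structure-domain calling and between-condition transition maps.

Arabidopsis chromosome arms partition into loose (LSD) and compacted (CSD)
structure domains — the plant analogue of A/B compartments.  Per chromosome,
the balanced cis map is distance-normalized (observed/expected by diagonal),
converted to a Pearson correlation matrix, and the leading eigenvector of that
correlation matrix gives each bin a PC1 value.  The eigenvector sign is
intrinsically arbitrary, so it is oriented by positive correlation with an
activity track (gene density or H3K4me3); bins with PC1 > 0 are LSD, PC1 < 0
CSD.  Pericentromeric bins are excluded from the computation and stay masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import BALANCED, ContactMatrix
from .genome import PERICENTROMERE, GenomeLayout, build_bins

LSD = "LSD"
CSD = "CSD"
MASKED = "masked"

TRANSITIONS = ("LSD->LSD", "CSD->CSD", "CSD->LSD", "LSD->CSD")


@dataclass
class StructureDomainSet:
    layout: GenomeLayout
    pc1: np.ndarray  # per-bin PC1 value; 0 where masked
    labels: np.ndarray  # per-bin {LSD, CSD, masked}
    condition: str = ""
    orientation_mode: str = "track"


@dataclass
class TransitionMap:
    layout: GenomeLayout
    categories: np.ndarray  # per-bin transition label or "masked"
    percentages: dict[str, float]  # over bins unmasked in both conditions
    per_chromosome: pd.DataFrame  # chrom x category counts


def _oe_normalize(sub: np.ndarray) -> np.ndarray:
    """Divide each diagonal of a (contiguous) cis submatrix by its mean."""
    out = np.zeros_like(sub, dtype=float)
    m = sub.shape[0]
    for s in range(m):
        d = np.diag(sub, k=s)
        mu = d.mean()
        if mu > 0:
            vals = d / mu
            idx = np.arange(m - s)
            out[idx, idx + s] = vals
            out[idx + s, idx] = vals
    return out


def compartment_pc1(
    M: ContactMatrix,
    orientation_track: np.ndarray,
    condition: str = "",
    min_bins: int = 10,
) -> StructureDomainSet:
    """Call LSD/CSD labels from PC1 of the distance-normalized correlation map.

    ``orientation_track`` is a per-bin activity signal (gene density or an
    H3K4me3 track) used only to fix the eigenvector sign per chromosome so that
    positive PC1 means the active (loose) state.
    """
    if M.state != BALANCED:
        raise ValueError("compartment_pc1 expects a balanced matrix")
    layout = M.layout
    n = layout.n_bins
    orientation_track = np.asarray(orientation_track, dtype=float)
    if orientation_track.shape != (n,):
        raise ValueError("orientation track length must equal the number of bins")
    rc = np.array([b.region_class for b in build_bins(layout)])
    pc1 = np.zeros(n)
    offsets = layout.chrom_offsets()
    for chrom in layout.chrom_names:
        off = offsets[chrom]
        ids = np.arange(off, off + layout.n_bins_of(chrom))
        usable = M.mask[ids] & (rc[ids] != PERICENTROMERE)
        # O/E over the full chromosome grid keeps genomic distance meaningful,
        # then arms are concatenated for the correlation step
        oe = _oe_normalize(M.matrix[np.ix_(ids, ids)])
        keep = ids[usable] - off
        if keep.size < min_bins:
            warnings.warn(
                f"{chrom}: only {keep.size} usable arm bins (<{min_bins}); masked"
            )
            continue
        sub = oe[np.ix_(keep, keep)]
        sd = sub.std(axis=0)
        var_ok = sd > 0
        if var_ok.sum() < min_bins:
            warnings.warn(f"{chrom}: too few variable bins; masked")
            continue
        corr = np.corrcoef(sub[np.ix_(var_ok, var_ok)], rowvar=False)
        w, v = np.linalg.eigh(corr)
        vec = v[:, -1]  # leading eigenvector
        track = orientation_track[ids[usable][var_ok] + 0]
        if track.std() == 0:
            raise ValueError(f"{chrom}: zero-variance orientation track")
        r = np.corrcoef(vec, track)[0, 1]
        if r < 0:
            vec = -vec
        pc1[ids[usable][var_ok]] = vec
    labels = np.full(n, MASKED, dtype=object)
    labels[pc1 > 0] = LSD
    labels[pc1 < 0] = CSD
    return StructureDomainSet(layout, pc1, labels, condition=condition)


def classify_transitions(sd_a: StructureDomainSet, sd_b: StructureDomainSet) -> TransitionMap:
    """Four-way per-bin transition categories between two called conditions."""
    if sd_a.layout.n_bins != sd_b.layout.n_bins:
        raise ValueError("layout mismatch between conditions")
    n = sd_a.layout.n_bins
    cats = np.full(n, MASKED, dtype=object)
    both = (sd_a.labels != MASKED) & (sd_b.labels != MASKED)
    for i in np.where(both)[0]:
        cats[i] = f"{sd_a.labels[i]}->{sd_b.labels[i]}"
    total = int(both.sum())
    if total == 0:
        raise ValueError("no bins called in both conditions")
    percentages = {
        t: 100.0 * float((cats == t).sum()) / total for t in TRANSITIONS
    }
    ci = sd_a.layout.bin_chrom_index()
    rows = []
    for k, chrom in enumerate(sd_a.layout.chrom_names):
        row = {"chrom": chrom}
        for t in TRANSITIONS:
            row[t] = int(((cats == t) & (ci == k)).sum())
        rows.append(row)
    return TransitionMap(sd_a.layout, cats, percentages, pd.DataFrame(rows))


def domain_intervals(
    layout: GenomeLayout, labels: np.ndarray
) -> pd.DataFrame:
    """Merge maximal runs of identically labelled bins into intervals.

    Works for LSD/CSD label arrays and for transition-category arrays; masked
    bins break runs and are not reported.
    """
    bins = build_bins(layout)
    rows = []
    cur = None
    for b in bins:
        lab = labels[b.index]
        if cur is not None and (lab != cur["name"] or b.chrom != cur["chrom"]):
            rows.append(cur)
            cur = None
        if lab == MASKED:
            continue
        if cur is None:
            cur = {"chrom": b.chrom, "start": b.start, "end": b.end, "name": lab}
        else:
            cur["end"] = b.end
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def domain_interaction_levels(
    M: ContactMatrix, sd: StructureDomainSet
) -> dict[str, np.ndarray]:
    """Cis contact-value distributions for both-LSD, both-CSD and mixed bin pairs.

    The ``mixed`` distribution (one LSD and one CSD bin) is the natural
    baseline against which same-label (plaid) enrichment is tested.
    """
    layout = M.layout
    ci = layout.bin_chrom_index()
    out: dict[str, np.ndarray] = {}
    iu, ju = np.triu_indices(layout.n_bins, k=1)
    same = (ci[iu] == ci[ju]) & M.mask[iu] & M.mask[ju]
    for lab in (LSD, CSD):
        sel = same & (sd.labels[iu] == lab) & (sd.labels[ju] == lab)
        vals = M.matrix[iu[sel], ju[sel]]
        if vals.size == 0:
            raise ValueError(f"no cis bin pairs with both bins labelled {lab}")
        out[lab] = vals
    mix = same & (
        ((sd.labels[iu] == LSD) & (sd.labels[ju] == CSD))
        | ((sd.labels[iu] == CSD) & (sd.labels[ju] == LSD))
    )
    out["mixed"] = M.matrix[iu[mix], ju[mix]]
    return out
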