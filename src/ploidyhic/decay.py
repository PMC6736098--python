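"""Distance-decay curves and interaction decay exponents (IDEs).

The IDE is the slope of an ordinary least-squares fit of log10 mean contact
frequency against log10 genomic distance; it summarizes chromatin-fiber packing
for a region (whole genome cis, one chromosome, a pericentromere, or the pooled
telomeric ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMatrix
from .genome import PERICENTROMERE, GenomeLayout, build_bins, telomere_bins

DEFAULT_FIT_RANGE = (100_000, 10_000_000)  # bp; excludes the self-ligation diagonal


@dataclass
class DecayProfile:
    region: str
    distances: np.ndarray  # bp, strictly increasing (bin multiples)
    mean_frequency: np.ndarray
    n_pairs: np.ndarray
    fit_range: tuple[int, int] | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None


def _region_bin_groups(layout: GenomeLayout, region_spec: str) -> list[np.ndarray]:
    """Bin-id groups over which decay is averaged; pairs never cross groups."""
    bins = build_bins(layout)
    offsets = layout.chrom_offsets()
    if region_spec == "whole_genome_cis":
        return [
            np.arange(offsets[c], offsets[c] + layout.n_bins_of(c))
            for c in layout.chrom_names
        ]
    if region_spec.startswith("chromosome:"):
        c = region_spec.split(":", 1)[1]
        if c not in layout.chrom_lengths:
            raise KeyError(f"unknown chromosome {c!r}")
        return [np.arange(offsets[c], offsets[c] + layout.n_bins_of(c))]
    if region_spec.startswith("pericentromere:"):
        c = region_spec.split(":", 1)[1]
        ids = np.array(
            [b.index for b in bins if b.chrom == c and b.region_class == PERICENTROMERE],
            dtype=int,
        )
        return [ids]
    if region_spec == "telomeres":
        return [np.asarray(ids, dtype=int) for ids in telomere_bins(layout).values()]
    raise ValueError(f"unknown region_spec {region_spec!r}")


def decay_curve(M: ContactMatrix, region_spec: str) -> DecayProfile:
    """Mean balanced contact value at each genomic distance within a region.

    For distance s (in bins, s >= 1) the mean runs over all unmasked bin pairs
    (i, i+s) with both bins inside the region; regions with several parts
    (chromosomes, telomeric ends) contribute pairs within each part only.
    """
    layout = M.layout
    groups = _region_bin_groups(layout, region_spec)
    n_usable = sum(int(M.mask[g].sum()) for g in groups)
    if n_usable < 3:
        raise ValueError(f"region {region_spec!r} has fewer than 3 usable bins")
    max_s = max((g.max() - g.min()) for g in groups if g.size) if groups else 0
    sums = np.zeros(max_s + 1)
    counts = np.zeros(max_s + 1, dtype=np.int64)
    for g in groups:
        if g.size < 2:
            continue
        g = np.sort(g)
        sub = M.matrix[np.ix_(g, g)]
        ok = M.mask[g]
        m = g.size
        for s in range(1, m):
            d = np.diag(sub, k=s)
            keep = ok[:-s] & ok[s:]
            # genomic distance is the bin-id gap (contiguous grid within a part)
            gap = g[s:] - g[:-s]
            for gv in np.unique(gap[keep]):
                pick = keep & (gap == gv)
                sums[gv] += d[pick].sum()
                counts[gv] += int(pick.sum())
    s_vals = np.nonzero(counts)[0]
    if s_vals.size == 0:
        raise ValueError(f"no bin pairs at positive distance in region {region_spec!r}")
    return DecayProfile(
        region=region_spec,
        distances=s_vals * layout.bin_size,
        mean_frequency=sums[s_vals] / counts[s_vals],
        n_pairs=counts[s_vals],
    )


def fit_ide(
    profile: DecayProfile, fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
) -> DecayProfile:
    """OLS fit of log10(mean frequency) on log10(distance bp) inside ``fit_range``.

    Only strictly positive mean frequencies enter the fit; the slope is the IDE.
    Returns the profile with slope/intercept/R^2 filled in.
    """
    lo, hi = fit_range
    sel = (
        (profile.distances >= lo)
        & (profile.distances <= hi)
        & (profile.mean_frequency > 0)
    )
    if sel.sum() < 3:
        raise ValueError(
            f"fewer than 3 positive points in fit range {fit_range} "
            f"for region {profile.region!r}"
        )
    x = np.log10(profile.distances[sel].astype(float))
    y = np.log10(profile.mean_frequency[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    profile.fit_range = (lo, hi)
    profile.slope = float(slope)
    profile.intercept = float(intercept)
    profile.r_squared = r2
    return profile
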