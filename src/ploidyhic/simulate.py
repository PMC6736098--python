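"""Two-condition synthetic cohort generator.

Emulates the statistical structure the comparative analysis assumes, for a
diploid-like condition and a genome-doubled (tetraploid-like) condition sharing
one reference layout:

* cis contacts with power-law distance decay (condition-specific exponent),
* plaid compartment structure of loose (LSD, sign +1) and compacted (CSD, -1)
  domains, with a fraction of arm bins flipped in the doubled condition,
* uniform trans background, higher in the doubled condition,
* extra "relocated" bins in the doubled condition whose contacts shift from cis
  to trans (a block/shape effect that survives matrix balancing, unlike any
  pure per-bin scaling),
* a mild pairwise boost of LSD-LSD contacts in the doubled condition (elevated
  regulatory-element contacts),
* histone tracks anti-correlated between domains (H3K4me3 high in LSD,
  H3K27me3 high in CSD), following each condition's own domain profile,
* genes placed preferentially in LSD bins, expression higher in LSD, and DE
  genes planted in "intended-differential" bins at a controllable fraction.

The flipped plus relocated bins form the generator's intended-differential
ground truth, recorded in the manifest; the observational study this emulates
has no such ground truth, so the simulator must carry its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactMatrix, write_triplets
from .epigenome import SignalTrack
from .genome import (
    ARM_LEFT,
    ARM_RIGHT,
    PERICENTROMERE,
    GenomeLayout,
    GenomicInterval,
    build_bins,
)

DIPLOID = "diploid"
TETRAPLOID = "tetraploid"
CONDITIONS = (DIPLOID, TETRAPLOID)
MARKS = ("H3K4me3", "H3K27me3")

# rng stream ids (mixed with the user seed)
_STREAM_CONTACTS = {DIPLOID: 0, TETRAPLOID: 1}
_STREAM_TRACKS = 2
_STREAM_GENES = 3
_STREAM_ENHANCERS = 4
_STREAM_STRUCTURE = 5


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the studied contrast.

    The doubled condition decays faster with distance (steeper IDE), has a
    higher trans background, 10% of arm bins flipped between LSD and CSD, and
    743 DE genes of which 72.5% fall in intended-differential bins with a
    436:307 up:down split.
    """

    n_chromosomes: int = 3
    chrom_length: int = 6_000_000
    bin_size: int = 50_000
    pericentromere_fraction: float = 1 / 6  # central heterochromatic block
    telomere_fraction: float = 0.05
    decay_exponent: dict[str, float] = field(
        default_factory=lambda: {DIPLOID: 0.8, TETRAPLOID: 1.0}
    )
    plaid_strength: float = 0.4
    trans_level: dict[str, float] = field(
        default_factory=lambda: {DIPLOID: 0.8, TETRAPLOID: 1.2}
    )
    sequencing_depth: float = 200.0
    compartment_block_bins: int = 10
    flip_fraction: float = 0.10  # of arm bins, flipped in the doubled condition
    differential_bin_fraction: float = 0.25  # of all bins: flips + relocated
    relocation_factor: float = 2.0  # cis/trans redistribution of relocated bins
    lsd_pair_boost: float = 1.2  # LSD-LSD pairwise boost in the doubled condition
    mark_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "H3K4me3": {"LSD": 8.0, "CSD": 2.0},
            "H3K27me3": {"LSD": 2.0, "CSD": 8.0},
        }
    )
    mark_noise_sd: float = 1.0
    peak_threshold: float = 5.0
    n_genes: int = 7430
    de_fraction: float = 0.1  # 743 DE genes at the default n_genes
    de_in_differential_fraction: float | None = 0.725  # None = uniform placement
    up_fraction: float = 436 / 743
    gene_weight_lsd: float = 3.0
    gene_weight_csd: float = 1.0
    gene_weight_peri: float = 0.15
    expr_log2_mean: dict[str, float] = field(
        default_factory=lambda: {"LSD": 5.0, "CSD": 3.0}
    )
    expr_log2_sd: float = 1.0
    n_enhancers: int = 600
    enhancer_length: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if self.decay_exponent[cond] <= 0:
                raise ValueError("decay exponents must be positive")
            if self.trans_level[cond] < 0:
                raise ValueError("trans level must be non-negative")
        if not (0 <= self.plaid_strength < 1):
            raise ValueError("plaid_strength must be in [0, 1)")
        for frac in (self.flip_fraction, self.de_fraction, self.up_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.de_in_differential_fraction is not None and not (
            0 <= self.de_in_differential_fraction <= 1
        ):
            raise ValueError("de_in_differential_fraction must be in [0, 1] or None")


@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    layout: GenomeLayout
    profiles: dict[str, np.ndarray]  # per-condition per-bin sign (+1 LSD / -1 CSD)
    flip_bins: np.ndarray
    relocated_bins: np.ndarray
    intended_differential: np.ndarray  # boolean per bin
    contacts: dict[str, ContactMatrix]
    tracks: dict[tuple[str, str], SignalTrack]  # (mark, condition)
    peaks: dict[tuple[str, str], list[GenomicInterval]]
    genes: pd.DataFrame
    enhancers: list[GenomicInterval]

    @property
    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.cfg)
        return {
            "config": cfg,
            "rng_seed": self.cfg.rng_seed,
            "flip_bins": [int(b) for b in self.flip_bins],
            "relocated_bins": [int(b) for b in self.relocated_bins],
            "intended_differential_bins": [
                int(b) for b in np.where(self.intended_differential)[0]
            ],
            "profiles": {c: [int(s) for s in p] for c, p in self.profiles.items()},
        }


def make_layout(cfg: SimulationConfig) -> GenomeLayout:
    """Layout with equal-length chromosomes and central pericentromeres."""
    chroms = [(f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chromosomes)]
    peri = {}
    for name, length in chroms:
        half = cfg.pericentromere_fraction * length / 2
        # snap to the bin grid so pericentromeric bins are unambiguous
        s = int(round((length / 2 - half) / cfg.bin_size)) * cfg.bin_size
        e = int(round((length / 2 + half) / cfg.bin_size)) * cfg.bin_size
        if s < e:  # too-short chromosomes get no pericentromere block
            peri[name] = (s, e)
    return GenomeLayout(
        chromosomes=chroms,
        bin_size=cfg.bin_size,
        pericentromeres=peri,
        telomere_fraction=cfg.telomere_fraction,
    )


def _arm_runs(layout: GenomeLayout) -> list[np.ndarray]:
    """Contiguous arm-bin id runs (one per chromosome arm)."""
    runs = []
    bins = build_bins(layout)
    for chrom in layout.chrom_names:
        for arm in (ARM_LEFT, ARM_RIGHT):
            ids = np.array(
                [b.index for b in bins if b.chrom == chrom and b.region_class == arm],
                dtype=int,
            )
            if ids.size:
                runs.append(ids)
    return runs


def compartment_profiles(
    cfg: SimulationConfig, layout: GenomeLayout
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Intended per-bin signs per condition plus the flipped-bin ids.

    The diploid profile alternates plaid blocks (+1 first) along each arm;
    pericentromeric bins are always -1 (compacted).  The doubled condition
    flips randomly chosen plaid blocks (trimmed to hit the target bin count).
    """
    n = layout.n_bins
    prof_a = np.full(n, -1, dtype=int)
    blocks: list[np.ndarray] = []
    for run in _arm_runs(layout):
        for k, s in enumerate(range(0, run.size, cfg.compartment_block_bins)):
            block = run[s : s + cfg.compartment_block_bins]
            prof_a[block] = 1 if k % 2 == 0 else -1
            blocks.append(block)
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_STRUCTURE])
    n_arm = sum(b.size for b in blocks)
    target = int(round(cfg.flip_fraction * n_arm))
    order = rng.permutation(len(blocks))
    flip: list[int] = []
    for bi in order:
        if len(flip) >= target:
            break
        take = min(blocks[bi].size, target - len(flip))
        flip.extend(blocks[bi][:take])
    flip_bins = np.array(sorted(flip), dtype=int)
    prof_b = prof_a.copy()
    prof_b[flip_bins] *= -1
    return {DIPLOID: prof_a, TETRAPLOID: prof_b}, flip_bins


def differential_ground_truth(
    cfg: SimulationConfig, layout: GenomeLayout, flip_bins: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Relocated-bin ids and the combined intended-differential flag vector."""
    n = layout.n_bins
    rc = np.array([b.region_class for b in build_bins(layout)])
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_STRUCTURE, 1])
    target_total = int(round(cfg.differential_bin_fraction * n))
    candidates = np.setdiff1d(np.where(rc != PERICENTROMERE)[0], flip_bins)
    n_extra = max(0, target_total - flip_bins.size)
    relocated = np.sort(rng.choice(candidates, size=min(n_extra, candidates.size),
                                   replace=False))
    flags = np.zeros(n, dtype=bool)
    flags[flip_bins] = True
    flags[relocated] = True
    return relocated, flags


def expected_contacts(
    cfg: SimulationConfig,
    layout: GenomeLayout,
    condition: str,
    profiles: dict[str, np.ndarray],
    relocated_bins: np.ndarray,
) -> np.ndarray:
    """Generative expected-count matrix (no sampling noise)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n = layout.n_bins
    sign = profiles[condition]
    alpha = cfg.decay_exponent[condition]
    N = cfg.sequencing_depth
    delta = cfg.plaid_strength
    ci = layout.bin_chrom_index()
    same_chrom = ci[:, None] == ci[None, :]
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)  # bin distance within chrom
    plaid = 1.0 + delta * (sign[:, None] * sign[None, :])
    E = np.where(same_chrom, 0.0, cfg.trans_level[condition])
    with np.errstate(divide="ignore"):
        decay = np.where(s >= 1, s ** (-alpha), 1.0)
    E = np.where(same_chrom, N * decay * plaid, E)
    if condition == TETRAPLOID:
        reloc = np.zeros(n, dtype=bool)
        reloc[relocated_bins] = True
        f = cfg.relocation_factor
        cis_scale = np.ones((n, n))
        trans_scale = np.ones((n, n))
        cis_scale[reloc, :] /= f
        cis_scale[:, reloc] /= f
        trans_scale[reloc, :] *= f
        trans_scale[:, reloc] *= f
        E = np.where(same_chrom, E * cis_scale, E * trans_scale)
        lsd = sign > 0
        boost = np.where(lsd[:, None] & lsd[None, :], cfg.lsd_pair_boost, 1.0)
        E = E * boost
    return E


def simulate_contacts(
    cfg: SimulationConfig,
    condition: str,
    layout: GenomeLayout | None = None,
    profiles: dict[str, np.ndarray] | None = None,
    relocated_bins: np.ndarray | None = None,
    expectation_mode: bool = False,
) -> ContactMatrix:
    """Poisson-sampled (or expectation-mode) contact map for one condition."""
    if layout is None:
        layout = make_layout(cfg)
    if profiles is None:
        profiles, flip_bins = compartment_profiles(cfg, layout)
        if relocated_bins is None:
            relocated_bins, _ = differential_ground_truth(cfg, layout, flip_bins)
    if relocated_bins is None:
        relocated_bins = np.array([], dtype=int)
    E = expected_contacts(cfg, layout, condition, profiles, relocated_bins)
    if expectation_mode:
        return ContactMatrix(layout, E)
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_CONTACTS[condition]])
    n = layout.n_bins
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(E[iu, ju]).astype(float)
    M = np.zeros((n, n))
    M[iu, ju] = counts
    M[ju, iu] = counts
    return ContactMatrix(layout, M)


# -- tracks, peaks, genes, enhancers --------------------------------------


def _label_of(sign: np.ndarray) -> np.ndarray:
    return np.where(sign > 0, "LSD", "CSD")


def simulate_tracks(
    cfg: SimulationConfig, layout: GenomeLayout, profiles: dict[str, np.ndarray]
) -> tuple[dict[tuple[str, str], SignalTrack], dict[tuple[str, str], list[GenomicInterval]]]:
    """Per-bin mark signal and threshold-called peak intervals per condition."""
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_TRACKS])
    bins = build_bins(layout)
    tracks: dict[tuple[str, str], SignalTrack] = {}
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {}
    for mark in MARKS:
        for cond in CONDITIONS:
            labels = _label_of(profiles[cond])
            mean = np.array([cfg.mark_means[mark][l] for l in labels])
            vals = np.clip(mean + rng.normal(0, cfg.mark_noise_sd, layout.n_bins), 0, None)
            tracks[(mark, cond)] = SignalTrack(layout, vals, mark=mark, condition=cond)
            hot = vals > cfg.peak_threshold
            ivs: list[GenomicInterval] = []
            cur = None
            for b in bins:
                if hot[b.index]:
                    if cur is not None and cur.chrom == b.chrom and cur.end == b.start:
                        cur = GenomicInterval(cur.chrom, cur.start, b.end)
                    else:
                        if cur is not None:
                            ivs.append(cur)
                        cur = GenomicInterval(b.chrom, b.start, b.end)
                elif cur is not None:
                    ivs.append(cur)
                    cur = None
            if cur is not None:
                ivs.append(cur)
            peaks[(mark, cond)] = ivs
    return tracks, peaks


def _bin_weights(cfg: SimulationConfig, layout: GenomeLayout, sign: np.ndarray) -> np.ndarray:
    rc = np.array([b.region_class for b in build_bins(layout)])
    w = np.where(sign > 0, cfg.gene_weight_lsd, cfg.gene_weight_csd)
    w = np.where(rc == PERICENTROMERE, cfg.gene_weight_peri, w)
    return w / w.sum()


def simulate_genes(
    cfg: SimulationConfig,
    layout: GenomeLayout,
    profiles: dict[str, np.ndarray],
    intended_differential: np.ndarray,
) -> pd.DataFrame:
    """Gene table with TSS, category, expression per condition and DE status.

    DE genes are planted so that (when ``de_in_differential_fraction`` is set)
    an exact rounded count of them falls in intended-differential bins; DE
    directions are assigned to the target up:down split, preferring up in
    CSD->LSD flip bins and down in LSD->CSD flip bins.
    """
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_GENES])
    n = layout.n_bins
    bins = build_bins(layout)
    widths = np.array([b.end - b.start for b in bins])
    starts = np.array([b.start for b in bins])
    chrom_of = np.array([b.chrom for b in bins])
    n_genes = cfg.n_genes
    n_de = int(round(cfg.de_fraction * n_genes))
    w_all = _bin_weights(cfg, layout, profiles[DIPLOID])

    gene_bins = np.empty(n_genes, dtype=int)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[:n_de] = True
    if cfg.de_in_differential_fraction is None:
        gene_bins[:] = rng.choice(n, size=n_genes, p=w_all)
    else:
        k_in = int(round(cfg.de_in_differential_fraction * n_de))
        diff_ids = np.where(intended_differential)[0]
        other_ids = np.where(~intended_differential)[0]
        w_diff = w_all[diff_ids] / w_all[diff_ids].sum()
        w_other = w_all[other_ids] / w_all[other_ids].sum()
        gene_bins[:k_in] = rng.choice(diff_ids, size=k_in, p=w_diff)
        gene_bins[k_in:n_de] = rng.choice(other_ids, size=n_de - k_in, p=w_other)
        gene_bins[n_de:] = rng.choice(n, size=n_genes - n_de, p=w_all)

    tss = starts[gene_bins] + rng.integers(0, widths[gene_bins])
    # keep promoters inside the chromosome
    tss = np.maximum(tss, 2001)
    strand = rng.choice(["+", "-"], size=n_genes)
    category = rng.choice(
        ["coding", "non-coding", "pseudogene"], size=n_genes, p=[0.83, 0.147, 0.023]
    )

    sign_a, sign_b = profiles[DIPLOID], profiles[TETRAPLOID]
    lab_a = _label_of(sign_a)[gene_bins]
    expr_mu = np.array([cfg.expr_log2_mean[l] for l in lab_a])
    log2_expr_a = rng.normal(expr_mu, cfg.expr_log2_sd)

    # DE directions: exact split, flip-driven where possible
    n_up = int(round(cfg.up_fraction * n_de))
    de_idx = np.where(is_de)[0]
    transition = np.where(
        (sign_a[gene_bins] < 0) & (sign_b[gene_bins] > 0), "CSD->LSD",
        np.where((sign_a[gene_bins] > 0) & (sign_b[gene_bins] < 0), "LSD->CSD", "same"),
    )
    up = np.zeros(n_genes, dtype=bool)
    csd_to_lsd = [i for i in de_idx if transition[i] == "CSD->LSD"]
    lsd_to_csd = [i for i in de_idx if transition[i] == "LSD->CSD"]
    rest = [i for i in de_idx if transition[i] == "same"]
    rng.shuffle(rest)
    chosen_up = list(csd_to_lsd)[: n_up]
    need = n_up - len(chosen_up)
    if need > 0:
        chosen_up += rest[:need]
    up[np.array(chosen_up, dtype=int)] = True
    # anything not up among DE is down (includes the LSD->CSD planted genes)
    del lsd_to_csd

    log2fc = rng.normal(0.0, 0.3, n_genes).clip(-0.95, 0.95)
    mag = 1.0 + rng.exponential(0.8, n_genes)
    log2fc[is_de & up] = mag[is_de & up]
    log2fc[is_de & ~up] = -mag[is_de & ~up]
    de_status = np.where(is_de & up, "up", np.where(is_de, "down", "none"))

    padj = rng.uniform(0.06, 1.0, n_genes)
    padj[is_de] = rng.uniform(1e-8, 1e-3, n_genes)[is_de]
    expr_a = 2.0 ** log2_expr_a
    expr_b = expr_a * 2.0 ** log2fc

    df = pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "chrom": chrom_of[gene_bins],
            "tss": tss.astype(int),
            "strand": strand,
            "category": category,
            "expr_a": expr_a,
            "expr_b": expr_b,
            "log2fc": log2fc,
            "de_status": de_status,
            "pvalue": padj,  # synthetic table: raw p and padj coincide
            "padj": padj,
        }
    )
    return df.sample(frac=1.0, random_state=cfg.rng_seed).reset_index(drop=True)


def simulate_enhancers(
    cfg: SimulationConfig, layout: GenomeLayout, profiles: dict[str, np.ndarray]
) -> list[GenomicInterval]:
    """Short candidate-enhancer intervals, denser in LSD bins."""
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_ENHANCERS])
    bins = build_bins(layout)
    w = _bin_weights(cfg, layout, profiles[DIPLOID])
    chosen = rng.choice(layout.n_bins, size=cfg.n_enhancers, p=w)
    out = []
    for k, b in enumerate(chosen):
        width = bins[b].end - bins[b].start
        off = int(rng.integers(0, max(1, width - cfg.enhancer_length)))
        s = bins[b].start + off
        out.append(
            GenomicInterval(bins[b].chrom, s, s + cfg.enhancer_length, name=f"E{k:04d}")
        )
    return out


def gene_density_track(genes: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Genes-per-bin track (TSS counts), the default PC1 orientation evidence."""
    counts = np.zeros(layout.n_bins)
    for row in genes.itertuples():
        counts[layout.bin_index(row.chrom, int(row.tss))] += 1
    return counts


def generate(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the complete two-condition dataset in memory."""
    layout = make_layout(cfg)
    profiles, flip_bins = compartment_profiles(cfg, layout)
    relocated, intended = differential_ground_truth(cfg, layout, flip_bins)
    contacts = {
        cond: simulate_contacts(cfg, cond, layout, profiles, relocated)
        for cond in CONDITIONS
    }
    tracks, peaks = simulate_tracks(cfg, layout, profiles)
    genes = simulate_genes(cfg, layout, profiles, intended)
    enhancers = simulate_enhancers(cfg, layout, profiles)
    return SyntheticDataset(
        cfg, layout, profiles, flip_bins, relocated, intended,
        contacts, tracks, peaks, genes, enhancers,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every artifact (triplets, bedGraph, BEDs, TSVs) plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "chrom.sizes", "w") as fh:
        for name, length in ds.layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(outdir / "pericentromeres.bed", "w") as fh:
        for name, (s, e) in ds.layout.pericentromeres.items():
            fh.write(f"{name}\t{s}\t{e}\n")
    for cond, cm in ds.contacts.items():
        write_triplets(cm, outdir / f"contacts_{cond}.tsv")
    bins = build_bins(ds.layout)
    for (mark, cond), track in ds.tracks.items():
        with open(outdir / f"{mark}_{cond}.bedgraph", "w") as fh:
            for b in bins:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{track.values[b.index]:.6g}\n")
    for (mark, cond), ivs in ds.peaks.items():
        with open(outdir / f"{mark}_{cond}_peaks.bed", "w") as fh:
            for iv in ivs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    ds.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    with open(outdir / "enhancers.bed", "w") as fh:
        for iv in ds.enhancers:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(ds.manifest, fh, indent=1, sort_keys=True)
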