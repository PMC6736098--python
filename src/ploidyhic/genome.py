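"""Genome coordinate system: chromosomes, fixed-width bin grid and genomic partitions.

Everything downstream (contact matrices, signal tracks, gene tables) is keyed to
the bin grid defined here.  Coordinates are 0-based half-open (BED convention)
throughout the package; 1-based inputs must be converted at the reader boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ARM_LEFT = "arm_left"
ARM_RIGHT = "arm_right"
PERICENTROMERE = "pericentromere"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named/categorised."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    category: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bin:
    chrom: str
    index: int  # genome-wide id, consecutive in chromosome order
    start: int
    end: int
    region_class: str  # arm_left | arm_right | pericentromere


@dataclass
class GenomeLayout:
    """Chromosome sizes, pericentromere partition and the shared bin grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Width of the fixed bin grid in bp (last bin of a chromosome may be short).
    pericentromeres
        Per-chromosome ``(start, end)`` interval in bp.  Chromosomes without an
        entry are treated as all-arm (with a warning at bin build time).
    telomere_fraction
        Fraction of each chromosome end treated as telomeric.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int = 50_000
    pericentromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    telomere_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not (0.0 < self.telomere_fraction < 0.5):
            raise ValueError("telomere_fraction must be in (0, 0.5)")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for chrom, (s, e) in self.pericentromeres.items():
            length = dict(self.chromosomes).get(chrom)
            if length is None:
                raise ValueError(f"pericentromere for unknown chromosome {chrom!r}")
            if not (0 <= s < e <= length):
                raise ValueError(
                    f"pericentromere {chrom}:{s}-{e} outside chromosome (len {length})"
                )

    # -- derived grids -----------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_bins_of(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.bin_size)  # ceil division

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chrom_names)

    def chrom_offsets(self) -> dict[str, int]:
        """Genome-wide index of the first bin of each chromosome."""
        offsets, acc = {}, 0
        for name, _ in self.chromosomes:
            offsets[name] = acc
            acc += self.n_bins_of(name)
        return offsets

    def bin_index(self, chrom: str, pos: int) -> int:
        """Genome-wide id of the bin containing position ``pos`` (0-based)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self.chrom_offsets()[chrom] + pos // self.bin_size

    def bin_chrom_index(self) -> np.ndarray:
        """Per-bin integer chromosome id (order of ``self.chromosomes``)."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for ci, name in enumerate(self.chrom_names):
            off = self.chrom_offsets()[name]
            out[off : off + self.n_bins_of(name)] = ci
        return out


def build_bins(layout: GenomeLayout) -> list[Bin]:
    """Tile each chromosome into consecutive bins and label genomic partitions.

    A bin is labelled pericentromeric when more than half of its length overlaps
    the chromosome's pericentromere interval; other bins are labelled by which
    side of the pericentromere midpoint they fall on.  Chromosomes without a
    pericentromere entry get all-arm (``arm_left``) bins and a warning.
    """
    bins: list[Bin] = []
    idx = 0
    for chrom, length in layout.chromosomes:
        peri = layout.pericentromeres.get(chrom)
        if peri is None:
            warnings.warn(
                f"no pericentromere defined for {chrom}; all bins treated as arm bins"
            )
        for start in range(0, length, layout.bin_size):
            end = min(start + layout.bin_size, length)
            if peri is None:
                cls = ARM_LEFT
            else:
                ps, pe = peri
                overlap = max(0, min(end, pe) - max(start, ps))
                if overlap * 2 > (end - start):
                    cls = PERICENTROMERE
                else:
                    mid = (ps + pe) / 2
                    cls = ARM_LEFT if (start + end) / 2 < mid else ARM_RIGHT
            bins.append(Bin(chrom, idx, start, end, cls))
            idx += 1
    widths = {}
    for b in bins:
        widths[b.chrom] = widths.get(b.chrom, 0) + (b.end - b.start)
    assert widths == layout.chrom_lengths, "bin tiling does not partition the genome"
    return bins


def bins_frame(layout: GenomeLayout) -> pd.DataFrame:
    """Bin table as a DataFrame (chrom, start, end, index, region_class)."""
    bins = build_bins(layout)
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "index": [b.index for b in bins],
            "region_class": [b.region_class for b in bins],
        }
    )


def interval_to_bins(iv: GenomicInterval, layout: GenomeLayout) -> list[int]:
    """Genome-wide ids of all bins overlapping ``iv`` by at least 1 bp."""
    if iv.chrom not in layout.chrom_lengths:
        raise KeyError(f"unknown chromosome {iv.chrom!r} in interval")
    length = layout.chrom_lengths[iv.chrom]
    if not (0 <= iv.start < iv.end <= length):
        raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome")
    off = layout.chrom_offsets()[iv.chrom]
    first = iv.start // layout.bin_size
    last = (iv.end - 1) // layout.bin_size  # end is exclusive
    return [off + b for b in range(first, last + 1)]


def telomere_bins(layout: GenomeLayout) -> dict[tuple[str, str], list[int]]:
    """Bins overlapping the telomeric fraction of each chromosome end.

    Returns a mapping ``(chrom, "left"|"right") -> bin ids``.
    """
    out: dict[tuple[str, str], list[int]] = {}
    for chrom, length in layout.chromosomes:
        t = layout.telomere_fraction * length
        left = GenomicInterval(chrom, 0, int(np.ceil(t)))
        right = GenomicInterval(chrom, int(np.floor(length - t)), length)
        out[(chrom, "left")] = interval_to_bins(left, layout)
        out[(chrom, "right")] = interval_to_bins(right, layout)
    return out


# -- readers ---------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column chrom.sizes TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], usecols=[0, 1])
    return list(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into GenomicInterval records (name/score kept if present)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            ivs.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name=name,
                                score=score)
            )
    return ivs


def layout_from_files(
    chrom_sizes: str | Path,
    pericentromere_bed: str | Path | None = None,
    bin_size: int = 50_000,
    telomere_fraction: float = 0.05,
) -> GenomeLayout:
    """Build a GenomeLayout from a chrom.sizes file and optional pericentromere BED."""
    peri: dict[str, tuple[int, int]] = {}
    if pericentromere_bed is not None:
        for iv in read_bed(pericentromere_bed):
            peri[iv.chrom] = (iv.start, iv.end)
    return GenomeLayout(
        chromosomes=read_chrom_sizes(chrom_sizes),
        bin_size=bin_size,
        pericentromeres=peri,
        telomere_fraction=telomere_fraction,
    )
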