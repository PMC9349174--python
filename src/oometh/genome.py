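"""Coordinate frame shared by all analysis stages.

A :class:`GenomeLayout` names the chromosomes (with an autosome / chrX
class per chromosome), :func:`make_bin_grid` tiles each chromosome with
fixed-size bins (10 kb by default downstream), and genes / SNPs are thin
record types layered on the same coordinates.

All coordinates are 0-based half-open internally; 1-based conventions are
handled only at file boundaries (see :mod:`oometh.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

AUTOSOME = "autosome"
CHRX = "chrX"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    klass: str = AUTOSOME  # AUTOSOME or CHRX

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length")
        if self.klass not in (AUTOSOME, CHRX):
            raise ValueError(f"unknown chromosome class {self.klass!r}")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and autosome/X class."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("empty genome layout")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        n_x = sum(c.klass == CHRX for c in self.chromosomes)
        n_auto = sum(c.klass == AUTOSOME for c in self.chromosomes)
        if n_auto < 1:
            raise ValueError("layout needs at least one autosome")
        if n_x > 1:
            raise ValueError("layout admits at most one chrX")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def class_of(self, chrom: str) -> str:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.klass
        raise KeyError(f"unknown chromosome {chrom!r}")

    @classmethod
    def from_lengths(
        cls, lengths: dict[str, int], x_names: Sequence[str] = ("chrX", "X")
    ) -> "GenomeLayout":
        chroms = tuple(
            Chromosome(n, int(l), CHRX if n in x_names else AUTOSOME)
            for n, l in lengths.items()
        )
        return cls(chroms)


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int
    end: int
    index: int  # ordinal within chromosome

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    maternal_allele: str
    paternal_allele: str
    shared_with_third_strain: bool = False

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(f"SNP at {self.chrom}:{self.pos} is not polymorphic")


class BinGrid:
    """Fixed-size tiling of a :class:`GenomeLayout`.

    Bins are ordered by (chromosome order, start); the terminal bin of each
    chromosome is truncated to the chromosome end and kept.  The grid is
    exposed both as an iterable of :class:`GenomicBin` and as a DataFrame
    (``.df`` with columns chrom/start/end/index/klass) for vectorized work.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.layout = layout
        self.bin_size = int(bin_size)
        chroms, starts, ends, idxs, klasses = [], [], [], [], []
        offsets: dict[str, int] = {}
        off = 0
        for c in layout.chromosomes:
            n = -(-c.length // self.bin_size)  # ceil division
            offsets[c.name] = off
            s = np.arange(n, dtype=np.int64) * self.bin_size
            e = np.minimum(s + self.bin_size, c.length)
            chroms.append(np.full(n, c.name, dtype=object))
            starts.append(s)
            ends.append(e)
            idxs.append(np.arange(n, dtype=np.int64))
            klasses.append(np.full(n, c.klass, dtype=object))
            off += n
        self._offsets = offsets
        self.df = pd.DataFrame(
            {
                "chrom": np.concatenate(chroms),
                "start": np.concatenate(starts),
                "end": np.concatenate(ends),
                "index": np.concatenate(idxs),
                "klass": np.concatenate(klasses),
            }
        )

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def klass(self) -> np.ndarray:
        return self.df["klass"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def __len__(self) -> int:
        return self.n_bins

    def __iter__(self) -> Iterator[GenomicBin]:
        for row in self.df.itertuples(index=False):
            yield GenomicBin(row.chrom, int(row.start), int(row.end), int(row.index))

    def bin_at(self, i: int) -> GenomicBin:
        row = self.df.iloc[i]
        return GenomicBin(row["chrom"], int(row["start"]), int(row["end"]), int(row["index"]))

    def locate_index(self, chrom: str, pos: int) -> int:
        """Global row index of the bin containing ``pos`` (0-based)."""
        length = self.layout.length_of(chrom)  # KeyError for unknown chrom
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        return self._offsets[chrom] + pos // self.bin_size

    def locate_indices(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        length = self.layout.length_of(chrom)
        pos = np.asarray(pos)
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"positions outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def overlapping_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of all bins overlapping [start, end) by >= 1 bp."""
        length = self.layout.length_of(chrom)
        start = max(0, int(start))
        end = min(int(end), length)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        first = start // self.bin_size
        last = (end - 1) // self.bin_size
        off = self._offsets[chrom]
        return np.arange(off + first, off + last + 1, dtype=np.int64)


def make_bin_grid(layout: GenomeLayout, bin_size: int) -> BinGrid:
    """Tile every chromosome with ``bin_size`` bins (terminal bin truncated)."""
    return BinGrid(layout, bin_size)


def locate_bin(grid: BinGrid, chrom: str, pos: int) -> GenomicBin:
    """The unique bin with start <= pos < end."""
    return grid.bin_at(grid.locate_index(chrom, pos))


def gene_body_bins(grid: BinGrid, gene: GeneAnnotation) -> list[GenomicBin]:
    """All bins overlapping the gene body [start, end); 1 bp overlap counts."""
    if gene.chrom not in grid.layout.names:
        raise KeyError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom!r}")
    idx = grid.overlapping_indices(gene.chrom, gene.start, gene.end)
    return [grid.bin_at(int(i)) for i in idx]
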