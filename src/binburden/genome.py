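"""Fixed-width genome binning.

The coordinate system for all burden features is a partition of the
autosomes into ~5-Mb windows ("bins"). Each chromosome of length L is cut
into ceil(L / bin_size) closed 1-based intervals; the last bin on a
chromosome is shorter when L is not a multiple of the bin size. Bins carry
a dense global ordinal (0..N-1) in (chromosome order, start) order, which
is the feature index used everywhere downstream. For GRCh38 autosomes at
5 Mb this yields 587 bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GRCH38_AUTOSOMES",
    "GenomeBuild",
    "GenomicBin",
    "GenomicBinIndex",
    "UnmappablePosition",
    "build_bins",
    "normalize_chrom",
]

#: GRCh38 (hg38) autosome lengths in bp, primary assembly.
GRCH38_AUTOSOMES: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
}

DEFAULT_BIN_SIZE = 5_000_000


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name to the ``chr``-prefixed form.

    ``"1"`` and ``"chr1"`` are equivalent on input.
    """
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


class UnmappablePosition(KeyError):
    """A (chrom, pos) pair that falls outside the genome build."""


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths (bp)."""

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome name")
        for name in self.names:
            length = self.lengths.get(name)
            if length is None:
                raise ValueError(f"no length for chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")

    @classmethod
    def grch38(cls) -> "GenomeBuild":
        """The 22 GRCh38 autosomes."""
        return cls(tuple(GRCH38_AUTOSOMES), dict(GRCH38_AUTOSOMES))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeBuild":
        names: list[str] = []
        lengths: dict[str, int] = {}
        for raw_name, length in pairs:
            name = normalize_chrom(raw_name)
            if name in lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            names.append(name)
            lengths[name] = int(length)
        return cls(tuple(names), lengths)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeBuild":
        """Read a two-column TSV (name, length) as emitted by faidx etc."""
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0], int(fields[1])))
        return cls.from_pairs(pairs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class GenomicBin:
    """One window: 1-based closed interval plus its global feature ordinal."""

    chrom: str
    start: int
    end: int
    ordinal: int

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenomicBinIndex:
    """The full ordered bin partition of a genome build."""

    genome: GenomeBuild
    bin_size: int
    bins: list[GenomicBin]
    _offsets: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._offsets:
            for b in self.bins:
                self._offsets.setdefault(b.chrom, b.ordinal)

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def locate(self, chrom: str, pos: int) -> int:
        """Ordinal of the unique bin containing 1-based ``pos``.

        Raises :class:`UnmappablePosition` for unknown chromosomes or
        out-of-range positions; the caller decides whether to drop and log.
        """
        chrom = normalize_chrom(chrom)
        if chrom not in self.genome:
            raise UnmappablePosition(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self.genome.lengths[chrom]:
            raise UnmappablePosition(f"{chrom}:{pos} outside [1, {self.genome.lengths[chrom]}]")
        return self._offsets[chrom] + (pos - 1) // self.bin_size

    def to_bed(self, path: str | Path) -> None:
        """Export as BED (0-based half-open on disk)."""
        with open(path, "w") as fh:
            for b in self.bins:
                fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.ordinal}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicBinIndex":
        """Re-load a bin index exported by :meth:`to_bed`.

        The bin size is recovered as the maximal bin width; the genome
        build is reconstructed from the last bin end per chromosome.
        """
        bins: list[GenomicBin] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = normalize_chrom(fields[0])
            start0, end = int(fields[1]), int(fields[2])
            bins.append(GenomicBin(chrom, start0 + 1, end, len(bins)))
        if not bins:
            raise ValueError(f"{path}: no bins")
        lengths: dict[str, int] = {}
        names: list[str] = []
        for b in bins:
            if b.chrom not in lengths:
                names.append(b.chrom)
            lengths[b.chrom] = max(lengths.get(b.chrom, 0), b.end)
        genome = GenomeBuild(tuple(names), lengths)
        bin_size = max(b.end - b.start + 1 for b in bins)
        return cls(genome, bin_size, bins)


def build_bins(genome: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> GenomicBinIndex:
    """Partition every chromosome into ceiling-count fixed-width bins.

    Bin k (1-based) of a chromosome of length L covers
    ``[(k-1)*bin_size + 1, min(k*bin_size, L)]``; ordinals are assigned
    densely in chromosome order. GRCh38 autosomes at 5 Mb give 587 bins.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    bins: list[GenomicBin] = []
    for chrom in genome.names:
        length = genome.lengths[chrom]
        for k in range(math.ceil(length / bin_size)):
            start = k * bin_size + 1
            end = min((k + 1) * bin_size, length)
            bins.append(GenomicBin(chrom, start, end, len(bins)))
    return GenomicBinIndex(genome, bin_size, bins)
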