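"""Variant ingestion, functional classification, and MAF filtering.

Small variants are read from a multi-sample VCF, decomposed to one record
per alt allele, and assigned exactly one of seven functional categories:
three coding classes (stop-gain, frameshift, nonsynonymous) and four
non-coding classes (UTR, ncRNA, intronic, intergenic). Synonymous coding
variants belong to none of the seven classes and are dropped from feature
building. Population-common variants (minor allele frequency above a
threshold, default 0.05, in a reference panel supplied as a TSV) are
removed before burden counting.

Classification can come from a precomputed annotation table or from a
built-in classifier against a supplied gene model. The built-in classifier
uses the conventional annotator precedence: coding effect (stop-gain >
frameshift > nonsynonymous) > UTR > ncRNA > intronic > intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .genome import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalCategory",
    "CODING_CATEGORIES",
    "NONCODING_CATEGORIES",
    "VariantRecord",
    "Gene",
    "GeneModel",
    "read_genotypes",
    "classify_variant",
    "filter_common",
    "read_af_table",
    "read_annotation_table",
    "write_annotation_table",
]


class FunctionalCategory(str, Enum):
    """The seven variant consequence classes used for burden features."""

    NONSYNONYMOUS = "nonsynonymous"
    FRAMESHIFT = "frameshift"
    STOPCODON = "stopcodon"
    UTR = "utr"
    NCRNA = "ncrna"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CODING_CATEGORIES = frozenset(
    {FunctionalCategory.NONSYNONYMOUS, FunctionalCategory.FRAMESHIFT, FunctionalCategory.STOPCODON}
)
NONCODING_CATEGORIES = frozenset(FunctionalCategory) - CODING_CATEGORIES

# Precedence rank for overlapping annotations (lower wins). Synonymous is a
# coding-tier outcome that yields no category at all.
_RANK = {
    FunctionalCategory.STOPCODON: 0,
    FunctionalCategory.FRAMESHIFT: 1,
    FunctionalCategory.NONSYNONYMOUS: 2,
    FunctionalCategory.UTR: 4,
    FunctionalCategory.NCRNA: 5,
    FunctionalCategory.INTRONIC: 6,
    FunctionalCategory.INTERGENIC: 7,
}
_SYNONYMOUS_RANK = 3


@dataclass
class VariantRecord:
    """One biallelic alt allele at a genomic position (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    category: FunctionalCategory | None = None
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class Gene:
    """A gene with its transcript span, exons and CDS (1-based inclusive).

    ``cds_seq`` is the spliced coding sequence in transcription direction;
    it is required to assess codon-level effects of coding SNVs.
    """

    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = False
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.name}: exon [{s},{e}] outside span")
        exon_cover = _interval_set(self.exons)
        for s, e in self.cds:
            if not all(p in exon_cover for p in (s, e)):
                raise ValueError(f"{self.name}: CDS [{s},{e}] not within exons")
        if self.coding and self.cds_seq is not None:
            cds_len = sum(e - s + 1 for s, e in self.cds)
            if len(self.cds_seq) != cds_len:
                raise ValueError(f"{self.name}: cds_seq length {len(self.cds_seq)} != CDS extent {cds_len}")
            if cds_len % 3 != 0:
                raise ValueError(f"{self.name}: CDS length {cds_len} not a multiple of 3")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of ``pos`` within the spliced CDS, strand-aware."""
        ivals = sorted(self.cds)
        if self.strand == "-":
            off = 0
            for s, e in reversed(ivals):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        else:
            off = 0
            for s, e in ivals:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        raise ValueError(f"{self.name}: {pos} not in CDS")


def _interval_set(ivals: Sequence[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in ivals:
        out.update(range(s, e + 1))
    return out


@dataclass
class GeneModel:
    """A collection of genes supporting position-overlap queries."""

    genes: list[Gene]
    _by_chrom: dict[str, list[Gene]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_chrom:
            for g in self.genes:
                self._by_chrom.setdefault(g.chrom, []).append(g)

    def overlapping(self, chrom: str, pos: int) -> list[Gene]:
        chrom = normalize_chrom(chrom)
        return [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]

    # -- GFF3 round trip ---------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        """Write genes as GFF3. The spliced CDS sequence travels in a
        ``cds_seq`` attribute on the mRNA feature so that classification
        needs no separate reference FASTA."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID=gene:{g.name};Name={g.name}\n"
                )
                ttype = "mRNA" if g.coding else "ncRNA"
                attrs = f"ID=tx:{g.name};Parent=gene:{g.name}"
                if g.cds_seq:
                    attrs += f";cds_seq={g.cds_seq}"
                fh.write(f"{g.chrom}\t.\t{ttype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent=tx:{g.name}\n"
                    )
                for s, e in g.cds:
                    fh.write(
                        f"{g.chrom}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent=tx:{g.name}\n"
                    )

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModel":
        """Load a gene model from GFF3 (gene / mRNA|ncRNA / exon / CDS)."""
        genes: dict[str, Gene] = {}
        tx_to_gene: dict[str, str] = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line[:80]}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((f[0], f[2], int(f[3]), int(f[4]), f[6], attrs))
        for chrom, ftype, start, end, strand, attrs in rows:
            if ftype == "gene":
                name = attrs.get("Name") or attrs["ID"].split(":", 1)[-1]
                genes[attrs["ID"]] = Gene(name, chrom, strand, start, end, exons=[])
        for chrom, ftype, start, end, strand, attrs in rows:
            if ftype in ("mRNA", "ncRNA", "transcript"):
                parent = attrs["Parent"]
                tx_to_gene[attrs["ID"]] = parent
                g = genes[parent]
                g.coding = ftype == "mRNA"
                if "cds_seq" in attrs:
                    g.cds_seq = attrs["cds_seq"]
        for chrom, ftype, start, end, strand, attrs in rows:
            if ftype in ("exon", "CDS"):
                g = genes[tx_to_gene[attrs["Parent"]]]
                (g.exons if ftype == "exon" else g.cds).append((start, end))
        out = []
        for g in genes.values():
            g.exons.sort()
            g.cds.sort()
            out.append(
                Gene(g.name, g.chrom, g.strand, g.start, g.end, g.exons, g.cds, g.coding, g.cds_seq)
            )
        return cls(out)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_genotypes(
    vcf_path: str | Path,
    sample_subset: Sequence[str] | None = None,
) -> tuple[list[str], Iterator[tuple[VariantRecord, np.ndarray, np.ndarray]]]:
    """Stream per-alt-allele genotype presence from a multi-sample VCF.

    Returns the ordered sample list and an iterator of
    ``(VariantRecord, carries_alt, alt_dosage)`` where the arrays are
    per-sample (bool and 0/1/2 int). Multiallelic sites are decomposed to
    one record per alt allele; missing genotypes count as non-carriers.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise ValueError(f"samples not in VCF header: {sorted(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    n = len(samples)

    def _iter() -> Iterator[tuple[VariantRecord, np.ndarray, np.ndarray]]:
        for v in vcf:
            alts = v.ALT or []
            if len(alts) == 1:
                # gts012: 0/1/2 = alt dosage, 3 = missing -> non-carrier
                gt = v.gt_types
                dosage = np.where(gt == 3, 0, gt).astype(np.int16)
                yield (
                    VariantRecord(normalize_chrom(v.CHROM), v.POS, v.REF, alts[0]),
                    dosage > 0,
                    dosage,
                )
            else:
                geno = v.genotypes  # [[a1, a2, phased], ...]
                for k, alt in enumerate(alts, start=1):
                    dosage = np.zeros(n, dtype=np.int16)
                    for i, g in enumerate(geno):
                        dosage[i] = sum(1 for a in g[:-1] if a == k)
                    yield (
                        VariantRecord(normalize_chrom(v.CHROM), v.POS, v.REF, alt),
                        dosage > 0,
                        dosage,
                    )

    return samples, _iter()


# ---------------------------------------------------------------------------
# Functional classification
# ---------------------------------------------------------------------------


def _coding_effect(variant: VariantRecord, gene: Gene) -> FunctionalCategory | None | str:
    """Effect of a variant whose position lies in the CDS of ``gene``.

    Returns a category, the sentinel string ``"synonymous"``, or raises if
    the gene model is inconsistent with the variant.
    """
    dlen = abs(len(variant.ref) - len(variant.alt))
    if dlen:
        return (
            FunctionalCategory.FRAMESHIFT
            if dlen % 3
            # in-frame indel: protein-altering, grouped with nonsynonymous
            else FunctionalCategory.NONSYNONYMOUS
        )
    if not variant.is_snv:
        return FunctionalCategory.NONSYNONYMOUS  # same-length MNV
    if gene.cds_seq is None:
        raise ValueError(f"gene {gene.name} has no CDS sequence; cannot assess coding effect")
    off = gene.cds_offset(variant.pos)
    ref_base, alt_base = variant.ref, variant.alt
    if gene.strand == "-":
        ref_base = str(Seq(ref_base).complement())
        alt_base = str(Seq(alt_base).complement())
    if gene.cds_seq[off].upper() != ref_base.upper():
        raise ValueError(
            f"gene {gene.name}: CDS base {gene.cds_seq[off]!r} at offset {off} "
            f"does not match ref allele {variant.ref!r} at {variant.chrom}:{variant.pos}"
        )
    ci, cw = divmod(off, 3)
    codon = gene.cds_seq[3 * ci : 3 * ci + 3].upper()
    new_codon = codon[:cw] + alt_base.upper() + codon[cw + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == "*" and old_aa != "*":
        return FunctionalCategory.STOPCODON
    if new_aa != old_aa:
        return FunctionalCategory.NONSYNONYMOUS
    return "synonymous"


def classify_variant(variant: VariantRecord, gene_model: GeneModel | None) -> FunctionalCategory | None:
    """Assign exactly one of the seven categories (or None for synonymous).

    A precomputed category on the record passes through unchanged. A
    variant overlapping no gene is intergenic. Overlapping annotations are
    resolved by coding > UTR > ncRNA > intronic precedence.
    """
    if variant.category is not None:
        return variant.category
    if gene_model is None:
        raise ValueError("no gene model and no precomputed category")
    best_rank = _RANK[FunctionalCategory.INTERGENIC]
    best: FunctionalCategory | None = FunctionalCategory.INTERGENIC
    for gene in gene_model.overlapping(variant.chrom, variant.pos):
        if not gene.coding:
            cat: FunctionalCategory | None | str = FunctionalCategory.NCRNA
        elif gene.in_cds(variant.pos):
            cat = _coding_effect(variant, gene)
        elif gene.in_exon(variant.pos):
            cat = FunctionalCategory.UTR
        else:
            cat = FunctionalCategory.INTRONIC
        rank = _SYNONYMOUS_RANK if cat == "synonymous" else _RANK[cat]  # type: ignore[index]
        if rank < best_rank:
            best_rank = rank
            best = None if cat == "synonymous" else cat  # type: ignore[assignment]
    return best


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def read_af_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Read a TSV of (chrom, pos, ref, alt, af) into a lookup dict."""
    table: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            af = float(f[4])
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{path}:{lineno}: AF {af} outside [0, 1]")
            table[(normalize_chrom(f[0]), int(f[1]), f[2], f[3])] = af
    return table


def is_common(
    variant: VariantRecord,
    af_table: Mapping[tuple[str, int, str, str], float],
    threshold: float = 0.05,
) -> bool:
    """True iff the variant's folded minor allele frequency exceeds the
    threshold (strict inequality); variants absent from the table are not
    common by definition (retained)."""
    af = af_table.get(variant.key)
    if af is None:
        return False
    return min(af, 1.0 - af) > threshold


def filter_common(
    variants: Iterable[VariantRecord],
    af_table: Mapping[tuple[str, int, str, str], float],
    threshold: float = 0.05,
) -> list[VariantRecord]:
    """Drop variants with panel MAF strictly above ``threshold``.

    AF is folded to the minor allele, min(AF, 1-AF). Variants without a
    table entry are retained. Idempotent.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    retained, removed = [], 0
    for v in variants:
        af = af_table.get(v.key)
        if af is not None:
            v.population_af = af
        if is_common(v, af_table, threshold):
            removed += 1
        else:
            retained.append(v)
    logger.info("MAF filter: retained %d, removed %d (threshold %g)", len(retained), removed, threshold)
    return retained


# ---------------------------------------------------------------------------
# Precomputed annotation tables
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> dict[tuple[str, int, str, str], FunctionalCategory]:
    """Read a TSV of (chrom, pos, ref, alt, category)."""
    table: dict[tuple[str, int, str, str], FunctionalCategory] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            table[(normalize_chrom(f[0]), int(f[1]), f[2], f[3])] = FunctionalCategory(f[4])
    return table


def write_annotation_table(
    path: str | Path,
    entries: Iterable[tuple[tuple[str, int, str, str], FunctionalCategory]],
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcategory\n")
        for (chrom, pos, ref, alt), cat in entries:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{cat.value}\n")
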