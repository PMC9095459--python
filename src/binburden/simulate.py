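"""Synthetic case-control cohorts with known planted structure.

The generator emits everything the pipeline consumes — a multi-sample VCF,
a GFF3 gene model, a population allele-frequency TSV, and an 8-column
phenotype TSV — from a fully specified probabilistic model, so every stage
can be tested end-to-end without any real (controlled-access) data.

Model
-----
Per sample s, bin b, and functional category c, the number of rare variant
sites carried is Poisson with rate ``lambda * rho**(case_s and b planted
for c)``: a multiplicative case enrichment in a small set of effect bins,
baseline everywhere else. Each carried site is drawn without replacement
from a fixed per-(bin, category) pool of candidate sites engineered against
the synthetic gene model (stop-gain and nonsynonymous SNVs at designated
CDS codons, frameshift insertions in the CDS, and UTR / ncRNA / intronic /
intergenic SNVs in the matching intervals), so re-ingesting the VCF through
the annotation and burden stages reproduces the generator's counts exactly.

The eight diagnosis labels follow a liability-threshold model with one
shared latent factor per case, which induces the comorbidity (multiple
diagnoses per patient) seen in real cohorts; every case is forced to carry
at least one diagnosis and controls carry none. A configurable set of
common variants (panel AF > 0.05) is planted to exercise the MAF filter;
they appear in the VCF and the AF table but not in the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .genome import GenomeBuild, GenomicBinIndex, build_bins
from .models import DISORDER_LABELS, PhenotypeMatrix
from .variants import FunctionalCategory, Gene, GeneModel, VariantRecord

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "EFFECT_RHO_PRESETS",
    "mini_genome",
    "make_config",
    "generate_cohort",
    "expected_metrics",
]

#: Case-enrichment multipliers for the named effect-size presets. "strong"
#: is calibrated so a 20-round two-fold shuffle at n=400 lands at ~0.6-0.7
#: binary accuracy, the working point of the real study's reported range.
EFFECT_RHO_PRESETS = {"null": 1.0, "weak": 1.15, "medium": 1.3, "strong": 1.4}

# Bins narrower than this (trailing bins of real chromosomes) receive no
# planted sites; the synthetic gene/site layout needs this much room.
MIN_BIN_WIDTH = 450_000

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


def mini_genome(n_chroms: int = 4, chrom_length: int = 25_000_000) -> GenomeBuild:
    """A scaled-down genome (default 4 x 25 Mb -> 20 five-Mb bins)."""
    return GenomeBuild.from_pairs((f"chr{i+1}", chrom_length) for i in range(n_chroms))


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort.

    Defaults mirror the study cohort composition (1384 cases, 2795
    controls) on the mini-genome; the baseline burden rate ``baseline_rate``
    is per sample, bin, and category.
    """

    n_cases: int = 1384
    n_controls: int = 2795
    genome: GenomeBuild = field(default_factory=mini_genome)
    bin_size: int = 5_000_000
    baseline_rate: float = 3.0
    effect_bins: dict[FunctionalCategory, tuple[int, ...]] = field(default_factory=dict)
    rho: float = 1.0
    label_effects: dict[str, float] = field(default_factory=dict)
    pool_size: int = 40
    common_variants: int = 50
    common_af_range: tuple[float, float] = (0.10, 0.50)
    label_prevalence: tuple[float, ...] = (0.55, 0.35, 0.40, 0.25, 0.20, 0.12, 0.12, 0.15)
    comorbidity_loading: float = 0.6
    hom_fraction: float = 0.10
    rare_af_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.rho < 1.0:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if len(self.label_prevalence) != len(DISORDER_LABELS):
            raise ValueError("label_prevalence must have 8 entries")
        if not all(0.0 < p < 1.0 for p in self.label_prevalence):
            raise ValueError("prevalences must be in (0, 1)")
        if not 0.0 <= self.comorbidity_loading < 1.0:
            raise ValueError("comorbidity_loading must be in [0, 1)")
        n_bins = len(build_bins(self.genome, self.bin_size))
        for cat, bins in self.effect_bins.items():
            bad = [b for b in bins if not 0 <= b < n_bins]
            if bad:
                raise ValueError(f"effect bins {bad} for {cat} outside the {n_bins}-bin genome")
        for label in self.label_effects:
            if label not in DISORDER_LABELS:
                raise ValueError(f"unknown label {label!r} in label_effects")


def make_config(
    preset: str = "strong",
    n_cases: int = 200,
    n_controls: int = 200,
    n_effect_bins: int = 3,
    effect_categories: tuple[FunctionalCategory, ...] = (
        FunctionalCategory.NONSYNONYMOUS,
        FunctionalCategory.FRAMESHIFT,
        FunctionalCategory.STOPCODON,
    ),
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Convenience constructor: plant ``n_effect_bins`` effect bins in the
    given categories (coding by default, mirroring the coding-hotspot
    pattern) at the preset's enrichment multiplier."""
    rho = EFFECT_RHO_PRESETS[preset]
    genome = overrides.pop("genome", mini_genome())
    bin_size = overrides.pop("bin_size", 5_000_000)
    n_bins = len(build_bins(genome, bin_size))
    rng = np.random.default_rng(seed)
    effect: dict[FunctionalCategory, tuple[int, ...]] = {}
    if rho > 1.0 and n_effect_bins > 0:
        for cat in effect_categories:
            effect[cat] = tuple(
                int(b) for b in rng.choice(n_bins, size=min(n_effect_bins, n_bins), replace=False)
            )
    return CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        genome=genome,
        bin_size=bin_size,
        effect_bins=effect,
        rho=rho,
        seed=seed,
        **overrides,
    )


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, for recovery tests."""

    effect_bins: dict[FunctionalCategory, tuple[int, ...]]
    rho: float
    label_effects: dict[str, float]
    seed: int
    common_variant_keys: list[tuple[str, int, str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effect_bins": {c.value: list(b) for c, b in self.effect_bins.items()},
            "rho": self.rho,
            "label_effects": self.label_effects,
            "seed": self.seed,
            "common_variant_keys": [list(k) for k in self.common_variant_keys],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class _Site:
    """One candidate variant site with its realized carriers."""

    chrom: str
    pos: int
    ref: str
    alt: str
    category: FunctionalCategory
    carriers: np.ndarray  # bool (n_samples,)
    homs: np.ndarray  # bool, subset of carriers
    af: float | None = None
    is_common: bool = False


@dataclass
class SyntheticCohort:
    """An in-memory cohort plus writers for the on-disk formats."""

    config: CohortConfig
    bin_index: GenomicBinIndex
    gene_model: GeneModel
    sample_ids: list[str]
    phenotypes: PhenotypeMatrix
    counts: dict[FunctionalCategory, np.ndarray]  # (n_samples, n_bins) int
    sites: list[_Site]
    truth: PlantedTruth

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def af_rows(self) -> list[tuple[str, int, str, str, float]]:
        return [
            (s.chrom, s.pos, s.ref, s.alt, s.af) for s in self.sites if s.af is not None
        ]

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(s.chrom, s.pos, s.ref, s.alt, category=s.category)
            for s in self.sites
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF, gene model GFF3, AF TSV, annotation TSV, phenotype
        TSV, and the planted truth JSON; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "phenotypes": outdir / "phenotypes.tsv",
            "af": outdir / "af.tsv",
            "gene_model": outdir / "genes.gff3",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.json",
        }
        self._write_vcf(paths["vcf"])
        self.phenotypes.to_tsv(paths["phenotypes"])
        with open(paths["af"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\taf\n")
            for row in self.af_rows():
                fh.write("\t".join(str(x) for x in row[:4]) + f"\t{row[4]:.6g}\n")
        self.gene_model.to_gff3(paths["gene_model"])
        with open(paths["annotations"], "w") as fh:
            fh.write("chrom\tpos\tref\talt\tcategory\n")
            for s in self.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.category.value}\n")
        self.truth.to_json(paths["truth"])
        return paths

    def _write_vcf(self, path: Path) -> None:
        chrom_rank = {c: i for i, c in enumerate(self.bin_index.genome.names)}
        ordered = sorted(self.sites, key=lambda s: (chrom_rank[s.chrom], s.pos))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=binburden-simulate\n")
            for name in self.bin_index.genome.names:
                fh.write(f"##contig=<ID={name},length={self.bin_index.genome.lengths[name]}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.sample_ids) + "\n")
            for s in ordered:
                gts = np.where(s.carriers, np.where(s.homs, "1/1", "0/1"), "0/0")
                fh.write(
                    f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Gene / site layout within one bin
# ---------------------------------------------------------------------------

# Offsets (bp) of the synthetic features relative to each bin start.
_GENE_OFFSET = 100_000
_NC_OFFSET = 200_000
_INTERGENIC_OFFSET = 300_000
_COMMON_OFFSET = 400_000


def _make_bin_gene_pair(chrom: str, bin_start: int, ordinal: int, rng: np.random.Generator) -> tuple[Gene, Gene]:
    """One coding gene (two exons, split CDS) and one single-exon ncRNA."""
    g = bin_start + _GENE_OFFSET
    cds = [(g + 200, g + 998), (g + 6000, g + 7999)]  # 799 + 2000 = 2799 bp
    n_codons = 2799 // 3
    codons = list(rng.choice(_NONSTOP_CODONS, size=n_codons))
    # Designated codon slots: nonsynonymous (GCT, G->C gives CCT), stop-gain
    # (CGA, C->T gives TGA), frameshift anchor (GGT, insert A after the G).
    for ci in range(0, 40):
        codons[ci] = "GCT"
    for ci in range(100, 140):
        codons[ci] = "CGA"
    for ci in range(200, 240):
        codons[ci] = "GGT"
    coding = Gene(
        name=f"G{ordinal:03d}C",
        chrom=chrom,
        strand="+",
        start=g,
        end=g + 9999,
        exons=[(g, g + 999), (g + 6000, g + 9999)],
        cds=cds,
        coding=True,
        cds_seq="".join(codons),
    )
    nc_start = bin_start + _NC_OFFSET
    ncrna = Gene(
        name=f"G{ordinal:03d}N",
        chrom=chrom,
        strand="+",
        start=nc_start,
        end=nc_start + 4999,
        exons=[(nc_start, nc_start + 4999)],
        coding=False,
    )
    return coding, ncrna


def _cds_pos(gene_start: int, offset: int) -> int:
    """Genomic position of 0-based spliced-CDS offset for the layout above."""
    g = gene_start
    return g + 200 + offset if offset < 799 else g + 6000 + (offset - 799)


def _site_pools(
    chrom: str, bin_start: int, gene: Gene, nc: Gene, pool_size: int
) -> dict[FunctionalCategory, list[tuple[int, str, str]]]:
    """Candidate (pos, ref, alt) pools per category for one bin."""
    g = gene.start
    pools: dict[FunctionalCategory, list[tuple[int, str, str]]] = {}
    pools[FunctionalCategory.NONSYNONYMOUS] = [
        (_cds_pos(g, 3 * ci), "G", "C") for ci in range(0, pool_size)
    ]
    pools[FunctionalCategory.STOPCODON] = [
        (_cds_pos(g, 3 * ci), "C", "T") for ci in range(100, 100 + pool_size)
    ]
    pools[FunctionalCategory.FRAMESHIFT] = [
        (_cds_pos(g, 3 * ci), "G", "GA") for ci in range(200, 200 + pool_size)
    ]
    pools[FunctionalCategory.UTR] = [
        (g + 8000 + 2 * i, "A", "G") for i in range(pool_size)  # 3' UTR
    ]
    pools[FunctionalCategory.NCRNA] = [
        (nc.start + 10 * i, "A", "G") for i in range(pool_size)
    ]
    pools[FunctionalCategory.INTRONIC] = [
        (g + 1000 + 20 * i, "A", "G") for i in range(pool_size)
    ]
    pools[FunctionalCategory.INTERGENIC] = [
        (bin_start + _INTERGENIC_OFFSET + 100 * i, "A", "G") for i in range(pool_size)
    ]
    return pools


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Liability-threshold labels for the cases; >= 1 diagnosis enforced."""
    n, k = config.n_cases, len(DISORDER_LABELS)
    if n == 0:
        return np.zeros((0, k), dtype=np.int8)
    a = config.comorbidity_loading
    f = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    z = a * f[:, None] + np.sqrt(1.0 - a * a) * eps
    tau = norm.ppf(1.0 - np.asarray(config.label_prevalence))
    Y = (z > tau).astype(np.int8)
    empty = Y.sum(axis=1) == 0
    if empty.any():
        Y[np.flatnonzero(empty), z[empty].argmax(axis=1)] = 1
    return Y


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model; reproducible given
    ``config.seed``. Trailing bins narrower than ~450 kb receive no sites
    (their burden is structurally zero)."""
    rng = np.random.default_rng(config.seed)
    bin_index = build_bins(config.genome, config.bin_size)
    n_bins = len(bin_index)
    n = config.n_cases + config.n_controls
    sample_ids = [f"S{i:05d}" for i in range(n)]
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    Y = np.zeros((n, len(DISORDER_LABELS)), dtype=np.int8)
    Y[: config.n_cases] = _draw_labels(config, rng)
    phen = PhenotypeMatrix(sample_ids, Y)

    genes: list[Gene] = []
    pools_by_bin: dict[int, dict[FunctionalCategory, list[tuple[int, str, str]]]] = {}
    for b in bin_index.bins:
        if b.end - b.start + 1 < MIN_BIN_WIDTH:
            continue
        coding, nc = _make_bin_gene_pair(b.chrom, b.start, b.ordinal, rng)
        genes.extend((coding, nc))
        pools_by_bin[b.ordinal] = _site_pools(b.chrom, b.start, coding, nc, config.pool_size)
    gene_model = GeneModel(genes)

    counts = {c: np.zeros((n, n_bins), dtype=np.int64) for c in FunctionalCategory}
    sites: list[_Site] = []
    label_mult = np.ones(n)
    for label, lrho in config.label_effects.items():
        j = DISORDER_LABELS.index(label)
        label_mult = label_mult * np.where(Y[:, j] == 1, lrho, 1.0)

    P = config.pool_size
    for b in bin_index.bins:
        pools = pools_by_bin.get(b.ordinal)
        if pools is None:
            continue
        for cat in FunctionalCategory:
            rate = np.full(n, config.baseline_rate)
            if b.ordinal in config.effect_bins.get(cat, ()):
                rate = rate * np.where(is_case, config.rho, 1.0) * label_mult
            k = np.minimum(rng.poisson(rate), P)
            counts[cat][:, b.ordinal] = k
            # per sample, the k carried sites are the k smallest random ranks
            ranks = rng.random((n, P)).argsort(axis=1).argsort(axis=1)
            mask = ranks < k[:, None]
            homs = mask & (rng.random((n, P)) < config.hom_fraction)
            pool = pools[cat]
            carried_sites = np.flatnonzero(mask.any(axis=0))
            for j in carried_sites:
                pos, ref, alt = pool[j]
                af = (
                    float(rng.uniform(0.001, 0.05))
                    if rng.random() < config.rare_af_fraction
                    else None
                )
                sites.append(
                    _Site(b.chrom, pos, ref, alt, cat, mask[:, j].copy(), homs[:, j].copy(), af=af)
                )

    # Planted common variants: in the AF table with AF > 0.05, carried by
    # many samples, intergenic by position; the MAF filter must remove all
    # of them before burden counting.
    common_keys: list[tuple[str, int, str, str]] = []
    wide_bins = [bin_index.bins[o] for o in sorted(pools_by_bin)]
    per_bin_counter: dict[int, int] = {}
    for i in range(config.common_variants):
        b = wide_bins[i % len(wide_bins)]
        idx = per_bin_counter.get(b.ordinal, 0)
        per_bin_counter[b.ordinal] = idx + 1
        pos = b.start + _COMMON_OFFSET + 50 * idx
        af = float(rng.uniform(*config.common_af_range))
        carrier_p = 1.0 - (1.0 - af) ** 2  # HWE carrier probability
        carriers = rng.random(n) < carrier_p
        homs = carriers & (rng.random(n) < af)
        sites.append(
            _Site(b.chrom, pos, "A", "G", FunctionalCategory.INTERGENIC, carriers, homs, af=af, is_common=True)
        )
        common_keys.append((b.chrom, pos, "A", "G"))

    truth = PlantedTruth(
        effect_bins=dict(config.effect_bins),
        rho=config.rho,
        label_effects=dict(config.label_effects),
        seed=config.seed,
        common_variant_keys=common_keys,
    )
    return SyntheticCohort(config, bin_index, gene_model, sample_ids, phen, counts, sites, truth)


def expected_metrics(config: CohortConfig) -> dict[str, float]:
    """Analytic chance baselines for the configured cohort.

    A balanced binary split has null accuracy 1/2; guessing each of k
    independent binary labels uniformly matches the whole vector with
    probability (1/2)^k — 1/256 for the 8 disorders.
    """
    k = len(DISORDER_LABELS)
    return {
        "null_accuracy": 0.5,
        "random_exact_match": 0.5**k,
        "n_label_combinations": float(2**k),
    }
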