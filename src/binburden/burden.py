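"""Collapse genotypes into samples x bins burden-count matrices.

One matrix per functional category; entry (s, b) is the number of retained
variants of that category in bin b for which sample s carries at least one
alternate allele (site-presence, the default) or the sum of alt dosages
(allele-dosage mode). Matrices for different categories are never merged:
each variant class is modelled separately downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomicBinIndex, UnmappablePosition
from .variants import FunctionalCategory, VariantRecord

logger = logging.getLogger(__name__)

__all__ = ["BurdenMatrix", "build_burden_matrix", "build_all_burden_matrices"]


@dataclass
class BurdenMatrix:
    """Integer burden counts for one functional category."""

    category: FunctionalCategory
    samples: list[str]
    bin_labels: list[str]
    counts: np.ndarray  # shape (n_samples, n_bins), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.bin_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.bin_labels)} bins"
            )
        if (self.counts < 0).any():
            raise ValueError("negative burden count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.bin_labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = f"sample\t#category={self.category.value}".split("\t")[0]
        with open(path, "w") as fh:
            fh.write(f"#category={self.category.value}\n")
            df.to_csv(fh, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BurdenMatrix":
        with open(path) as fh:
            first = fh.readline()
            m = re.match(r"#category=(\S+)", first)
            if not m:
                raise ValueError(f"{path}: missing #category header line")
            category = FunctionalCategory(m.group(1))
            df = pd.read_csv(fh, sep="\t", index_col="sample")
        return cls(category, [str(s) for s in df.index], list(df.columns), df.to_numpy(dtype=np.int64))


def build_burden_matrix(
    genotype_stream: Iterable[tuple[VariantRecord, np.ndarray, np.ndarray]],
    bin_index: GenomicBinIndex,
    category: FunctionalCategory,
    samples: list[str],
    counting_mode: str = "presence",
) -> BurdenMatrix:
    """Accumulate one category's burden counts over a genotype stream.

    Variants whose ``category`` differs are ignored (stream may be mixed);
    variants mapping to no bin are dropped with a warning count. The stream
    must already be MAF-filtered and classified.
    """
    if counting_mode not in ("presence", "dosage"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    mats = build_all_burden_matrices(
        genotype_stream, bin_index, samples, counting_mode=counting_mode, categories=[category]
    )
    return mats[category]


def build_all_burden_matrices(
    genotype_stream: Iterable[tuple[VariantRecord, np.ndarray, np.ndarray]],
    bin_index: GenomicBinIndex,
    samples: list[str],
    counting_mode: str = "presence",
    categories: Iterable[FunctionalCategory] | None = None,
) -> dict[FunctionalCategory, BurdenMatrix]:
    """One pass over the stream, one matrix per requested category."""
    if counting_mode not in ("presence", "dosage"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    cats = list(categories) if categories is not None else list(FunctionalCategory)
    n, m = len(samples), len(bin_index)
    acc = {c: np.zeros((n, m), dtype=np.int64) for c in cats}
    unmapped = 0
    for rec, carries, dosage in genotype_stream:
        if rec.category is None or rec.category not in acc:
            continue
        if carries.shape[0] != n:
            raise ValueError(f"genotype vector length {carries.shape[0]} != {n} samples")
        try:
            b = bin_index.locate(rec.chrom, rec.pos)
        except UnmappablePosition:
            unmapped += 1
            continue
        if counting_mode == "presence":
            acc[rec.category][:, b] += carries.astype(np.int64)
        else:
            acc[rec.category][:, b] += dosage.astype(np.int64)
    if unmapped:
        logger.warning("dropped %d variants mapping to no bin", unmapped)
    labels = bin_index.labels
    return {c: BurdenMatrix(c, list(samples), labels, acc[c]) for c in cats}
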