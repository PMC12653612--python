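"""Histogram density estimation over gene-number and log-size axes.

Genomes are grouped into classes of fixed width along the gene-count axis
(default 500 genes) or the base-10 logarithm of genome size (default 0.1
decades).  The probability density in class ``j`` is

    f[j] = count[j] / (interval * n_total)

so densities are per gene (or per decade) and independent of sample size.
Class labels follow the minimal-multiple convention: class 0 covers
``[0, interval]`` and class ``k >= 1`` covers ``(k*interval, (k+1)*interval]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .genome_table import GenomeRecord

__all__ = [
    "BinnedDensity",
    "bin_gene_numbers",
    "bin_log_sizes",
    "rice_rule",
    "freedman_diaconis",
]


@dataclass(frozen=True)
class BinnedDensity:
    """A histogram density estimate on a regular class grid.

    Attributes
    ----------
    axis:
        ``"gene_number"`` (classes of whole genes) or ``"log10_size"``
        (classes of decades of genome size).
    interval:
        Class width, in genes or decades.
    class_labels:
        Ascending label per class: the minimal multiple of ``interval``
        the class covers.
    counts:
        Genomes per class.
    density:
        ``counts / (interval * n_total)`` — probability per gene or per
        decade.
    n_total:
        Total genomes in the dataset (including any that fell outside the
        classed range); the normalizer of ``density``.
    """

    axis: Literal["gene_number", "log10_size"]
    interval: float
    class_labels: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be positive")
        if len(self.class_labels) != len(self.counts):
            raise ValueError("labels and counts must align")

    @property
    def class_indices(self) -> np.ndarray:
        """Ordinal class numbers k = label / interval, as integers."""
        return np.rint(np.asarray(self.class_labels) / self.interval).astype(int)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("class_label\tcount\tdensity\n")
            for label, count, dens in zip(self.class_labels, self.counts, self.density):
                fh.write(f"{label:g}\t{int(count)}\t{dens!r}\n")


def _assign_class(value: float, interval: float) -> int:
    """Class ordinal for the minimal-multiple labeling.

    Class 0 is closed on both sides, [0, interval]; every later class k is
    (k*interval, (k+1)*interval].
    """
    if value <= interval:
        return 0
    return int(math.ceil(value / interval)) - 1


def bin_gene_numbers(
    records: Sequence[GenomeRecord],
    interval: int = 500,
    max_genes: int = 100_000,
) -> BinnedDensity:
    """Group genomes into gene-number classes and estimate the density f_g.

    Genomes with more than ``max_genes`` genes are excluded from the class
    grid but still counted in ``n_total``, so the densities keep their global
    normalization (the density integral equals the fraction of genomes
    binned, which may be slightly below 1).
    """
    if interval < 1:
        raise ValueError("interval must be a positive number of genes")
    if max_genes % interval:
        raise ValueError("max_genes must be a multiple of interval")
    if not records:
        raise ValueError("cannot bin an empty record list")

    n_classes = max_genes // interval
    counts = np.zeros(n_classes, dtype=np.int64)
    for record in records:
        if record.total_genes > max_genes:
            continue
        counts[_assign_class(record.total_genes, interval)] += 1

    n_total = len(records)
    labels = np.arange(n_classes, dtype=float) * interval
    density = counts / (interval * n_total)
    return BinnedDensity(
        axis="gene_number",
        interval=float(interval),
        class_labels=labels,
        counts=counts,
        density=density,
        n_total=n_total,
    )


def bin_log_sizes(
    records: Sequence[GenomeRecord], interval: float = 0.1
) -> BinnedDensity:
    """Group genomes into classes of log10(genome size) and estimate f_s.

    The class grid spans the observed range of log-sizes; density is per
    decade.  Records with non-positive size cannot occur for valid
    :class:`~genomestats.genome_table.GenomeRecord` objects, but are
    rejected defensively.
    """
    if interval <= 0:
        raise ValueError("interval must be positive (decades)")
    if not records:
        raise ValueError("cannot bin an empty record list")

    logs = []
    for record in records:
        if record.size_bp < 1:
            continue
        logs.append(math.log10(record.size_bp))
    if not logs:
        raise ValueError("no records with positive size")

    ordinals = np.array([_assign_class(v, interval) for v in logs], dtype=np.int64)
    k_max = int(ordinals.max())
    counts = np.bincount(ordinals, minlength=k_max + 1).astype(np.int64)

    n_total = len(records)
    labels = np.arange(k_max + 1, dtype=float) * interval
    density = counts / (interval * n_total)
    return BinnedDensity(
        axis="log10_size",
        interval=float(interval),
        class_labels=labels,
        counts=counts,
        density=density,
        n_total=n_total,
    )


def rice_rule(n: int) -> int:
    """Rice's rule for the number of histogram bins: 2 * n**(1/3), rounded.

    For the 25,975-genome dataset this gives 59 bins.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    return int(round(2.0 * n ** (1.0 / 3.0)))


def freedman_diaconis(q1: float, q3: float, n: int) -> float:
    """Freedman-Diaconis bin width: 2 * IQR * n**(-1/3)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if q3 < q1:
        raise ValueError("q3 must be >= q1")
    return 2.0 * (q3 - q1) * n ** (-1.0 / 3.0)
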