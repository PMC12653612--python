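"""Cumulative extensive/intensive gene fractions along an ordered genome series.

Genomes are arranged by increasing gene number (size breaking ties).  Walking
up the series, each step from genome ``k-1`` to genome ``k`` adds
``g_k - g_{k-1}`` genes, of which the model says a fraction

    dg_e/dg = 1 - l_e(s_{k-1}) / l_emax

are extensive — the average length ``l_e`` being evaluated at the *model*
size of the previous genome (the closed-form size curve, not the observed
size).  The cumulative extensive fraction of genome ``k`` is the accumulated
extensive increments divided by its total gene count ``g_k``; the intensive
fraction is its complement.  These model fractions are compared with the
empirical split of each genome into protein-coding + pseudogenes (the
extensive candidates) versus non-coding genes (the intensive candidates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_table import GenomeRecord
from .size_model import SizeModelParams, dge_fraction, s_of_g

__all__ = [
    "FractionSeries",
    "cumulative_extensive_fraction",
    "empirical_fractions",
    "compare_predicted_vs_empirical",
]


@dataclass(frozen=True)
class FractionSeries:
    """Per-genome model and empirical gene-type fractions, ordered by gene count."""

    gene_numbers: np.ndarray
    ge_over_g: np.ndarray
    gi_over_g: np.ndarray
    empirical_pc_ps: np.ndarray
    empirical_nc: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_numbers)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "gene_number": self.gene_numbers,
                "ge_over_g": self.ge_over_g,
                "gi_over_g": self.gi_over_g,
                "empirical_pc_ps": self.empirical_pc_ps,
                "empirical_nc": self.empirical_nc,
            }
        )
        frame.to_csv(path, sep="\t", index=False)


def cumulative_extensive_fraction(
    records: Sequence[GenomeRecord],
    params: SizeModelParams,
    count_baseline_as_extensive: bool = True,
) -> FractionSeries:
    """Model extensive/intensive fractions for every genome in the series.

    Records are sorted by (gene number, size); genomes below the model's
    minimal gene number ``g0`` are excluded.  The first increment runs from
    the minimal genome ``(g0, s0)`` to the first record.  With
    ``count_baseline_as_extensive`` the ``g0`` genes of the minimal genome
    count as extensive (the series then starts near fraction 1); otherwise
    only accumulated increments count.

    Genomes sharing a gene number contribute zero-length increments and
    simply repeat the fraction of their gene count.
    """
    ordered = sorted(
        (r for r in records if r.total_genes >= params.g0),
        key=lambda r: (r.total_genes, r.size_bp),
    )
    if not ordered:
        raise ValueError("no records at or above the model's minimal gene number")

    g = np.array([r.total_genes for r in ordered], dtype=float)
    model_s = s_of_g(g, params)

    # dg_e/dg at the previous genome's model size; the first step uses (g0, s0).
    prev_s = np.concatenate([[params.s0], model_s[:-1]])
    prev_g = np.concatenate([[params.g0], g[:-1]])
    increments = dge_fraction(prev_s, params) * (g - prev_g)
    numerator = np.cumsum(increments)
    if count_baseline_as_extensive:
        numerator = numerator + params.g0
    ge = np.clip(numerator / g, 0.0, 1.0)

    pc_ps = np.array(
        [(r.pc_genes + r.ps_genes) / r.total_genes for r in ordered]
    )
    nc = np.array([r.nc_genes / r.total_genes for r in ordered])
    return FractionSeries(
        gene_numbers=g,
        ge_over_g=ge,
        gi_over_g=1.0 - ge,
        empirical_pc_ps=pc_ps,
        empirical_nc=nc,
    )


def empirical_fractions(
    records: Sequence[GenomeRecord],
) -> tuple[pd.DataFrame, int]:
    """Per-genome protein-coding, pseudogene and non-coding fractions.

    Returns a data frame with columns ``gene_number, pc, ps, nc, pc_ps`` and
    the number of records excluded for having zero genes.
    """
    rows = []
    n_excluded = 0
    for r in records:
        if r.total_genes == 0:
            n_excluded += 1
            continue
        rows.append(
            {
                "gene_number": r.total_genes,
                "pc": r.pc_genes / r.total_genes,
                "ps": r.ps_genes / r.total_genes,
                "nc": r.nc_genes / r.total_genes,
                "pc_ps": (r.pc_genes + r.ps_genes) / r.total_genes,
            }
        )
    return pd.DataFrame(rows), n_excluded


def compare_predicted_vs_empirical(series: FractionSeries) -> pd.DataFrame:
    """Per-genome differences between model and empirical fractions.

    Columns: the extensive-vs-(pc+ps) and intensive-vs-(nc) differences,
    with summary statistics available via ``DataFrame.describe()`` (mean and
    quantiles).  One row per genome in the series.
    """
    return pd.DataFrame(
        {
            "gene_number": series.gene_numbers,
            "extensive_minus_pc_ps": series.ge_over_g - series.empirical_pc_ps,
            "intensive_minus_nc": series.gi_over_g - series.empirical_nc,
        }
    )
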