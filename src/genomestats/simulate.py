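"""Synthetic genome tables with the statistical structure the analysis assumes.

The generator draws, per genome:

1. a gene count from the background + five-Poisson + step mixture (component
   chosen with probability proportional to its coefficient, class drawn from
   the component's mass function, count placed uniformly within the class's
   500-gene range — class 0 from 149 up, matching the smallest observed
   genome);
2. a genome size on the closed-form size-evolution curve with multiplicative
   base-10 log-normal scatter, resampled to stay at or above the minimal
   size ``s0``;
3. a split of the genes into protein-coding + pseudogene versus non-coding,
   centred on the model's cumulative extensive fraction at that point of the
   series, with Gaussian scatter; pseudogenes take a small fixed share of
   the extensive pool.

Genomes are i.i.d. draws — no phylogenetic correlation — and the defaults
reproduce the published reference parameter sets, so fitting the simulated
output back should recover those parameters up to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .fractions import cumulative_extensive_fraction
from .genome_table import Domain, GenomeRecord, write_genome_table
from .mixture import CLASS_WIDTH, MixtureParams, published_mixture_params
from .size_model import SizeModelParams, published_size_params, s_of_g

__all__ = ["SimulationConfig", "sample_gene_counts", "sample_sizes",
           "split_gene_types", "generate_table", "generate_records"]

#: Smallest gene count placed in class 0 (the smallest genome analyzed).
MIN_GENES = 149

#: Pseudogenes as a fixed share of the extensive (pc + ps) gene pool.
PS_SHARE = 0.07

#: Classes kept when tabulating the step component's decaying tail.
_STEP_TAIL_CLASSES = 400


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated genome table.

    ``size_noise_sigma`` is the standard deviation of the base-10 logarithm
    of the multiplicative size scatter (0.15 decades by default — the size
    cloud spans a fraction of a decade at fixed gene number).
    ``fraction_noise_sigma`` scatters the per-genome extensive share around
    the model value (0.05 by default).
    """

    n_genomes: int = 25_975
    mixture: MixtureParams = field(default_factory=published_mixture_params)
    size_params: SizeModelParams = field(default_factory=published_size_params)
    size_noise_sigma: float = 0.15
    fraction_noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be at least 1")
        if self.size_noise_sigma < 0 or self.fraction_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Read ``key = value`` lines; unlisted fields keep their defaults."""
        data: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = float(value.strip())
        kwargs = {}
        for key in ("n_genomes", "seed"):
            if key in data:
                kwargs[key] = int(data.pop(key))
        for key in ("size_noise_sigma", "fraction_noise_sigma"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown simulation keys: {sorted(data)}")
        return cls(**kwargs)


def _component_tables(mixture: MixtureParams):
    """Sampling probabilities and class samplers for every mixture component."""
    names = []
    weights = []
    names.append("bg")
    weights.append(mixture.a_bg)
    for i, comp in enumerate(mixture.poissons, start=1):
        names.append(f"P{i}")
        weights.append(comp.a)
    if mixture.step is not None:
        names.append("S")
        weights.append(mixture.step.a)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all mixture coefficients are zero; nothing to sample")
    # Renormalized to sum to one for sampling (the printed coefficients sum
    # to ~0.9923; sampling requires a proper distribution).
    return names, weights / total


def _sample_step_classes(
    step, n: int, rng: np.random.Generator
) -> np.ndarray:
    ks = np.arange(step.k_start, step.k_decay + _STEP_TAIL_CLASSES)
    mass = np.where(
        ks < step.k_decay,
        step.plateau_value,
        np.exp(-step.gamma * (ks - step.k_decay)) * step.plateau_value,
    )
    return rng.choice(ks, size=n, p=mass / mass.sum())


def sample_gene_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw per-genome gene counts from the mixture.

    A component is chosen per genome with probability proportional to its
    coefficient; a class is drawn from that component's mass function; the
    gene count is uniform within the class's 500-gene range (class 0 starts
    at the minimal observed genome, 149 genes).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mixture = config.mixture
    names, probs = _component_tables(mixture)
    choice = rng.choice(len(names), size=config.n_genomes, p=probs)

    classes = np.zeros(config.n_genomes, dtype=np.int64)
    for idx, name in enumerate(names):
        sel = choice == idx
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        if name == "bg":
            classes[sel] = rng.integers(0, mixture.L, size=n_sel)
        elif name == "S":
            classes[sel] = _sample_step_classes(mixture.step, n_sel, rng)
        else:
            comp = mixture.poissons[int(name[1:]) - 1]
            classes[sel] = comp.k0 + rng.poisson(comp.lam, size=n_sel)

    low = np.where(classes == 0, MIN_GENES, classes * CLASS_WIDTH + 1)
    high = (classes + 1) * CLASS_WIDTH
    return rng.integers(low, high + 1)


def sample_sizes(
    gene_counts: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sizes on the model curve with log-normal scatter, floored at ``s0``.

    Draws below the minimal size are resampled (up to a fixed number of
    rounds, then clamped), so the output never undercuts ``s0``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = np.asarray(gene_counts)
    params = config.size_params
    if np.any(counts < params.g0):
        raise ValueError(f"gene counts must be >= g0 = {params.g0}")
    base = s_of_g(counts.astype(float), params)
    sizes = base * 10.0 ** rng.normal(0.0, config.size_noise_sigma, counts.shape)
    for _ in range(100):
        bad = sizes < params.s0
        if not bad.any():
            break
        sizes[bad] = base[bad] * 10.0 ** rng.normal(
            0.0, config.size_noise_sigma, int(bad.sum())
        )
    np.maximum(sizes, params.s0, out=sizes)
    return np.rint(sizes).astype(np.int64)


def split_gene_types(
    gene_counts: np.ndarray,
    sizes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split each genome's genes into (protein-coding, pseudogene, non-coding).

    The extensive share of each genome follows the cumulative
    extensive-fraction series of the size model over the sampled gene
    counts, perturbed by Gaussian noise; it is realized as pc + ps genes
    (ps a fixed small proportion) and the remainder as non-coding.  The
    three integers sum exactly to the total.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = np.asarray(gene_counts, dtype=np.int64)
    order = np.argsort(counts, kind="stable")

    probe = [
        GenomeRecord.build("probe", "probe", int(g), 0, 0, int(s))
        for g, s in zip(counts[order], np.asarray(sizes)[order])
    ]
    series = cumulative_extensive_fraction(probe, config.size_params)
    share = np.empty(len(counts))
    share[order] = series.ge_over_g

    share = np.clip(
        share + rng.normal(0.0, config.fraction_noise_sigma, share.shape), 0.0, 1.0
    )
    extensive = np.rint(share * counts).astype(np.int64)
    ps = np.rint(PS_SHARE * extensive).astype(np.int64)
    pc = extensive - ps
    nc = counts - extensive
    return pc, ps, nc


def _domain_label(total_genes: int) -> Domain:
    # Coarse, deliberately schematic labels: prokaryote-sized gene counts
    # below ~7500 genes, eukaryote-sized above.  Metadata only; no
    # computation in the package consumes the label.
    return Domain.BACTERIA if total_genes <= 7_500 else Domain.EUKARYOTA


def generate_records(config: SimulationConfig) -> list[GenomeRecord]:
    """Simulate a full set of genome records (in-memory form of the table)."""
    rng = np.random.default_rng(config.seed)
    counts = sample_gene_counts(config, rng)
    sizes = sample_sizes(counts, config, rng)
    pc, ps, nc = split_gene_types(counts, sizes, config, rng)
    return [
        GenomeRecord.build(
            assembly_name=f"SYN{i:06d}.1",
            organism_name=f"Synthetica simulata {i}",
            total_genes=int(counts[i]),
            pc_genes=int(pc[i]),
            ps_genes=int(ps[i]),
            size_bp=int(sizes[i]),
            domain=_domain_label(int(counts[i])),
        )
        for i in range(config.n_genomes)
    ]


def generate_table(config: SimulationConfig, path: str | Path) -> list[GenomeRecord]:
    """Simulate a genome table and write it in the NCBI summary dialect."""
    records = generate_records(config)
    write_genome_table(records, path)
    return records
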