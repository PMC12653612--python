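import numpy as np
import pytest

from genomestats import (
    BinnedDensity,
    GenomeRecord,
    published_mixture_params,
    published_size_params,
)
from genomestats.mixture import mixture_mass_grid


@pytest.fixture(scope="session")
def reference_mixture():
    return published_mixture_params()


@pytest.fixture(scope="session")
def reference_size():
    return published_size_params()


@pytest.fixture(scope="session")
def reference_density(reference_mixture):
    """Noise-free class density generated exactly from the reference mixture."""
    mass = mixture_mass_grid(reference_mixture, 200)
    n_total = 25_975
    return BinnedDensity(
        axis="gene_number",
        interval=500.0,
        class_labels=np.arange(200.0) * 500,
        counts=np.rint(mass * 500 * n_total).astype(np.int64),
        density=mass / 500.0,
        n_total=n_total,
    )


@pytest.fixture
def small_records():
    """A handful of hand-sized genome records."""
    return [
        GenomeRecord.build("ASM001.1", "Minimalis prima", 149, 140, 2, 140_000),
        GenomeRecord.build("ASM002.1", "Bacterium medium", 3_200, 3_000, 100, 3_300_000),
        GenomeRecord.build("ASM003.1", "Bacterium grande", 6_477, 6_000, 200, 7_000_000),
        GenomeRecord.build("ASM004.1", "Eukaryon modicum", 21_000, 18_000, 900, 1_500_000_000),
        GenomeRecord.build("ASM005.1", "Planta magna", 40_000, 28_000, 2_000, 4_000_000_000,
                           domain="Eukaryota"),
    ]
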