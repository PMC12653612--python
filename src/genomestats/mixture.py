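"""The bg5Ps mixture model of the gene-number density, and a geometric baseline.

The density of genomes over 500-gene classes is modelled as a linear
combination of seven components:

* ``bg`` — a uniform background, mass ``1/L`` on classes ``0 <= k < L``;
* ``P1 .. P5`` — shifted Poisson distributions: component ``i`` places mass
  ``lambda_i**(k - k0_i) * exp(-lambda_i) / (k - k0_i)!`` on classes
  ``k >= k0_i``.  Each Poisson component is read as one group of genomes
  evolving at rate ``lambda_i`` along the class axis, having started at
  class ``k0_i``;
* ``S`` — a step input: a flat plateau of length ``L_s`` classes followed by
  exponential decay at rate ``gamma``, normalized by ``L_s + 1/gamma``
  (the continuous-time normalizer).  It is read as a group that leaves
  replicas behind as it advances, fading after the plateau.

The mixture value at class ``k`` is

    m[k] = a_bg * bg[k] + sum_i a_i * P_i[k] + a_s * S[k]

and the density per gene is ``m[k] / 500``.  Coefficients are not
constrained to sum to one; the published reference fit sums to ~0.9923 and
is evaluated as printed.

The geometric baseline ``f_g0 * q**k`` is the naive every-genome-spawns-q
model whose explosive growth the mixture replaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import stats

__all__ = [
    "PoissonComponent",
    "StepParams",
    "MixtureParams",
    "GeometricParams",
    "COMPONENT_ORDER",
    "published_mixture_params",
    "poisson_component",
    "step_component",
    "background_component",
    "evaluate_mixture",
    "decompose",
    "dominant_component",
    "step_mean",
    "geometric_model",
    "rate_summary",
]

# Fixed component order: deterministic tie-breaking and reporting.
COMPONENT_ORDER = ("bg", "P1", "P2", "P3", "P4", "P5", "S")

#: Genes per class in the reference analysis; density per gene = mass / CLASS_WIDTH.
CLASS_WIDTH = 500


@dataclass(frozen=True)
class PoissonComponent:
    """One shifted Poisson component: coefficient, rate, and start class."""

    a: float
    lam: float
    k0: int

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("coefficient must be non-negative")
        if self.lam <= 0:
            raise ValueError("Poisson rate must be positive")
        if self.k0 < 0:
            raise ValueError("start class must be non-negative")


@dataclass(frozen=True)
class StepParams:
    """Step-with-exponential-decay component.

    Plateau of value ``1/(L_s + 1/gamma)`` on ``k_start <= k < k_decay``
    with ``k_decay = k_start + L_s``, then decay
    ``exp(-gamma*(k - k_decay)) / (L_s + 1/gamma)`` for ``k >= k_decay``.
    The value is continuous at ``k_decay``.
    """

    a: float
    k_start: int
    L_s: int
    gamma: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("coefficient must be non-negative")
        if self.L_s < 0:
            raise ValueError("plateau length must be non-negative")
        if self.gamma <= 0:
            raise ValueError("decay rate must be positive")

    @property
    def k_decay(self) -> int:
        return self.k_start + self.L_s

    @property
    def plateau_value(self) -> float:
        return 1.0 / (self.L_s + 1.0 / self.gamma)


@dataclass(frozen=True)
class MixtureParams:
    """Full parameter set of the background + Poissons + step mixture."""

    a_bg: float
    L: int
    poissons: tuple[PoissonComponent, ...]
    step: StepParams | None

    def __post_init__(self) -> None:
        if not 0 <= self.a_bg:
            raise ValueError("background coefficient must be non-negative")
        if self.L < 1:
            raise ValueError("background support length must be positive")
        if len(self.poissons) > 5:
            raise ValueError("at most five Poisson components are supported")

    @property
    def coefficients(self) -> dict[str, float]:
        out = {"bg": self.a_bg}
        for i, comp in enumerate(self.poissons, start=1):
            out[f"P{i}"] = comp.a
        if self.step is not None:
            out["S"] = self.step.a
        return out

    @property
    def coefficient_sum(self) -> float:
        return float(sum(self.coefficients.values()))

    # -- flat key/value serialization ------------------------------------

    def to_dict(self) -> dict[str, float | int]:
        out: dict[str, float | int] = {"a_bg": self.a_bg, "L": self.L}
        for i, comp in enumerate(self.poissons, start=1):
            out[f"a_{i}"] = comp.a
            out[f"lambda_{i}"] = comp.lam
            out[f"k0_{i}"] = comp.k0
        if self.step is not None:
            out["a_s"] = self.step.a
            out["k0_s"] = self.step.k_start
            out["L_s"] = self.step.L_s
            out["gamma"] = self.step.gamma
        return out

    @classmethod
    def from_dict(cls, data: dict[str, float | int]) -> "MixtureParams":
        poissons = []
        for i in range(1, 6):
            if f"a_{i}" in data:
                poissons.append(
                    PoissonComponent(
                        a=float(data[f"a_{i}"]),
                        lam=float(data[f"lambda_{i}"]),
                        k0=int(data[f"k0_{i}"]),
                    )
                )
        step = None
        if "a_s" in data:
            step = StepParams(
                a=float(data["a_s"]),
                k_start=int(data["k0_s"]),
                L_s=int(data["L_s"]),
                gamma=float(data["gamma"]),
            )
        return cls(
            a_bg=float(data["a_bg"]),
            L=int(data["L"]),
            poissons=tuple(poissons),
            step=step,
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in self.to_dict().items():
                fh.write(f"{key} = {value!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "MixtureParams":
        data: dict[str, float | int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = float(value.strip())
        return cls.from_dict(data)


@dataclass(frozen=True)
class GeometricParams:
    """Geometric-progression baseline: density f_g0 * q**k at class k."""

    f_g0: float
    q: float

    def __post_init__(self) -> None:
        if self.f_g0 <= 0 or self.q <= 0:
            raise ValueError("f_g0 and q must be positive")


def published_mixture_params() -> MixtureParams:
    """The published reference fit of the mixture to 25,975 genomes.

    Five Poisson groups starting at classes 0, 2, 4, 6, 44 with rates
    6.13–23.09, a step input on classes 30–59 decaying at 0.0457 per class,
    and a flat background of 0.007 over 200 classes.
    """
    return MixtureParams(
        a_bg=0.007000,
        L=200,
        poissons=(
            PoissonComponent(a=0.531584, lam=6.133813, k0=0),
            PoissonComponent(a=0.074895, lam=23.092150, k0=2),
            PoissonComponent(a=0.153836, lam=9.513952, k0=4),
            PoissonComponent(a=0.161564, lam=2.071796, k0=6),
            PoissonComponent(a=0.004509, lam=16.900607, k0=44),
        ),
        step=StepParams(a=0.058909, k_start=30, L_s=29, gamma=0.045683),
    )


# ---------------------------------------------------------------------------
# Component mass functions
# ---------------------------------------------------------------------------


def _check_class(k: object) -> int:
    if isinstance(k, (bool,)) or not isinstance(k, (int, np.integer)):
        raise TypeError(f"class index must be an integer, got {k!r}")
    return int(k)


def poisson_component(k: int, lam: float, k0: int = 0) -> float:
    """Mass of a shifted Poisson at class ``k``: pmf(k - k0; lam), 0 below k0.

    Evaluated through the log-gamma form of the Poisson pmf so that classes
    up to the full 200-class grid (and far beyond) do not overflow the
    factorial.
    """
    k = _check_class(k)
    if lam <= 0:
        raise ValueError("Poisson rate must be positive")
    if k < k0:
        return 0.0
    return float(stats.poisson.pmf(k - k0, lam))


def step_component(k: int, step: StepParams) -> float:
    """Mass of the step-with-decay component at class ``k``."""
    k = _check_class(k)
    if k < step.k_start:
        return 0.0
    if k < step.k_decay:
        return step.plateau_value
    return math.exp(-step.gamma * (k - step.k_decay)) * step.plateau_value


def background_component(k: int, L: int) -> float:
    """Uniform background mass: 1/L on classes 0 <= k < L, else 0."""
    k = _check_class(k)
    if 0 <= k < L:
        return 1.0 / L
    return 0.0


# ---------------------------------------------------------------------------
# Mixture evaluation and decomposition
# ---------------------------------------------------------------------------


def decompose(k: int, params: MixtureParams) -> dict[str, float]:
    """Weighted contribution of every component to the mixture mass at ``k``.

    Keys follow :data:`COMPONENT_ORDER`; the values sum exactly (same
    floating-point additions) to ``evaluate_mixture(k, params)['class_mass']``.
    """
    k = _check_class(k)
    if k < 0:
        raise ValueError("class index must be non-negative")
    parts = {"bg": params.a_bg * background_component(k, params.L)}
    for i, comp in enumerate(params.poissons, start=1):
        parts[f"P{i}"] = comp.a * poisson_component(k, comp.lam, comp.k0)
    if params.step is not None:
        parts["S"] = params.step.a * step_component(k, params.step)
    return parts


def evaluate_mixture(k: int, params: MixtureParams) -> dict[str, float]:
    """Mixture class mass and per-gene density at class ``k``.

    Returns ``{"class_mass": m, "density_per_gene": m / 500}``.
    """
    mass = math.fsum(decompose(k, params).values())
    return {"class_mass": mass, "density_per_gene": mass / CLASS_WIDTH}


def mixture_mass_grid(params: MixtureParams, n_classes: int) -> np.ndarray:
    """Vector of mixture class masses on classes 0 .. n_classes-1."""
    ks = np.arange(n_classes)
    total = np.zeros(n_classes)
    if params.a_bg > 0:
        total[ks < params.L] += params.a_bg / params.L
    for comp in params.poissons:
        total += comp.a * stats.poisson.pmf(ks - comp.k0, comp.lam)
    if params.step is not None:
        s = params.step
        vals = np.zeros(n_classes)
        plateau = (ks >= s.k_start) & (ks < s.k_decay)
        vals[plateau] = s.plateau_value
        tail = ks >= s.k_decay
        vals[tail] = np.exp(-s.gamma * (ks[tail] - s.k_decay)) * s.plateau_value
        total += s.a * vals
    return total


def dominant_component(k: int, params: MixtureParams) -> str:
    """Identity of the component with the largest contribution at class ``k``.

    Ties are broken by the fixed order bg, P1..P5, S.
    """
    parts = decompose(k, params)
    best = "bg"
    best_val = -1.0
    for name in COMPONENT_ORDER:
        if name in parts and parts[name] > best_val:
            best = name
            best_val = parts[name]
    return best


def step_mean(step: StepParams) -> float:
    """Mean class offset of the step input: (L_s^2/2 + 1/gamma)/(L_s + 1/gamma).

    This is the first moment of the continuous plateau-plus-exponential
    profile, used as the step analogue of a Poisson rate.
    """
    inv_gamma = 1.0 / step.gamma
    return (step.L_s**2 / 2.0 + inv_gamma) / (step.L_s + inv_gamma)


def geometric_model(k: int, params: GeometricParams) -> float:
    """Geometric-progression density f_g0 * q**k."""
    return params.f_g0 * params.q ** _check_class(k)


def rate_summary(params: MixtureParams) -> list[tuple[str, float]]:
    """Component rates ordered by start class.

    Poisson components report their rate ``lambda_i``; the step input
    reports its mean offset :func:`step_mean`.
    """
    entries: list[tuple[int, int, str, float]] = []
    for i, comp in enumerate(params.poissons, start=1):
        entries.append((comp.k0, COMPONENT_ORDER.index(f"P{i}"), f"P{i}", comp.lam))
    if params.step is not None:
        entries.append(
            (
                params.step.k_start,
                COMPONENT_ORDER.index("S"),
                "S",
                step_mean(params.step),
            )
        )
    entries.sort(key=lambda item: (item[0], item[1]))
    return [(name, rate) for _, _, name, rate in entries]
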