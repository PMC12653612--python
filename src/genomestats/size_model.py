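"""Genome-size evolution: the extensive/intensive ODE model and its solution.

The model partitions each small change ``dg`` in gene number into extensive
genes (``dg_e``), which add an average length ``l_e`` of sequence each, and
intensive genes (``dg_i``), which add none (nested/overlapping genes):

    ds      = l_e * dg_e
    dg_e    = (1 - l_e/l_emax) * dg
    l_e(s)  = a*(s - s0) + l_e0

with ``l_emax`` the ceiling on the extensive-gene length.  Substituting and
passing to the continuous limit gives the logistic-type ODE

    s'(g) = a*((s - s0) + b) * (1 - c*((s - s0) + b)),
    b = l_e0/a,  c = a/l_emax

whose closed-form solution through the minimal genome ``(g0, s0)`` is

    s(g) = A*e^{a(g-g0)} / (1 + B*e^{a(g-g0)}) - A/(1+B) + s0,
    A = b/(1 - b*c),  B = b*c/(1 - b*c).

``s(g)`` rises from ``s0`` and saturates at ``s0 + A/B - A/(1+B)``: genome
growth is self-limiting because new genes get longer (up to ``l_emax``) while
their extensive fraction ``1 - l_e/l_emax`` shrinks to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .density import BinnedDensity
from .genome_table import GenomeRecord
from .mixture import CLASS_WIDTH, MixtureParams, mixture_mass_grid

__all__ = [
    "SizeModelParams",
    "TransformParams",
    "SizeFitResult",
    "published_size_params",
    "derive_params",
    "s_of_g",
    "le_of_s",
    "dge_fraction",
    "fit_size_model",
    "transform_density",
]


@dataclass(frozen=True)
class SizeModelParams:
    """Fitted and derived parameters of the size-evolution model.

    ``A`` (bp), ``B`` (dimensionless) and ``a`` (per gene) are the fitted
    shape parameters; ``g0`` (genes) and ``s0`` (bp) anchor the curve at the
    minimal genome.  ``b``, ``c``, ``le0`` and ``lemax`` are derived:
    ``b = A/(1+B)``, ``c = B/A``, ``le0 = a*b``, ``lemax = a/c``.
    """

    A: float
    B: float
    a: float
    g0: float
    s0: float
    b: float
    c: float
    le0: float
    lemax: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.a <= 0:
            raise ValueError("A, B and a must be positive")
        if not 0.0 < self.b * self.c < 1.0:
            raise ValueError("derived b*c must lie strictly between 0 and 1")

    @property
    def s_max(self) -> float:
        """Saturation size: the supremum of s(g) as g grows without bound."""
        return self.s0 + self.A / self.B - self.A / (1.0 + self.B)

    def to_dict(self) -> dict[str, float]:
        return {
            "A": self.A,
            "B": self.B,
            "a": self.a,
            "g0": self.g0,
            "s0": self.s0,
            "b": self.b,
            "c": self.c,
            "le0": self.le0,
            "lemax": self.lemax,
        }

    def to_file(self, path: str | Path) -> None:
        fitted = {"A", "B", "a", "g0", "s0"}
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in self.to_dict().items():
                tag = "fitted" if key in fitted else "derived"
                fh.write(f"{key} = {value!r}  # {tag}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SizeModelParams":
        data: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = float(value.strip())
        return derive_params(data["A"], data["B"], data["a"], data["g0"], data["s0"])


@dataclass(frozen=True)
class TransformParams:
    """Linear gene-number-to-size transform: s = p1*g, f_s = p2*f_g."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0:
            raise ValueError("p1 and p2 must be positive")


def published_size_params() -> SizeModelParams:
    """The published reference fit of the size model to 25,975 genomes."""
    return derive_params(
        A=5_000_000.26632,
        B=0.00202752763471099,
        a=0.000202289166662222,
        g0=149,
        s0=137_475.095259792,
    )


def derive_params(A: float, B: float, a: float, g0: float, s0: float) -> SizeModelParams:
    """Fill the derived parameters b, c, l_e0, l_emax from the fitted set.

    Raises ``ValueError`` when the fitted set is outside the model's domain
    (A, B, a must be positive, which forces 0 < b*c < 1).
    """
    if A <= 0:
        raise ValueError("A must be positive")
    if B <= 0:
        raise ValueError("B must be positive (B = 0 gives an unbounded model)")
    if a <= 0:
        raise ValueError("a must be positive")
    b = A / (1.0 + B)
    c = B / A
    return SizeModelParams(
        A=A, B=B, a=a, g0=g0, s0=s0, b=b, c=c, le0=a * b, lemax=a / c
    )


def params_from_bc(b: float, c: float, a: float, g0: float, s0: float) -> SizeModelParams:
    """Reconstruct the model from (b, c): A = b/(1-bc), B = bc/(1-bc)."""
    bc = b * c
    if not 0.0 < bc < 1.0:
        raise ValueError("b*c must lie strictly between 0 and 1")
    return derive_params(A=b / (1.0 - bc), B=bc / (1.0 - bc), a=a, g0=g0, s0=s0)


def s_of_g(g, params: SizeModelParams):
    """Model genome size (bp) at gene number ``g``; scalar or array.

    The closed-form solution of the size ODE through ``(g0, s0)``; strictly
    increasing in ``g`` and bounded above by ``params.s_max``.
    """
    g_arr = np.asarray(g, dtype=float)
    if np.any(g_arr < params.g0):
        raise ValueError(f"g must be >= g0 = {params.g0}")
    # exp overflow is benign here: A*e/(1+B*e) -> A/B as e -> inf.
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.exp(params.a * (g_arr - params.g0))
        logistic = np.where(
            np.isinf(e), params.A / params.B, params.A * e / (1.0 + params.B * e)
        )
    out = logistic - params.A / (1.0 + params.B) + params.s0
    return float(out) if np.isscalar(g) else out


def le_of_s(s, params: SizeModelParams, clamp: bool = False):
    """Average extensive-gene length at genome size ``s``: a*(s-s0) + l_e0.

    With ``clamp=True`` the value is capped at ``l_emax`` so the extensive
    fraction stays non-negative for sizes beyond the model's validity range.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < params.s0):
        raise ValueError(f"s must be >= s0 = {params.s0}")
    le = params.a * (s_arr - params.s0) + params.le0
    if clamp:
        le = np.minimum(le, params.lemax)
    return float(le) if np.isscalar(s) else le


def dge_fraction(s, params: SizeModelParams):
    """Fraction of new genes that are extensive at size ``s``: 1 - l_e/l_emax.

    Clamped into [0, 1]; the intensive complement is ``l_e/l_emax``.
    """
    le = le_of_s(s, params, clamp=True)
    frac = 1.0 - le / params.lemax
    return float(frac) if np.isscalar(s) else frac


@dataclass(frozen=True)
class SizeFitResult:
    """Outcome of fitting the size model to (gene number, size) pairs."""

    params: SizeModelParams
    rmse: float
    relative_error: float
    converged: bool
    seed: int
    loss_scale: str


def fit_size_model(
    records: Sequence[GenomeRecord],
    seed: int = 0,
    g0: float | None = None,
    s0: float | None = None,
    loss_scale: str = "raw",
    restarts: int = 8,
) -> SizeFitResult:
    """Fit the closed-form size curve to per-genome (g, s) pairs.

    ``g0`` and ``s0`` default to the minimal genome in the dataset (the
    record with the smallest gene count, size breaking ties).  ``A``, ``B``
    and ``a`` are optimized in log-space by bounded least squares from
    ``restarts`` deterministic multi-starts seeded from data scales; the
    best solution wins.  ``loss_scale`` selects residuals on raw size
    ("raw", default) or log10 size ("log").
    """
    pairs = sorted({(r.total_genes, r.size_bp) for r in records})
    if len(pairs) < 5:
        raise ValueError("need at least 5 distinct (gene number, size) pairs")
    g = np.array([p[0] for p in pairs], dtype=float)
    s = np.array([p[1] for p in pairs], dtype=float)

    if g0 is None or s0 is None:
        minimal = min(records, key=lambda r: (r.total_genes, r.size_bp))
        g0 = float(minimal.total_genes) if g0 is None else g0
        s0 = float(minimal.size_bp) if s0 is None else s0

    keep = g >= g0
    g, s = g[keep], s[keep]
    if loss_scale not in ("raw", "log"):
        raise ValueError("loss_scale must be 'raw' or 'log'")

    s_scale = float(np.max(s))

    def residuals(theta: np.ndarray) -> np.ndarray:
        A, B, a = 10.0 ** theta
        try:
            params = derive_params(A, B, a, g0, s0)
        except ValueError:
            return np.full_like(g, 1e6)
        pred = s_of_g(g, params)
        if loss_scale == "log":
            return np.log10(np.maximum(pred, 1.0)) - np.log10(s)
        return (pred - s) / s_scale

    rng = np.random.default_rng(seed)
    g_span = max(float(np.max(g) - g0), 1.0)
    # Data-scale starting grid: A near the size span, B small-to-moderate,
    # a such that the exponential turns over within the observed gene range.
    base_starts = [
        np.array([math.log10(s_scale), lb, math.log10(f / g_span)])
        for lb in (-3.0, -2.0, -1.0, 0.0)
        for f in (1.0, 5.0)
    ]
    starts = base_starts[: max(restarts, 1)]
    while len(starts) < restarts:
        starts.append(starts[len(starts) % len(base_starts)] + rng.normal(0, 0.5, 3))

    lo = np.array([math.log10(s0) - 2.0, -8.0, math.log10(1.0 / g_span) - 4.0])
    hi = np.array([math.log10(s_scale) + 4.0, 4.0, 0.0])
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol

    A, B, a = 10.0 ** best.x
    params = derive_params(A, B, a, g0, s0)
    resid = s_of_g(g, params) - s
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SizeFitResult(
        params=params,
        rmse=rmse,
        relative_error=rmse / float(np.mean(s)),
        converged=bool(best.success),
        seed=seed,
        loss_scale=loss_scale,
    )


def transform_density(
    fg: BinnedDensity,
    mixture: MixtureParams | None = None,
    p1: float = 1000.0,
    p2: float | None = None,
    observed_fs: BinnedDensity | None = None,
) -> tuple[np.ndarray, np.ndarray, TransformParams]:
    """Map a gene-number density onto the log-size axis via s = p1*g.

    Each gene-number class (label ``g``, density ``f_g``) is placed at
    ``log10(p1*g)`` with density ``p2*f_g``.  The model prediction
    (``mixture`` given) or the empirical densities (``mixture=None``) can be
    transformed.  When ``p2`` is omitted it is calibrated by a single-point
    match of maxima against ``observed_fs``:
    ``p2 = max(observed_fs) / max(f_g)``, which leaves the argmax location
    untouched.

    Returns ``(log10_size, density, TransformParams)``.
    """
    if p1 <= 0:
        raise ValueError("p1 must be positive")
    labels = np.asarray(fg.class_labels, dtype=float)
    if mixture is not None:
        dens = mixture_mass_grid(mixture, len(labels)) / CLASS_WIDTH
    else:
        dens = np.asarray(fg.density, dtype=float)

    # Class 0 has label 0; place it at the class midpoint to keep log finite.
    g_coords = np.where(labels > 0, labels, fg.interval / 2.0)
    log_s = np.log10(p1 * g_coords)

    if p2 is None:
        if observed_fs is None:
            raise ValueError("p2 calibration requires an observed log-size density")
        peak = float(np.max(dens))
        if peak <= 0:
            raise ValueError("cannot calibrate p2 against an all-zero density")
        p2 = float(np.max(observed_fs.density)) / peak
    return log_s, p2 * dens, TransformParams(p1=p1, p2=p2)
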