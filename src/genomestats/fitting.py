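"""Fitting the density models to binned data by RMSE minimization.

The objective throughout is the root-mean-square error between observed and
predicted class densities.  The mixture is fitted by staged component
addition: a constant background first, then shifted Poisson components one
at a time (each initialized at the largest remaining residual shoulder, its
start class searched over a small integer grid), and finally the
step-with-decay input.  Every enlarged model is warm-started from the
smaller model's solution, so the achieved RMSE is non-increasing along the
sequence.  Continuous parameters are optimized with bounded trust-region
least squares; multi-start perturbations guard against local minima.  All
randomness flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .density import BinnedDensity, bin_gene_numbers
from .genome_table import GenomeRecord
from .mixture import (
    GeometricParams,
    MixtureParams,
    PoissonComponent,
    StepParams,
)

__all__ = [
    "FitResult",
    "rmse_objective",
    "fit_mixture",
    "fit_geometric",
    "holdout_validate",
    "HoldoutResult",
]

# Optimizer settings (documented defaults; the objective tolerance and
# iteration cap apply per start).
DEFAULT_RESTARTS = 20
MAX_ITER = 100
OBJ_TOL = 1e-10


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its goodness of fit.

    ``relative_error`` is the RMSE divided by the mean observed density over
    the fitted classes — the fraction the average prediction misses by.
    """

    params: MixtureParams | GeometricParams
    rmse: float
    relative_error: float
    n_components: int
    converged: bool
    seed: int


def rmse_objective(
    observed: BinnedDensity | np.ndarray,
    predicted: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Root-mean-square error between observed and predicted densities.

    ``mask`` restricts the error to a subset of classes (hold-out fitting).
    """
    obs = np.asarray(
        observed.density if isinstance(observed, BinnedDensity) else observed,
        dtype=float,
    )
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted are on different class grids")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != obs.shape:
            raise ValueError("mask does not match the class grid")
        obs, pred = obs[mask], pred[mask]
    if obs.size == 0:
        raise ValueError("no classes to compare")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


# ---------------------------------------------------------------------------
# Fast vectorized component evaluation on a class grid
# ---------------------------------------------------------------------------


def _poisson_pmf_grid(ks: np.ndarray, lam: float, k0: int) -> np.ndarray:
    """Shifted Poisson pmf on integer grid, via log-gamma (overflow-safe)."""
    x = ks - k0
    out = np.zeros(ks.shape, dtype=float)
    valid = x >= 0
    xv = x[valid].astype(float)
    out[valid] = np.exp(xv * np.log(lam) - lam - gammaln(xv + 1.0))
    return out


def _step_grid(ks: np.ndarray, k_start: int, L_s: int, gamma: float) -> np.ndarray:
    plateau_value = 1.0 / (L_s + 1.0 / gamma)
    k_decay = k_start + L_s
    out = np.zeros(ks.shape, dtype=float)
    out[(ks >= k_start) & (ks < k_decay)] = plateau_value
    tail = ks >= k_decay
    out[tail] = np.exp(-gamma * (ks[tail] - k_decay)) * plateau_value
    return out


@dataclass
class _Structure:
    """Integer skeleton of a mixture: start classes and step geometry."""

    k0s: tuple[int, ...]
    step: tuple[int, int] | None  # (k_start, L_s)
    L: int

    @property
    def n_free(self) -> int:
        # a_bg + (a_i, lam_i) per Poisson + (a_s, gamma) if step
        return 1 + 2 * len(self.k0s) + (2 if self.step else 0)


def _unpack(x: np.ndarray, struct: _Structure):
    p = len(struct.k0s)
    a_bg = x[0]
    a_i = x[1 : 1 + p]
    lam_i = x[1 + p : 1 + 2 * p]
    if struct.step:
        a_s, gamma = x[1 + 2 * p], x[2 + 2 * p]
    else:
        a_s, gamma = 0.0, 1.0
    return a_bg, a_i, lam_i, a_s, gamma


def _predict(x: np.ndarray, struct: _Structure, ks: np.ndarray, interval: float) -> np.ndarray:
    a_bg, a_i, lam_i, a_s, gamma = _unpack(x, struct)
    mass = np.where(ks < struct.L, a_bg / struct.L, 0.0)
    for a, lam, k0 in zip(a_i, lam_i, struct.k0s):
        mass = mass + a * _poisson_pmf_grid(ks, lam, k0)
    if struct.step:
        k_start, L_s = struct.step
        mass = mass + a_s * _step_grid(ks, k_start, L_s, gamma)
    return mass / interval


def _bounds(struct: _Structure) -> tuple[np.ndarray, np.ndarray]:
    p = len(struct.k0s)
    lo = [0.0] + [0.0] * p + [1e-2] * p
    hi = [10.0] + [10.0] * p + [400.0] * p
    if struct.step:
        lo += [0.0, 1e-4]
        hi += [10.0, 10.0]
    return np.array(lo), np.array(hi)


def _solve(
    x0: np.ndarray,
    struct: _Structure,
    ks: np.ndarray,
    obs: np.ndarray,
    mask: np.ndarray,
    interval: float,
):
    lo, hi = _bounds(struct)
    x0 = np.clip(x0, lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        return (_predict(x, struct, ks, interval) - obs)[mask]

    return least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        ftol=OBJ_TOL,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=MAX_ITER * (struct.n_free + 1),
    )


def _to_params(x: np.ndarray, struct: _Structure) -> MixtureParams:
    a_bg, a_i, lam_i, a_s, gamma = _unpack(x, struct)
    poissons = tuple(
        PoissonComponent(a=float(a), lam=float(lam), k0=int(k0))
        for a, lam, k0 in sorted(
            zip(a_i, lam_i, struct.k0s), key=lambda t: (t[2], t[1])
        )
    )
    step = None
    if struct.step:
        k_start, L_s = struct.step
        step = StepParams(a=float(a_s), k_start=k_start, L_s=L_s, gamma=float(gamma))
    return MixtureParams(a_bg=float(a_bg), L=struct.L, poissons=poissons, step=step)


def _from_params(params: MixtureParams) -> tuple[np.ndarray, _Structure]:
    k0s = tuple(c.k0 for c in params.poissons)
    step = (params.step.k_start, params.step.L_s) if params.step else None
    struct = _Structure(k0s=k0s, step=step, L=params.L)
    x = [params.a_bg]
    x += [c.a for c in params.poissons]
    x += [c.lam for c in params.poissons]
    if params.step:
        x += [params.step.a, params.step.gamma]
    return np.array(x, dtype=float), struct


def _residual_shoulder(
    x: np.ndarray, struct: _Structure, ks: np.ndarray, obs: np.ndarray,
    mask: np.ndarray, interval: float,
) -> tuple[int, float, float]:
    """Locate the largest unexplained bump: peak class, its height, its mass."""
    resid = np.where(mask, obs - _predict(x, struct, ks, interval), 0.0)
    resid = np.clip(resid, 0.0, None)
    k_peak = int(np.argmax(resid))
    height = float(resid[k_peak])
    # mass of the contiguous positive region around the peak
    thresh = 0.05 * height
    left = k_peak
    while left > 0 and resid[left - 1] > thresh:
        left -= 1
    right = k_peak
    while right < len(resid) - 1 and resid[right + 1] > thresh:
        right += 1
    mass = float(np.sum(resid[left : right + 1]) * interval)
    return k_peak, height, mass


@dataclass
class _Candidate:
    """One member of the structure beam: a solved model and its score."""

    x: np.ndarray
    struct: _Structure
    rmse: float
    converged: bool


def _bump_moments(resid: np.ndarray, k_peak: int, height: float):
    """Weighted mean and variance of the contiguous residual bump at k_peak."""
    thresh = 0.02 * height
    left = k_peak
    while left > 0 and resid[left - 1] > thresh:
        left -= 1
    right = k_peak
    while right < len(resid) - 1 and resid[right + 1] > thresh:
        right += 1
    region = np.arange(left, right + 1)
    w = resid[region]
    total = max(float(w.sum()), 1e-300)
    mu = float((w * region).sum() / total)
    var = float((w * (region - mu) ** 2).sum() / total)
    return mu, var


def _poisson_additions(cand, ks, obs, mask, interval):
    """Trial structures adding one Poisson at the largest residual bump.

    A shifted Poisson has mean k0 + lambda and variance lambda, so the
    bump's weighted moments (mu, v) propose k0 = round(mu - v) and
    lambda = v directly; windows around that proposal and around the raw
    peak cover blended bumps whose moments are inflated by neighbours.
    """
    k_peak, height, mass = _residual_shoulder(
        cand.x, cand.struct, ks, obs, mask, interval
    )
    if height <= 0:
        return
    resid = np.clip(
        np.where(mask, obs - _predict(cand.x, cand.struct, ks, interval), 0.0),
        0.0,
        None,
    )
    mu, var = _bump_moments(resid, k_peak, height)
    k0_moment = int(round(mu - var))
    candidates = set(range(max(0, k0_moment - 3), max(0, k0_moment + 4)))
    candidates.update(range(max(0, k_peak - 4), k_peak + 1))
    candidates.add(0)
    candidates = {k0 for k0 in candidates if k0 <= k_peak}
    p = len(cand.struct.k0s)
    for k0 in sorted(candidates):
        if k0 in cand.struct.k0s:
            continue
        trial = _Structure(
            k0s=cand.struct.k0s + (k0,), step=cand.struct.step, L=cand.struct.L
        )
        lam0 = max(mu - k0, 0.5)
        head = cand.x[: 1 + p]
        lams = cand.x[1 + p : 1 + 2 * p]
        tail = cand.x[1 + 2 * p :]
        for a0 in (max(mass, 1e-6), 1e-9):  # the tiny start keeps nestedness
            yield trial, np.concatenate([head, [a0], lams, [lam0], tail])


def _step_additions(cand, ks, obs, mask, interval):
    """Trial structures adding the plateau+decay input near the residual onset."""
    k_peak, height, mass = _residual_shoulder(
        cand.x, cand.struct, ks, obs, mask, interval
    )
    if height <= 0:
        return
    resid = np.clip(
        np.where(mask, obs - _predict(cand.x, cand.struct, ks, interval), 0.0),
        0.0,
        None,
    )
    first_pos = int(np.argmax(resid > 0.25 * height))
    starts = {max(0, first_pos + d) for d in range(-5, 8)}
    starts.add(max(0, k_peak - 10))
    # coarse global scan over the residual's support: the plateau onset may
    # sit far from the dominant shoulder
    support = np.flatnonzero(resid > 0.02 * height)
    if support.size:
        starts.update(range(int(support[0]), int(support[-1]) + 1, 4))
    for k_start in sorted(starts):
        for L_s in (10, 20, 30, 40, 50):
            trial = _Structure(
                k0s=cand.struct.k0s, step=(k_start, L_s), L=cand.struct.L
            )
            yield trial, np.concatenate([cand.x, [max(mass, 1e-6), 0.05]])


def fit_mixture(
    observed: BinnedDensity,
    n_poisson: int = 5,
    use_step: bool = True,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    init: MixtureParams | None = None,
    mask: np.ndarray | None = None,
    beam_width: int = 3,
    structure_search: bool = True,
) -> FitResult:
    """Fit the background + Poissons (+ step) mixture to a binned density.

    The model is grown one component at a time from a background-only fit.
    A beam of the ``beam_width`` best partial models is kept; at every stage
    each of them tries adding a Poisson component (start class searched on
    an integer grid around the largest residual shoulder) or, if not yet
    present, the step input (onset and plateau length searched the same
    way).  The beam makes the stage at which the step enters part of the
    search rather than a fixed choice.  Each enlarged model is warm-started
    from its parent — including a copy with a vanishing new coefficient —
    so the best achievable RMSE never increases as components are added.
    The winning structure gets a multi-start polish of its continuous
    parameters (``restarts`` perturbed solves) and a +-1 sweep of its
    integer start classes.  ``init`` supplies an optional warm-start
    parameter set that competes with the staged construction.  ``mask``
    (boolean per class) restricts the fitted classes (hold-out).

    With ``structure_search=False`` (requires ``init``) the staged
    construction and all integer moves are skipped: the start classes and
    step geometry of ``init`` are kept and only the continuous parameters
    are re-optimized (multi-start).  This is the mode for refining a known
    or published component structure: alternative structures can fit a
    single histogram realization almost equally well, so a full structure
    search is not guaranteed to return to the structure of ``init``.

    Deterministic for fixed inputs and ``seed``.
    """
    if n_poisson < 0 or n_poisson > 5:
        raise ValueError("n_poisson must be between 0 and 5")
    obs = np.asarray(observed.density, dtype=float)
    n_classes = obs.size
    if n_classes == 0:
        raise ValueError("observed density has no classes")
    ks = np.arange(n_classes)
    interval = float(observed.interval)
    if mask is None:
        mask = np.ones(n_classes, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != obs.shape:
            raise ValueError("mask does not match the class grid")
        if not mask.any():
            raise ValueError("mask excludes every class")

    rng = np.random.default_rng(seed)
    L = n_classes  # background spans the whole fitted grid

    def score(x: np.ndarray, struct: _Structure) -> float:
        return rmse_objective(obs, _predict(x, struct, ks, interval), mask)

    if not structure_search:
        if init is None:
            raise ValueError("structure_search=False requires an init parameter set")
        x_init, struct_init = _from_params(init)
        struct_init = _Structure(k0s=struct_init.k0s, step=struct_init.step, L=L)
        sol = _solve(x_init, struct_init, ks, obs, mask, interval)
        best_x, best_rmse = sol.x, score(sol.x, struct_init)
        for _ in range(max(restarts - 1, 0)):
            x0 = x_init * np.exp(rng.normal(0.0, 0.2, size=x_init.shape))
            sol_r = _solve(x0, struct_init, ks, obs, mask, interval)
            r = score(sol_r.x, struct_init)
            if r < best_rmse - OBJ_TOL:
                best_x, best_rmse = sol_r.x, r
        mean_obs = float(np.mean(obs[mask]))
        return FitResult(
            params=_to_params(best_x, struct_init),
            rmse=best_rmse,
            relative_error=best_rmse / mean_obs if mean_obs > 0 else np.inf,
            n_components=1 + len(struct_init.k0s) + (1 if struct_init.step else 0),
            converged=bool(sol.success),
            seed=seed,
        )

    # Stage 0: background only (closed-form optimum is the masked mean).
    root = _Candidate(
        x=np.array([float(np.mean(obs[mask])) * L * interval]),
        struct=_Structure(k0s=(), step=None, L=L),
        rmse=0.0,
        converged=True,
    )
    root.rmse = score(root.x, root.struct)

    n_stages = n_poisson + (1 if use_step else 0)
    beam = [root]
    for _ in range(n_stages):
        children: list[_Candidate] = []
        for cand in beam:
            trials = []
            if len(cand.struct.k0s) < n_poisson:
                trials.extend(_poisson_additions(cand, ks, obs, mask, interval))
            if use_step and cand.struct.step is None:
                trials.extend(_step_additions(cand, ks, obs, mask, interval))
            for trial, x0 in trials:
                sol = _solve(x0, trial, ks, obs, mask, interval)
                children.append(
                    _Candidate(
                        x=sol.x,
                        struct=trial,
                        rmse=score(sol.x, trial),
                        converged=cand.converged and bool(sol.success),
                    )
                )
        if not children:
            break
        # keep the best few distinct structures; reserve one slot for the
        # best step-free child so a pure-Poisson path survives until the
        # plateau stands out of the residual
        children.sort(key=lambda c: c.rmse)
        beam = []
        seen = set()
        for child in children:
            key = (tuple(sorted(child.struct.k0s)), child.struct.step)
            if key in seen:
                continue
            seen.add(key)
            beam.append(child)
            if len(beam) >= beam_width:
                break
        if use_step and all(c.struct.step is not None for c in beam):
            stepless = [c for c in children if c.struct.step is None]
            if stepless:
                beam[-1] = stepless[0]

    best = min(beam, key=lambda c: c.rmse)
    x, struct, converged = best.x, best.struct, best.converged

    # Optional warm start competes with the staged construction.
    if init is not None:
        x_init, struct_init = _from_params(init)
        struct_init = _Structure(k0s=struct_init.k0s, step=struct_init.step, L=L)
        sol = _solve(x_init, struct_init, ks, obs, mask, interval)
        if score(sol.x, struct_init) < score(x, struct):
            x, struct = sol.x, struct_init

    # Reseed moves: remove one component at a time and re-add it through
    # the residual-guided search; escapes misplaced components that the
    # greedy stages locked in.
    x, struct, converged = _reseed_components(
        x, struct, ks, obs, mask, interval, converged
    )

    # Multi-start polish: perturb continuous parameters, keep the best.
    best_x, best_struct = x, struct
    best_rmse = score(x, struct)
    for _ in range(max(restarts - 1, 0)):
        x0 = x * np.exp(rng.normal(0.0, 0.2, size=x.shape))
        sol = _solve(x0, struct, ks, obs, mask, interval)
        r = score(sol.x, struct)
        if r < best_rmse - OBJ_TOL:
            best_x, best_rmse = sol.x, r

    # Integer refinement: shift each start class by +-1 while it helps.
    best_x, best_struct = _refine_starts(
        best_x, best_struct, ks, obs, mask, interval
    )
    best_rmse = score(best_x, best_struct)

    params = _to_params(best_x, best_struct)
    mean_obs = float(np.mean(obs[mask]))
    return FitResult(
        params=params,
        rmse=best_rmse,
        relative_error=best_rmse / mean_obs if mean_obs > 0 else np.inf,
        n_components=1 + len(best_struct.k0s) + (1 if best_struct.step else 0),
        converged=converged,
        seed=seed,
    )


def _drop_poisson(x: np.ndarray, struct: _Structure, idx: int):
    """Remove Poisson ``idx`` from the parameter vector and structure."""
    p = len(struct.k0s)
    keep = [0] + [1 + j for j in range(p) if j != idx] \
        + [1 + p + j for j in range(p) if j != idx] \
        + list(range(1 + 2 * p, x.size))
    k0s = tuple(k for j, k in enumerate(struct.k0s) if j != idx)
    return x[keep], _Structure(k0s=k0s, step=struct.step, L=struct.L)


def _reseed_components(x, struct, ks, obs, mask, interval, converged):
    """Cyclic remove-and-re-add of every component, keeping improvements."""

    def cost(x_, s_):
        return rmse_objective(obs, _predict(x_, s_, ks, interval), mask)

    best = cost(x, struct)
    for _round in range(3):
        improved = False
        n_targets = len(struct.k0s) + (1 if struct.step else 0)
        for idx in range(n_targets):
            if idx < len(struct.k0s):
                x_red, s_red = _drop_poisson(x, struct, idx)
                adder = _poisson_additions
            else:
                x_red = x[:-2]
                s_red = _Structure(k0s=struct.k0s, step=None, L=struct.L)
                adder = _step_additions
            sol_red = _solve(x_red, s_red, ks, obs, mask, interval)
            parent = _Candidate(
                x=sol_red.x, struct=s_red, rmse=cost(sol_red.x, s_red),
                converged=True,
            )
            for trial, x0 in adder(parent, ks, obs, mask, interval):
                sol = _solve(x0, trial, ks, obs, mask, interval)
                r = cost(sol.x, trial)
                if r < best - OBJ_TOL:
                    x, struct, best = sol.x, trial, r
                    improved = True
        if not improved:
            break
    return x, struct, converged


def _refine_starts(x, struct, ks, obs, mask, interval):
    def cost(x_, s_):
        return rmse_objective(obs, _predict(x_, s_, ks, interval), mask)

    best_x, best_struct, best = x, struct, cost(x, struct)
    improved = True
    sweeps = 0
    while improved and sweeps < 4:
        improved = False
        sweeps += 1
        p = len(best_struct.k0s)
        moves = [
            {idx: delta} for idx in range(p) for delta in (-2, -1, 1, 2)
        ] + [
            {i: di, j: dj}
            for i in range(p)
            for j in range(i + 1, p)
            for di in (-1, 1)
            for dj in (-1, 1)
        ]
        for move in moves:
            k0s = list(best_struct.k0s)
            for idx, delta in move.items():
                k0s[idx] += delta
            if min(k0s) < 0 or len(set(k0s)) < len(k0s):
                continue
            trial = _Structure(
                k0s=tuple(k0s), step=best_struct.step, L=best_struct.L
            )
            sol = _solve(best_x, trial, ks, obs, mask, interval)
            if cost(sol.x, trial) < best - OBJ_TOL:
                best_x, best_struct, best = sol.x, trial, cost(sol.x, trial)
                improved = True
        if best_struct.step:
            for dk, dL in ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, 1), (1, -1)):
                k_start, L_s = best_struct.step
                k_start, L_s = k_start + dk, L_s + dL
                if k_start < 0 or L_s < 1:
                    continue
                trial = _Structure(
                    k0s=best_struct.k0s, step=(k_start, L_s), L=best_struct.L
                )
                sol = _solve(best_x, trial, ks, obs, mask, interval)
                if cost(sol.x, trial) < best - OBJ_TOL:
                    best_x, best_struct, best = sol.x, trial, cost(sol.x, trial)
                    improved = True
    return best_x, best_struct


# ---------------------------------------------------------------------------
# Geometric baseline and hold-out validation
# ---------------------------------------------------------------------------


def fit_geometric(
    observed: BinnedDensity, mask: np.ndarray | None = None
) -> FitResult:
    """Least-squares fit of the geometric model f_g0 * q**k.

    Initialized by log-linear regression on the positive densities, then
    refined by bounded least squares on the density scale.
    """
    obs = np.asarray(observed.density, dtype=float)
    ks = np.arange(obs.size, dtype=float)
    if mask is None:
        mask = np.ones(obs.size, dtype=bool)
    pos = mask & (obs > 0)
    if np.count_nonzero(pos) < 2:
        raise ValueError("need at least 2 classes with positive density")

    slope, intercept = np.polyfit(ks[pos], np.log(obs[pos]), 1)
    x0 = np.array([np.exp(intercept), np.exp(slope)])

    def residuals(x: np.ndarray) -> np.ndarray:
        return (x[0] * x[1] ** ks - obs)[mask]

    sol = least_squares(
        residuals,
        np.clip(x0, 1e-300, None),
        bounds=(np.array([1e-300, 1e-6]), np.array([np.inf, np.inf])),
        ftol=OBJ_TOL,
        xtol=1e-14,
    )
    params = GeometricParams(f_g0=float(sol.x[0]), q=float(sol.x[1]))
    rmse = rmse_objective(obs, sol.x[0] * sol.x[1] ** ks, mask)
    mean_obs = float(np.mean(obs[mask]))
    return FitResult(
        params=params,
        rmse=rmse,
        relative_error=rmse / mean_obs if mean_obs > 0 else np.inf,
        n_components=1,
        converged=bool(sol.success),
        seed=0,
    )


@dataclass(frozen=True)
class HoldoutResult:
    """Refit on a reduced class grid, scored on the excluded classes."""

    refit: FitResult
    excluded_classes: tuple[int, ...]
    mean_relative_error_on_excluded: float


def holdout_validate(
    records: Sequence[GenomeRecord],
    exclude_range: tuple[int, int] | None = (3001, 4500),
    seed: int = 0,
    interval: int = 500,
    max_genes: int = 100_000,
    **fit_kwargs,
) -> HoldoutResult:
    """Refit the mixture with a gene-number range held out, and score it.

    ``exclude_range = (lo, hi)`` must align with class boundaries
    (``lo - 1`` and ``hi`` multiples of the interval).  The default excludes
    genomes of 3001-4500 genes — classes 6, 7 and 8 around the density peak.
    The refit model's predictions on the excluded classes are compared with
    the observed density; per-class relative errors are averaged.
    ``exclude_range=None`` excludes nothing (the refit equals a full fit).
    Extra keyword arguments are forwarded to :func:`fit_mixture`.
    """
    observed = bin_gene_numbers(records, interval=interval, max_genes=max_genes)
    if exclude_range is None:
        excluded: tuple[int, ...] = ()
    else:
        lo, hi = exclude_range
        if lo > hi:
            raise ValueError("exclude_range must be (lo, hi) with lo <= hi")
        if (lo - 1) % interval or hi % interval:
            raise ValueError(
                "exclude_range must align with class boundaries "
                f"(lo-1 and hi multiples of {interval})"
            )
        excluded = tuple(range((lo - 1) // interval, hi // interval))
    mask = np.ones(observed.density.size, dtype=bool)
    if excluded:
        mask[list(excluded)] = False
    if not mask.any():
        raise ValueError("exclusion empties the training grid")

    refit = fit_mixture(observed, seed=seed, mask=mask, **fit_kwargs)
    pred = _predict(*_grid_args(refit.params, observed))
    errors = []
    for k in excluded:
        if observed.density[k] > 0:
            errors.append(
                abs(pred[k] - observed.density[k]) / observed.density[k]
            )
    mean_err = float(np.mean(errors)) if errors else float("nan")
    return HoldoutResult(
        refit=refit,
        excluded_classes=excluded,
        mean_relative_error_on_excluded=mean_err,
    )


def predict_density(params: MixtureParams, observed: BinnedDensity) -> np.ndarray:
    """Model density on the class grid of ``observed``."""
    return _predict(*_grid_args(params, observed))


def _grid_args(params: MixtureParams, observed: BinnedDensity):
    x, struct = _from_params(params)
    ks = np.arange(observed.density.size)
    return x, struct, ks, float(observed.interval)
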