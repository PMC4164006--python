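"""Heterogeneous Rescorla-Wagner model: a population distribution over
(alpha, lambda) estimated from per-animal likelihood surfaces on a grid.

Each animal's binary CR sequence induces a likelihood surface over a grid of
learning parameters.  Summing the surfaces of all animals in a dataset and
normalising yields a population distribution P(alpha, lambda) that expresses
the learning heterogeneity of the group — e.g. a mass of non-learners near
the alpha = 0 / lambda = 0 axes next to a mode of fast, high-asymptote
learners.  Under ``grid_sum`` normalisation the distribution doubles as the
weight vector of a mixture model that can score held-out animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .cr_data import ROLE_CONDITIONING, CRMatrix, filter_spontaneous_responders
from .rw_model import RWParams

NORM_PER_ANIMAL = "per_animal_count"
NORM_GRID_SUM = "grid_sum"


@dataclass(frozen=True)
class ParamGrid:
    """Regular grid over the (alpha, lambda) unit square."""

    alphas: np.ndarray
    lambdas: np.ndarray

    @classmethod
    def regular(cls, spacing: float = 0.1) -> "ParamGrid":
        """Grid with the given spacing, including both endpoints 0 and 1."""
        n = int(round(1.0 / spacing)) + 1
        pts = np.linspace(0.0, 1.0, n)
        return cls(alphas=pts, lambdas=pts.copy())

    def __post_init__(self):
        for name, arr in (("alphas", self.alphas), ("lambdas", self.lambdas)):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
            if arr[0] < 0 or arr[-1] > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
            object.__setattr__(self, name, arr)

    @property
    def shape(self):
        return (self.alphas.size, self.lambdas.size)


@dataclass(frozen=True)
class GridDistribution:
    """Non-negative mass over a parameter grid, rows = alpha, cols = lambda."""

    grid: ParamGrid
    mass: np.ndarray
    normalization: str
    n_animals: int

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != self.grid.shape:
            raise ValueError(f"mass shape {mass.shape} != grid shape {self.grid.shape}")
        if np.any(mass < 0):
            raise ValueError("mass must be non-negative")
        if self.normalization not in (NORM_PER_ANIMAL, NORM_GRID_SUM):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == NORM_GRID_SUM and abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError("grid_sum mass must sum to 1 within 1e-12")
        object.__setattr__(self, "mass", mass)

    def as_grid_sum(self) -> "GridDistribution":
        """Re-normalised copy whose mass sums to exactly 1."""
        total = self.mass.sum()
        if total <= 0:
            raise ValueError("cannot normalise an all-zero mass")
        mass = self.mass / total
        mass = mass / mass.sum()  # kill residual rounding
        return GridDistribution(self.grid, mass, NORM_GRID_SUM, self.n_animals)

    def to_dict(self) -> dict:
        return {
            "alphas": self.grid.alphas.tolist(),
            "lambdas": self.grid.lambdas.tolist(),
            "mass": self.mass.ravel().tolist(),  # row-major
            "normalization": self.normalization,
            "n_animals": self.n_animals,
        }


def _log_surface(
    x: Sequence[int],
    grid: ParamGrid,
    rewarded: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """Log-likelihood of sequence ``x`` at every grid point, vectorised.

    Works in log space throughout so long sequences do not underflow.
    """
    x = np.asarray(x, dtype=float)
    if rewarded is None:
        rewarded = [True] * len(x)
    A = grid.alphas[:, None]
    L = grid.lambdas[None, :]
    v = np.zeros(grid.shape)
    ll = np.zeros(grid.shape)
    with np.errstate(divide="ignore"):
        for t, rew in enumerate(rewarded):
            if x[t] == 1:
                ll += np.log(v)
            else:
                ll += np.log1p(-v)
            if rew:
                v = v + A * (L - v)
    return ll


def likelihood_surface(
    x: Sequence[int],
    grid: ParamGrid,
    rewarded: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """Per-grid-point likelihood (probability, in [0, 1]) of one CR sequence."""
    with np.errstate(invalid="ignore"):
        out = np.exp(_log_surface(x, grid, rewarded))
    return np.nan_to_num(out, nan=0.0)


def population_distribution(
    m: CRMatrix,
    grid: Optional[ParamGrid] = None,
    normalization: str = NORM_PER_ANIMAL,
    *,
    scope: Optional[Iterable[str]] = None,
    exclude_spontaneous: bool = True,
) -> GridDistribution:
    """Sum of per-animal likelihood surfaces, normalised.

    ``per_animal_count`` divides the summed surfaces by the number of animals
    (the reporting convention); ``grid_sum`` divides by the grid total so the
    result is a proper probability mass usable as mixture weights.
    """
    if grid is None:
        grid = ParamGrid.regular()
    if exclude_spontaneous:
        m, _ = filter_spontaneous_responders(m)
    if m.n_animals == 0:
        raise ValueError("no animals to build a population distribution from")
    rewarded = [r == ROLE_CONDITIONING for r in m.trial_roles]
    cols = (
        np.arange(m.n_trials) if scope is None else np.flatnonzero(m.role_mask(scope))
    )
    total = np.zeros(grid.shape)
    # identical rows share a surface; group them
    seqs, counts = np.unique(m.responses[:, cols], axis=0, return_counts=True)
    rew_scoped = [rewarded[j] for j in cols]
    for seq, cnt in zip(seqs, counts):
        total += cnt * likelihood_surface(seq, grid, rew_scoped)
    if normalization == NORM_PER_ANIMAL:
        mass = total / m.n_animals
        return GridDistribution(grid, mass, NORM_PER_ANIMAL, m.n_animals)
    elif normalization == NORM_GRID_SUM:
        raw = GridDistribution(grid, total / max(total.sum(), 1e-300), NORM_PER_ANIMAL, m.n_animals)
        return GridDistribution(grid, raw.mass / raw.mass.sum(), NORM_GRID_SUM, m.n_animals)
    raise ValueError(f"unknown normalization {normalization!r}")


def marginals(d: GridDistribution):
    """(P_alpha, P_lambda): mass summed over the other parameter."""
    return d.mass.sum(axis=1), d.mass.sum(axis=0)


def mixture_loglik(
    x: Sequence[int],
    d: GridDistribution,
    rewarded: Optional[Sequence[bool]] = None,
    clamp: float = 0.0,
) -> float:
    """Log-likelihood of one sequence under the grid mixture (nats).

    Requires a ``grid_sum``-normalised distribution.  Computed with a
    log-sum-exp so tiny component likelihoods do not underflow.  ``clamp``
    bounds each component's per-trial probabilities away from 0/1, which
    keeps held-out scores finite when a grid point assigns probability zero
    to an observed response.
    """
    if d.normalization != NORM_GRID_SUM:
        raise ValueError("mixture_loglik requires grid_sum normalization")
    logl = _log_surface_clamped(x, d.grid, rewarded, clamp)
    with np.errstate(divide="ignore"):
        logw = np.log(d.mass)
    return float(logsumexp(logw + logl))


def _log_surface_clamped(x, grid, rewarded, clamp):
    if clamp <= 0:
        return _log_surface(x, grid, rewarded)
    x = np.asarray(x, dtype=float)
    if rewarded is None:
        rewarded = [True] * len(x)
    A = grid.alphas[:, None]
    L = grid.lambdas[None, :]
    v = np.zeros(grid.shape)
    ll = np.zeros(grid.shape)
    for t, rew in enumerate(rewarded):
        vc = np.clip(v, clamp, 1.0 - clamp)
        ll += np.log(vc) if x[t] == 1 else np.log1p(-vc)
        if rew:
            v = v + A * (L - v)
    return ll


def dataset_mixture_nll(
    m: CRMatrix,
    d: GridDistribution,
    scope: Optional[Iterable[str]] = None,
    clamp: float = 0.0,
) -> float:
    """Total mixture negative log-likelihood of a CR matrix (nats)."""
    rewarded = [r == ROLE_CONDITIONING for r in m.trial_roles]
    cols = (
        np.arange(m.n_trials) if scope is None else np.flatnonzero(m.role_mask(scope))
    )
    rew_scoped = [rewarded[j] for j in cols]
    total = 0.0
    seqs, counts = np.unique(m.responses[:, cols], axis=0, return_counts=True)
    for seq, cnt in zip(seqs, counts):
        total -= cnt * mixture_loglik(seq, d, rew_scoped, clamp=clamp)
    return float(total)


def predicted_curve(d: GridDistribution, n_trials: int) -> np.ndarray:
    """Model-implied group-average CR curve: mixture of RW trajectories."""
    if d.normalization != NORM_GRID_SUM:
        raise ValueError("predicted_curve requires grid_sum normalization")
    A = d.grid.alphas[:, None]
    L = d.grid.lambdas[None, :]
    v = np.zeros(d.grid.shape)
    out = np.empty(n_trials)
    for t in range(n_trials):
        out[t] = float((d.mass * v).sum())
        v = v + A * (L - v)
    return out


def point_mass(grid: ParamGrid, p: RWParams) -> GridDistribution:
    """Degenerate grid distribution concentrated on the nearest grid point."""
    i = int(np.argmin(np.abs(grid.alphas - p.alpha)))
    j = int(np.argmin(np.abs(grid.lambdas - p.lam)))
    mass = np.zeros(grid.shape)
    mass[i, j] = 1.0
    return GridDistribution(grid, mass, NORM_GRID_SUM, 1)
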