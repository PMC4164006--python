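"""Classical (homogeneous) Rescorla-Wagner model for binary CR sequences.

The model tracks an associative strength :math:`v_t` that is updated after
every rewarded conditioning trial by

.. math:: v_{t+1} = v_t + \\alpha (\\lambda - v_t)

with learning rate :math:`\\alpha \\in [0, 1]` and US effectiveness
(asymptote) :math:`\\lambda \\in [0, 1]`, starting from :math:`v_1 = 0` (no
prior associative strength).  The CR probability on trial ``t`` is read
directly as :math:`v_t` — i.e. the strength accrued over all *previous*
trials.  Unrewarded trials (CS-only, retention) read out the current strength
without updating it.

With all trials rewarded the iteration has the closed form

.. math:: v_t = \\lambda (1 - (1-\\alpha)^{t-1}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .cr_data import ROLE_CONDITIONING, CRMatrix, filter_spontaneous_responders

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = 1e-9


@dataclass(frozen=True)
class RWParams:
    """A single (learning rate, US effectiveness) point in the unit square."""

    alpha: float
    lam: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.lam <= 1.0):
            raise ValueError(
                f"RW parameters must lie in [0, 1]^2, got ({self.alpha}, {self.lam})"
            )


@dataclass(frozen=True)
class RWFitResult:
    params: RWParams
    nll: float               # exact (unclamped) negative log-likelihood, nats
    start: RWParams          # grid point used to initialise the optimiser
    n_animals: int
    n_excluded: int          # spontaneous responders removed before fitting
    scope: Optional[tuple] = None
    clamp: float = DEFAULT_CLAMP

    def to_dict(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "lambda": self.params.lam,
            "nll": self.nll,
            "start": {"alpha": self.start.alpha, "lambda": self.start.lam},
            "n_animals": self.n_animals,
            "n_excluded": self.n_excluded,
            "scope": None if self.scope is None else list(self.scope),
            "clamp": self.clamp,
        }


def rw_trajectory(p: RWParams, n_trials: int) -> np.ndarray:
    """Associative strengths v_1..v_T under all-rewarded conditioning trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    v = np.empty(n_trials)
    v[0] = 0.0
    for t in range(1, n_trials):
        v[t] = v[t - 1] + p.alpha * (p.lam - v[t - 1])
    return v


def trial_probabilities(p: RWParams, rewarded: Sequence[bool]) -> np.ndarray:
    """Per-trial CR probabilities for an arbitrary rewarded/unrewarded schedule.

    ``rewarded[t]`` says whether trial t ends in a US; only rewarded trials
    update the associative strength.  The probability on trial t is the
    strength *before* that trial's update.
    """
    v = 0.0
    out = np.empty(len(rewarded))
    for t, rew in enumerate(rewarded):
        out[t] = v
        if rew:
            v = v + p.alpha * (p.lam - v)
    return out


def sequence_loglik(
    x: Sequence[int],
    p: RWParams,
    rewarded: Optional[Sequence[bool]] = None,
    clamp: float = 0.0,
) -> float:
    """Bernoulli log-likelihood (nats) of one binary CR sequence.

    Uses the 0*log(0) = 0 convention; an impossible observation (e.g. a
    response on trial 1, where v_1 = 0) yields ``-inf`` unless ``clamp > 0``,
    in which case probabilities are clamped to [clamp, 1-clamp].
    """
    x = np.asarray(x, dtype=float)
    if rewarded is None:
        rewarded = [True] * len(x)
    v = trial_probabilities(p, rewarded)
    if clamp > 0:
        v = np.clip(v, clamp, 1.0 - clamp)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x == 1, np.log(v), np.log1p(-v))
    # 0*log 0: a term only counts when its observation occurred
    if np.any(np.isneginf(terms)):
        return float("-inf")
    return float(terms.sum())


def _scoped_columns(m: CRMatrix, scope: Optional[Iterable[str]]) -> np.ndarray:
    if scope is None:
        return np.arange(m.n_trials)
    return np.flatnonzero(m.role_mask(scope))


def dataset_nll(
    m: CRMatrix,
    p: RWParams,
    scope: Optional[Iterable[str]] = None,
    clamp: float = 0.0,
) -> float:
    """Total negative log-likelihood of a CR matrix under one (alpha, lambda).

    All animals share the same predicted probability per trial, so the sum
    reduces to per-trial response counts.  ``scope`` restricts which trial
    roles are scored; the associative-strength dynamics always follow the full
    trial sequence.  With ``clamp=0`` an impossible observation makes the
    result ``+inf`` (the offending animal ids are logged).
    """
    rewarded = [r == ROLE_CONDITIONING for r in m.trial_roles]
    v = trial_probabilities(p, rewarded)
    cols = _scoped_columns(m, scope)
    if cols.size == 0 or m.n_animals == 0:
        return 0.0
    v = v[cols]
    s = m.responses[:, cols].sum(axis=0).astype(float)
    n = float(m.n_animals)
    if clamp > 0:
        v = np.clip(v, clamp, 1.0 - clamp)
    else:
        bad_one = (v == 0.0) & (s > 0)
        bad_zero = (v == 1.0) & (s < n)
        if np.any(bad_one) or np.any(bad_zero):
            offenders = set()
            for jj in np.flatnonzero(bad_one):
                offenders.update(
                    m.animal_ids[i]
                    for i in np.flatnonzero(m.responses[:, cols[jj]] == 1)
                )
            for jj in np.flatnonzero(bad_zero):
                offenders.update(
                    m.animal_ids[i]
                    for i in np.flatnonzero(m.responses[:, cols[jj]] == 0)
                )
            logger.warning(
                "dataset_nll is +inf; impossible observations for animals %s",
                sorted(offenders),
            )
            return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(s > 0, s * np.log(v), 0.0) + np.where(
            n - s > 0, (n - s) * np.log1p(-v), 0.0
        )
    return float(-ll.sum())


def fit_homogeneous(
    m: CRMatrix,
    scope: Optional[Iterable[str]] = None,
    k_grid: float = 0.1,
    *,
    exclude_spontaneous: bool = True,
    clamp: float = DEFAULT_CLAMP,
) -> RWFitResult:
    """Maximum-likelihood (alpha, lambda) for a whole dataset.

    Initialisation is a grid search over [0, 1]^2 at spacing ``k_grid``
    (default 0.1), followed by bounded L-BFGS-B refinement within the unit
    square.  Ties on the grid are broken towards the lexicographically
    smallest (alpha, lambda).  The optimiser works on the clamped objective;
    the reported ``nll`` is exact (unclamped) and may be ``+inf`` if
    impossible observations remain.
    """
    n_excluded = 0
    if exclude_spontaneous:
        kept, removed = filter_spontaneous_responders(m)
        n_excluded = removed.n_animals
        if n_excluded:
            logger.info("fit_homogeneous: excluded %d spontaneous responders", n_excluded)
        m = kept
    if m.n_animals == 0:
        raise ValueError("no animals left to fit after exclusions")

    grid = np.round(np.arange(0.0, 1.0 + 1e-12, k_grid), 12)
    best = None
    for a in grid:
        for lam in grid:
            val = dataset_nll(m, RWParams(float(a), float(lam)), scope, clamp=clamp)
            key = (val, float(a), float(lam))
            if best is None or key < best:
                best = key
    start = RWParams(best[1], best[2])

    def objective(theta):
        return dataset_nll(
            m, RWParams(float(theta[0]), float(theta[1])), scope, clamp=clamp
        )

    res = minimize(
        objective,
        x0=[start.alpha, start.lam],
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
    )
    cand = RWParams(float(np.clip(res.x[0], 0, 1)), float(np.clip(res.x[1], 0, 1)))
    # never report a point worse than the grid start
    if objective([cand.alpha, cand.lam]) > best[0]:
        cand = start
    exact_nll = dataset_nll(m, cand, scope, clamp=0.0)
    return RWFitResult(
        params=cand,
        nll=exact_nll,
        start=start,
        n_animals=m.n_animals,
        n_excluded=n_excluded,
        scope=None if scope is None else tuple(scope),
        clamp=clamp,
    )
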