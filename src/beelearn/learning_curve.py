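"""Parametric regression of the group-average learning curve and the
decomposition of its maximum into individual-learning parameters.

The group-average CR probabilities across trials are fitted by

.. math:: p(CR) = a (1 - e^{-b (t - 1)}) + c (t - 1)

with amplitude ``a``, rate ``b`` (per trial) and linear slope ``c``.  Both
terms vanish at t = 1, so the curve is structurally zero on the first trial.
The maximum of the fitted curve over the trial range, ``p_max`` at trial time
``t_max``, is the quantity usually called the learning asymptote.  The
decomposition check compares it with

.. math:: p_{max} \\approx CR_{stability} \\cdot (1 - N_{nonresponders}/N),

i.e. the asymptote of the group curve reflects the proportion of responding
animals modulated by how reliably they respond — not a performance asymptote
of any individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .cr_data import ROLE_CONDITIONING, CRMatrix
from .descriptive_stats import average_cr_curve, cr_stability

BOUNDS_A = (0.0, 1.0)
BOUNDS_B = (0.0, 10.0)
BOUNDS_C = (-1.0, 1.0)


@dataclass(frozen=True)
class LearningCurveFit:
    a: float
    b: float
    c: float
    p_max: float
    t_max: float
    sse: float
    trials: tuple            # 1-based trial times used for the fit
    fit_scope: str = "conditioning"

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "p_max": self.p_max,
            "t_max": self.t_max,
            "sse": self.sse,
            "fit_scope": self.fit_scope,
            "trials": list(self.trials),
        }


def curve_eval(a: float, b: float, c: float, t) -> np.ndarray:
    """Evaluate the regression curve at trial time(s) ``t`` (1-based)."""
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-b * (t - 1.0))) + c * (t - 1.0)


def fit_learning_curve(
    p: Sequence[float], trials: Optional[Sequence[float]] = None
) -> LearningCurveFit:
    """Bounded least-squares fit of (a, b, c) to per-trial CR fractions.

    Deterministic multi-start: a coarse 5x5x5 grid over the parameter box
    (a in [0,1], b in [0,10], c in [-1,1]) seeds bounded trust-region
    least-squares runs; the lowest SSE wins, ties going to the smallest
    (b, |c|, a).  Needs at least 3 points for the 3 free parameters.
    """
    p = np.asarray(p, dtype=float)
    if trials is None:
        trials = np.arange(1, p.size + 1, dtype=float)
    else:
        trials = np.asarray(trials, dtype=float)
    if p.size != trials.size:
        raise ValueError("p and trials must have equal length")
    if p.size < 3:
        raise ValueError("need at least 3 points to fit 3 parameters")

    def residuals(theta):
        return curve_eval(*theta, trials) - p

    lo = np.array([BOUNDS_A[0], BOUNDS_B[0], BOUNDS_C[0]])
    hi = np.array([BOUNDS_A[1], BOUNDS_B[1], BOUNDS_C[1]])
    candidates = []
    for a0 in np.linspace(*BOUNDS_A, 5):
        for b0 in np.linspace(*BOUNDS_B, 5):
            for c0 in np.linspace(*BOUNDS_C, 5):
                res = least_squares(
                    residuals,
                    x0=[a0, b0, c0],
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
                sse = float(np.sum(res.fun**2))
                a, b, c = (float(v) for v in res.x)
                candidates.append((sse, b, abs(c), a, (a, b, c)))
                # keep the raw start too: trf nudges boundary starts off the
                # bounds, which would otherwise lose exact degenerate optima
                sse0 = float(np.sum(residuals([a0, b0, c0]) ** 2))
                candidates.append((sse0, b0, abs(c0), a0, (a0, b0, c0)))

    best_sse = min(c[0] for c in candidates)
    # ties (within numerical noise) resolved toward smallest (b, |c|, a)
    tied = [c for c in candidates if c[0] <= best_sse + 1e-12]
    tied.sort(key=lambda c: (c[1], c[2], c[3]))
    a, b, c = tied[0][4]
    sse = tied[0][0]

    t_lo, t_hi = float(trials.min()), float(trials.max())
    p_max, t_max = curve_max(a, b, c, (t_lo, t_hi))
    return LearningCurveFit(
        a=a, b=b, c=c, p_max=p_max, t_max=t_max, sse=sse,
        trials=tuple(float(t) for t in trials),
    )


def curve_max(
    a: float, b: float, c: float, t_range: Tuple[float, float]
) -> Tuple[float, float]:
    """(p_max, t_max): continuous maximum of the curve over ``t_range``.

    The curve's second derivative is -a b^2 e^{-b(t-1)} <= 0, so for a, b >= 0
    it is concave: the maximum is either the stationary point
    t* = 1 + ln(a b / -c) / b (when c < 0 and t* falls inside the range) or a
    range boundary.
    """
    t_lo, t_hi = float(t_range[0]), float(t_range[1])
    candidates = [t_lo, t_hi]
    if c < 0 and a > 0 and b > 0 and a * b > -c:
        t_star = 1.0 + np.log(a * b / (-c)) / b
        if t_lo < t_star < t_hi:
            candidates.append(float(t_star))
    vals = [float(curve_eval(a, b, c, t)) for t in candidates]
    i = int(np.argmax(vals))
    return vals[i], candidates[i]


def curve_max_bruteforce(
    a: float, b: float, c: float, t_range: Tuple[float, float], n_grid: int = 10_000
) -> Tuple[float, float]:
    """Independent numerical oracle for :func:`curve_max`.

    Dense grid search followed by a bounded scalar refinement around the best
    grid point.  Used in validation, never on the analysis path.
    """
    t_lo, t_hi = float(t_range[0]), float(t_range[1])
    ts = np.linspace(t_lo, t_hi, n_grid)
    vals = curve_eval(a, b, c, ts)
    i = int(np.argmax(vals))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, n_grid - 1)]
    if hi - lo <= 0:
        return float(vals[i]), float(ts[i])
    res = minimize_scalar(
        lambda t: -curve_eval(a, b, c, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_best = float(res.x)
    cands = [(float(curve_eval(a, b, c, t)), float(t)) for t in (t_best, t_lo, t_hi)]
    return max(cands, key=lambda v: v[0])


@dataclass(frozen=True)
class DecompositionResult:
    p_max: float
    predicted: float
    error: float             # signed: p_max - predicted
    cr_stability: float
    nonresponder_fraction: float


def fit_average_curve(m: CRMatrix, include_retention: bool = False) -> LearningCurveFit:
    """Fit the regression curve to a matrix's group-average CR probabilities.

    By default only conditioning trials enter the fit; pass
    ``include_retention=True`` to fit through every trial.
    """
    if include_retention:
        cols = np.arange(m.n_trials)
        scope_label = "all"
    else:
        cols = np.flatnonzero(m.role_mask({ROLE_CONDITIONING}))
        scope_label = "conditioning"
    curve = average_cr_curve(m)[cols]
    trials = (cols + 1).astype(float)
    fit = fit_learning_curve(curve, trials)
    return LearningCurveFit(
        a=fit.a, b=fit.b, c=fit.c, p_max=fit.p_max, t_max=fit.t_max,
        sse=fit.sse, trials=fit.trials, fit_scope=scope_label,
    )


def decomposition_check(
    m: CRMatrix, include_retention: bool = False
) -> DecompositionResult:
    """Compare the fitted curve maximum with stability x responder fraction.

    Both the curve fit and the stability/non-responder terms use the same
    retention-inclusion scope.  Raises :class:`ValueError` via the stability
    computation when no animal contributes (undefined stability).
    """
    fit = fit_average_curve(m, include_retention)
    report = cr_stability(m, include_retention=include_retention)
    if report.overall_stability is None:
        raise ValueError("CR stability undefined: no contributing animals")
    predicted = report.overall_stability * (1.0 - report.nonresponder_fraction)
    return DecompositionResult(
        p_max=fit.p_max,
        predicted=predicted,
        error=fit.p_max - predicted,
        cr_stability=report.overall_stability,
        nonresponder_fraction=report.nonresponder_fraction,
    )
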