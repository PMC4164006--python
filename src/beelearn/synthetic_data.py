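"""Synthetic CR-matrix generator with the statistical structure the analysis
assumes: a heterogeneous population of Rescorla-Wagner learners.

Each simulated animal carries its own (alpha, lambda); given those, its
responses are independent Bernoulli draws with per-trial probability equal
to the associative strength v_t.  Heterogeneity across animals — in
particular a non-learner subpopulation with lambda = 0 — is what produces
the serial dependence, first-response latency spread and non-responder mass
seen in real conditioning data.  Retention trials read out the post-training
strength without updating it (no extinction from the unrewarded CS).

Population kinds
----------------
* ``point``          — every animal shares one (alpha, lambda),
* ``two_component``  — non-learners (lambda = 0, alpha ~ U[0,1]) with
                       probability ``nonlearner_fraction``, otherwise a fixed
                       learner (alpha, lambda),
* ``beta_product``   — alpha and lambda drawn from independent Beta laws,
* ``explicit_grid``  — draws from a grid-sum-normalised GridDistribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cr_data import (
    ROLE_CONDITIONING,
    ROLE_RETENTION,
    CRHistory,
    CRMatrix,
    build_cr_matrix,
)
from .rw_heterogeneous import NORM_GRID_SUM, GridDistribution
from .rw_model import RWParams, rw_trajectory


@dataclass(frozen=True)
class PopulationSpec:
    kind: str
    point: Optional[RWParams] = None
    nonlearner_fraction: float = 0.0
    learner_params: Optional[RWParams] = None
    beta_shapes: Optional[Tuple[float, float, float, float]] = None  # (a_alpha, b_alpha, a_lam, b_lam)
    explicit: Optional[GridDistribution] = None

    def __post_init__(self):
        if self.kind == "point":
            if self.point is None:
                raise ValueError("point population requires 'point' parameters")
        elif self.kind == "two_component":
            if self.learner_params is None:
                raise ValueError("two_component population requires learner_params")
            if not 0.0 <= self.nonlearner_fraction <= 1.0:
                raise ValueError("nonlearner_fraction must be in [0, 1]")
        elif self.kind == "beta_product":
            if self.beta_shapes is None or len(self.beta_shapes) != 4:
                raise ValueError("beta_product requires 4 shape parameters")
            if any(s <= 0 for s in self.beta_shapes):
                raise ValueError("beta shapes must be positive")
        elif self.kind == "explicit_grid":
            if self.explicit is None:
                raise ValueError("explicit_grid requires a GridDistribution")
            if self.explicit.normalization != NORM_GRID_SUM:
                raise ValueError("explicit grid must be grid_sum normalised")
        else:
            raise ValueError(f"unknown population kind {self.kind!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    kind: str = "fixed_trials"
    n_conditioning: int = 6
    retention: bool = False
    max_trials: int = 6

    def __post_init__(self):
        if self.kind not in ("fixed_trials", "stop_at_first_cr"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_conditioning < 1 or self.max_trials < 1:
            raise ValueError("trial counts must be >= 1")


def sample_parameters(
    spec: PopulationSpec, n: int, seed: int
) -> List[RWParams]:
    """Draw n per-animal (alpha, lambda) pairs from a population spec."""
    rng = np.random.default_rng(seed)
    if spec.kind == "point":
        return [spec.point] * n
    if spec.kind == "two_component":
        out = []
        for _ in range(n):
            if rng.random() < spec.nonlearner_fraction:
                # convention: non-learners have lambda = 0, alpha uninformative
                out.append(RWParams(float(rng.random()), 0.0))
            else:
                out.append(spec.learner_params)
        return out
    if spec.kind == "beta_product":
        aa, ba, al, bl = spec.beta_shapes
        alphas = rng.beta(aa, ba, size=n)
        lams = rng.beta(al, bl, size=n)
        return [RWParams(float(a), float(l)) for a, l in zip(alphas, lams)]
    if spec.kind == "explicit_grid":
        d = spec.explicit
        flat = d.mass.ravel()
        idx = rng.choice(flat.size, size=n, p=flat)
        ii, jj = np.unravel_index(idx, d.mass.shape)
        return [
            RWParams(float(d.grid.alphas[i]), float(d.grid.lambdas[j]))
            for i, j in zip(ii, jj)
        ]
    raise AssertionError("unreachable")


def simulate_cr_matrix(
    params: Sequence[RWParams], protocol: ProtocolSpec, seed: int
) -> CRMatrix:
    """Bernoulli CR matrix for a fixed-trials protocol.

    Trial t of animal i is 1 with probability v_t from that animal's RW
    trajectory; an optional retention trial uses the post-training strength
    v_{T+1} with no update from the unrewarded presentation.
    """
    if protocol.kind != "fixed_trials":
        raise ValueError("simulate_cr_matrix handles fixed_trials protocols only; "
                         "use simulate_stop_at_first_cr for adaptive protocols")
    rng = np.random.default_rng(seed)
    n = len(params)
    t_cond = protocol.n_conditioning
    k = t_cond + (1 if protocol.retention else 0)
    probs = np.empty((n, k))
    for i, p in enumerate(params):
        v = rw_trajectory(p, t_cond + 1)  # includes post-training strength
        probs[i, :t_cond] = v[:t_cond]
        if protocol.retention:
            probs[i, t_cond] = v[t_cond]
    responses = (rng.random((n, k)) < probs).astype(np.int8)
    roles = [ROLE_CONDITIONING] * t_cond + (
        [ROLE_RETENTION] if protocol.retention else []
    )
    return build_cr_matrix(responses, roles)


def simulate_stop_at_first_cr(
    params: Sequence[RWParams], max_trials: int, seed: int
) -> List[CRHistory]:
    """Adaptive protocol: condition each animal until its first CR.

    Rewarded trials are simulated sequentially and stop after the first
    response (or at ``max_trials``), yielding histories from
    {01, 001, ..., 00...0}.
    """
    if max_trials < 2:
        raise ValueError("max_trials must be >= 2")
    rng = np.random.default_rng(seed)
    histories = []
    for p in params:
        v = rw_trajectory(p, max_trials)
        tokens = []
        for t in range(max_trials):
            r = int(rng.random() < v[t])
            tokens.append((r, True))
            if r == 1:
                break
        histories.append(CRHistory(tokens=tuple(tokens)))
    return histories


def simulate_durations(
    m: CRMatrix, mean_s: float = 3.0, dispersion: Optional[float] = None,
    seed: int = 0,
) -> np.ndarray:
    """Positive integer response durations (1-s resolution) where CR = 1.

    Durations follow a shifted geometric law on {1, 2, ...} with the given
    mean; passing ``dispersion`` (a shape parameter r > 0) switches to a
    shifted negative-binomial with the same mean, approaching a point mass
    as r grows.  Cells with no response are NaN (missing).
    """
    if mean_s <= 0:
        raise ValueError("mean_s must be positive")
    rng = np.random.default_rng(seed)
    out = np.full(m.responses.shape, np.nan)
    mask = m.responses == 1
    n_draw = int(mask.sum())
    if n_draw:
        if dispersion is None:
            p = min(1.0, 1.0 / mean_s)
            draws = rng.geometric(p, size=n_draw)
        else:
            r = float(dispersion)
            p = r / (r + max(mean_s - 1.0, 1e-12))
            draws = 1 + rng.negative_binomial(r, p, size=n_draw)
        out[mask] = draws.astype(float)
    return out


def simulate_grs(
    params: Sequence[RWParams], noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Gustatory response scores linked to the learning asymptote.

    GRS = round(10 * lambda + Gaussian noise), clamped to [0, 10]; at zero
    noise the score is a monotone function of lambda.  A deliberately simple
    link used to exercise GRS subgrouping, with no claim of physiological
    fidelity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lams = np.array([p.lam for p in params])
    raw = 10.0 * lams + rng.normal(0.0, noise_sd, size=lams.size)
    return np.clip(np.rint(raw), 0, 10).astype(np.int64)
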