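"""Individual-learning descriptive statistics for binary CR matrices.

Three parameters disentangle individual learning from the group-average
learning curve:

1. the fraction of non-responders (animals with no CR in any trial),
2. the first-response latency ``t_firstCR`` (1-based trial index), and
3. the CR stability — how persistently animals keep responding once they
   have responded for the first time.

CR stability is computed per first-CR subgroup as the unweighted mean of the
conditional probabilities p(x_t = 1 | t_firstCR = j) over later trials
t > j, and aggregated across subgroups by a size-weighted mean.  Neither
non-responders nor animals whose first CR falls on the last included trial
contribute.

The module also provides retention scores by subgroup and the binary and
duration-based discrimination indices used in retention tests with a novel
odorant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .cr_data import (
    ROLE_CONDITIONING,
    ROLE_RETENTION,
    CRMatrix,
    first_cr_trials,
    history_of_animal,
)


class EmptySubgroupError(ValueError):
    """Requested a conditional curve for a first-CR subgroup with no animals."""


class UndefinedStatisticError(ValueError):
    """A statistic has no contributing animals (e.g. stability of an
    all-non-responder dataset)."""


@dataclass(frozen=True)
class SubgroupStability:
    first_cr: int
    conditional_probs: tuple          # over trials t > first_cr, in trial order
    stability: float                  # unweighted mean of conditional_probs
    size: int


@dataclass(frozen=True)
class StabilityReport:
    """CR stability and companion individual-learning parameters.

    ``overall_stability`` is the subgroup-size-weighted mean of the per-
    subgroup stabilities, or None when no subgroup contributes.
    ``mean_first_cr`` averages t_firstCR over responders only.
    """

    per_subgroup: Dict[int, SubgroupStability]
    overall_stability: Optional[float]
    nonresponder_count: int
    nonresponder_fraction: float
    mean_first_cr: Optional[float]
    n_animals: int
    include_retention: bool = True

    @property
    def weights(self) -> Dict[int, int]:
        return {j: s.size for j, s in self.per_subgroup.items()}

    def to_dict(self) -> dict:
        d = {
            "cr_stability": self.overall_stability,
            "mean_t_first_cr": self.mean_first_cr,
            "nonresponder_fraction": self.nonresponder_fraction,
            "nonresponder_count": self.nonresponder_count,
            "n_animals": self.n_animals,
            "include_retention": self.include_retention,
            "subgroups": {
                str(j): {
                    "stability": s.stability,
                    "size": s.size,
                    "conditional_probs": list(s.conditional_probs),
                }
                for j, s in sorted(self.per_subgroup.items())
            },
        }
        s2 = self.per_subgroup.get(2)
        d["cr_stability_t2"] = None if s2 is None else s2.stability
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        lines = ["first_cr\tsize\tstability\tconditional_probs"]
        for j, s in sorted(self.per_subgroup.items()):
            probs = ",".join(f"{p:.6g}" for p in s.conditional_probs)
            lines.append(f"{j}\t{s.size}\t{s.stability:.6g}\t{probs}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DiscriminationInput:
    """Per-animal responses (and optional durations) to the trained CS and a
    novel odorant in a retention test."""

    x_cs: np.ndarray
    x_new: np.ndarray
    d_cs: Optional[np.ndarray] = None
    d_new: Optional[np.ndarray] = None

    def __post_init__(self):
        x_cs = np.asarray(self.x_cs)
        x_new = np.asarray(self.x_new)
        if x_cs.shape != x_new.shape or x_cs.ndim != 1:
            raise ValueError("x_cs and x_new must be 1-D of equal length")
        if not (np.isin(x_cs, (0, 1)).all() and np.isin(x_new, (0, 1)).all()):
            raise ValueError("responses must be 0/1")
        object.__setattr__(self, "x_cs", x_cs.astype(np.int8))
        object.__setattr__(self, "x_new", x_new.astype(np.int8))
        for name, d, x in (("d_cs", self.d_cs, x_cs), ("d_new", self.d_new, x_new)):
            if d is None:
                continue
            d = np.asarray(d, dtype=float)
            if d.shape != x_cs.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(np.isnan(d) != (x == 0)):
                raise ValueError(f"{name} must be missing exactly where the response is 0")
            object.__setattr__(self, name, d)

    @property
    def n(self) -> int:
        return self.x_cs.size

    def swapped(self) -> "DiscriminationInput":
        return DiscriminationInput(self.x_new, self.x_cs, self.d_new, self.d_cs)


# ---------------------------------------------------------------------------


def _scope_columns(m: CRMatrix, include_retention: bool) -> np.ndarray:
    if include_retention:
        return np.arange(m.n_trials)
    return np.flatnonzero(m.role_mask({ROLE_CONDITIONING}))


def average_cr_curve(m: CRMatrix) -> np.ndarray:
    """Group-average learning curve: fraction of animals responding per trial."""
    if m.n_animals == 0:
        raise ValueError("cannot average an empty matrix")
    return m.responses.mean(axis=0)


def conditional_response_curve(
    m: CRMatrix, j: int, include_retention: bool = True
) -> np.ndarray:
    """p(x_t = 1 | t_firstCR = j) for all included trials t > j.

    ``j`` is 1-based.  Raises :class:`EmptySubgroupError` when no animal has
    its first CR on trial ``j`` (an empty subgroup is not a zero curve).
    """
    cols = _scope_columns(m, include_retention)
    scope = None if include_retention else {ROLE_CONDITIONING}
    firsts = first_cr_trials(m, scope)
    members = [i for i, f in enumerate(firsts) if f == j]
    if not members:
        raise EmptySubgroupError(f"no animals with first CR on trial {j}")
    later = cols[cols > (j - 1)]
    return m.responses[np.ix_(members, later)].mean(axis=0)


def cr_stability(m: CRMatrix, include_retention: bool = True) -> StabilityReport:
    """CR stability report with subgroup detail (see module docstring).

    ``include_retention=False`` restricts the analysis to conditioning trials
    only (roles other than ``conditioning`` are ignored entirely).
    """
    if m.n_animals == 0:
        raise ValueError("empty matrix")
    cols = _scope_columns(m, include_retention)
    scope = None if include_retention else {ROLE_CONDITIONING}
    firsts = first_cr_trials(m, scope)

    nonresponders = sum(1 for f in firsts if f is None)
    responders = [f for f in firsts if f is not None]
    mean_first = float(np.mean(responders)) if responders else None

    last_trial = int(cols[-1]) + 1  # 1-based position of last included trial
    per_subgroup: Dict[int, SubgroupStability] = {}
    for j in sorted({f for f in responders if f != last_trial}):
        probs = conditional_response_curve(m, j, include_retention)
        size = sum(1 for f in firsts if f == j)
        per_subgroup[j] = SubgroupStability(
            first_cr=j,
            conditional_probs=tuple(float(p) for p in probs),
            stability=float(np.mean(probs)),
            size=size,
        )

    if per_subgroup:
        sizes = np.array([s.size for s in per_subgroup.values()], dtype=float)
        stabs = np.array([s.stability for s in per_subgroup.values()])
        overall = float((sizes * stabs).sum() / sizes.sum())
    else:
        overall = None

    return StabilityReport(
        per_subgroup=per_subgroup,
        overall_stability=overall,
        nonresponder_count=nonresponders,
        nonresponder_fraction=nonresponders / m.n_animals,
        mean_first_cr=mean_first,
        n_animals=m.n_animals,
        include_retention=include_retention,
    )


def first_cr_histogram(m: CRMatrix, scope=None) -> Dict[Optional[int], int]:
    """Counts of first-CR trial indices; key ``None`` is the non-responder bucket."""
    firsts = first_cr_trials(m, scope)
    hist: Dict[Optional[int], int] = {}
    for f in firsts:
        hist[f] = hist.get(f, 0) + 1
    return hist


def retention_by_group(
    m: CRMatrix, grouping="by_history"
) -> Dict[str, Tuple[Optional[float], int]]:
    """Fraction responding on the (first) retention trial, per animal group.

    ``grouping`` is one of
    * ``"by_history"`` — group by the training-phase CR-history string,
    * ``"responders_vs_nonresponders"`` — any CR during the training phase?
    * a custom mapping label -> sequence of animal indices (a partition).

    Empty groups report ``(None, 0)``.
    """
    ret_cols = m.retention_columns
    if ret_cols.size == 0:
        raise ValueError("matrix has no retention trial")
    ret = m.responses[:, int(ret_cols[0])]

    groups: Dict[str, list] = {}
    if grouping == "by_history":
        for i in range(m.n_animals):
            key = str(history_of_animal(m, i))
            groups.setdefault(key, []).append(i)
    elif grouping == "responders_vs_nonresponders":
        first_ret = int(ret_cols[0])
        training = m.responses[:, :first_ret]
        for i in range(m.n_animals):
            key = "responders" if training[i].any() else "non_responders"
            groups.setdefault(key, []).append(i)
    else:
        groups = {str(k): list(v) for k, v in dict(grouping).items()}

    out: Dict[str, Tuple[Optional[float], int]] = {}
    for key, idx in groups.items():
        if not idx:
            out[key] = (None, 0)
        else:
            out[key] = (float(ret[idx].mean()), len(idx))
    return out


def discrimination_index(d: DiscriminationInput) -> float:
    """Binary discrimination index: mean of (x_cs - x_new) over animals."""
    if d.n == 0:
        raise ValueError("empty discrimination input")
    return float((d.x_cs.astype(int) - d.x_new.astype(int)).mean())


def discrimination_index_duration(d: DiscriminationInput) -> float:
    """Duration-based discrimination index.

    Per animal the term is (d_cs - d_new) / max(d_cs, d_new), treating a
    missing duration (no response) as 0 in the numerator and denominator.
    Animals with no response to either stimulus carry no duration at all and
    are excluded from the average.
    """
    if d.d_cs is None or d.d_new is None:
        raise ValueError("durations required for the duration-based index")
    dcs = np.nan_to_num(d.d_cs, nan=0.0)
    dnew = np.nan_to_num(d.d_new, nan=0.0)
    contributing = (d.x_cs == 1) | (d.x_new == 1)
    if not contributing.any():
        raise UndefinedStatisticError("no animal responded to either stimulus")
    denom = np.maximum(dcs, dnew)[contributing]
    num = (dcs - dnew)[contributing]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return float(terms.mean())
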