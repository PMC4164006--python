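"""Cross-validated comparison of the homogeneous and heterogeneous
Rescorla-Wagner models.

For each fold of a k-fold split (default k = 4) both models are fitted on
the training animals — the homogeneous model by maximum likelihood, the
heterogeneous model as the grid-sum-normalised population distribution used
as mixture weights — and scored by the total negative log-likelihood of the
held-out animals.  The model with the lower total held-out NLL wins; exact
ties go to the homogeneous model (parsimony).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cr_data import CRMatrix, filter_spontaneous_responders
from .rw_model import DEFAULT_CLAMP, fit_homogeneous, dataset_nll
from .rw_heterogeneous import (
    NORM_GRID_SUM,
    ParamGrid,
    dataset_mixture_nll,
    population_distribution,
)

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"


@dataclass(frozen=True)
class FoldResult:
    fold: int
    heldout_nll_homogeneous: float
    heldout_nll_heterogeneous: float
    n_train: int
    n_test: int


@dataclass(frozen=True)
class CVReport:
    per_fold: Tuple[FoldResult, ...]
    total_nll_homogeneous: float
    total_nll_heterogeneous: float
    winner: str
    k: int
    seed: int
    n_animals: int
    n_excluded: int
    scoring: str = "heldout_mixture_nll"

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {
                    "fold": f.fold,
                    "heldout_nll_homogeneous": f.heldout_nll_homogeneous,
                    "heldout_nll_heterogeneous": f.heldout_nll_heterogeneous,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                }
                for f in self.per_fold
            ],
            "total_nll_homogeneous": self.total_nll_homogeneous,
            "total_nll_heterogeneous": self.total_nll_heterogeneous,
            "winner": self.winner,
            "k": self.k,
            "seed": self.seed,
            "n_animals": self.n_animals,
            "n_excluded": self.n_excluded,
            "scoring": self.scoring,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def kfold_split(n: int, k: int, seed: int) -> List[np.ndarray]:
    """Disjoint random folds covering range(n), sizes differing by at most 1."""
    if n < k:
        raise ValueError(f"cannot split {n} animals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start:start + size]))
        start += size
    return folds


def crossval_compare(
    m: CRMatrix,
    k: int = 4,
    seed: int = 0,
    scope: Optional[Iterable[str]] = None,
    *,
    grid: Optional[ParamGrid] = None,
    clamp: float = DEFAULT_CLAMP,
    exclude_spontaneous: bool = True,
) -> CVReport:
    """Four-fold (by default) cross-validated model comparison.

    Spontaneous responders are excluded before splitting, consistent with
    the fitting defaults.  Held-out sequences are scored with per-trial
    probabilities clamped to [clamp, 1-clamp] for both models, so a single
    boundary probability cannot produce an infinite score.
    """
    if grid is None:
        grid = ParamGrid.regular()
    n_excluded = 0
    if exclude_spontaneous:
        m, removed = filter_spontaneous_responders(m)
        n_excluded = removed.n_animals
    n = m.n_animals
    folds = kfold_split(n, k, seed)

    per_fold = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if train_idx.size == 0:
            raise ValueError(f"fold {fold_i} has no training animals")
        train = m.select_animals(train_idx)
        test = m.select_animals(test_idx)

        hom = fit_homogeneous(
            train, scope, exclude_spontaneous=False, clamp=clamp
        )
        nll_hom = dataset_nll(test, hom.params, scope, clamp=clamp)

        het = population_distribution(
            train, grid, NORM_GRID_SUM, scope=scope, exclude_spontaneous=False
        )
        nll_het = dataset_mixture_nll(test, het, scope, clamp=clamp)

        per_fold.append(
            FoldResult(
                fold=fold_i,
                heldout_nll_homogeneous=float(nll_hom),
                heldout_nll_heterogeneous=float(nll_het),
                n_train=train.n_animals,
                n_test=test.n_animals,
            )
        )

    tot_hom = float(sum(f.heldout_nll_homogeneous for f in per_fold))
    tot_het = float(sum(f.heldout_nll_heterogeneous for f in per_fold))
    winner = HETEROGENEOUS if tot_het < tot_hom else HOMOGENEOUS
    return CVReport(
        per_fold=tuple(per_fold),
        total_nll_homogeneous=tot_hom,
        total_nll_heterogeneous=tot_het,
        winner=winner,
        k=k,
        seed=seed,
        n_animals=n,
        n_excluded=n_excluded,
    )


def tabulate_scores(
    reports: Sequence[CVReport], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Score table across datasets: per-dataset total held-out NLLs with a
    win flag per model, plus a final 'Score' row of win counts."""
    if labels is None:
        labels = [str(i + 1) for i in range(len(reports))]
    rows = []
    wins_hom = wins_het = 0
    for label, rep in zip(labels, reports):
        flag_hom = int(rep.winner == HOMOGENEOUS)
        flag_het = int(rep.winner == HETEROGENEOUS)
        wins_hom += flag_hom
        wins_het += flag_het
        rows.append(
            {
                "dataset": label,
                "nll_homogeneous": rep.total_nll_homogeneous,
                "win_homogeneous": flag_hom,
                "nll_heterogeneous": rep.total_nll_heterogeneous,
                "win_heterogeneous": flag_het,
            }
        )
    rows.append(
        {
            "dataset": "Score",
            "nll_homogeneous": np.nan,
            "win_homogeneous": wins_hom,
            "nll_heterogeneous": np.nan,
            "win_heterogeneous": wins_het,
        }
    )
    return pd.DataFrame(rows)
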