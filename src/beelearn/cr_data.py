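"""Binary conditioned-response (CR) matrices: data model, CSV I/O, CR-history
notation, filtering and trial-wise permutation surrogates.

The universal input of the package is a matrix of 0/1 conditioned responses,
one row per animal and one column per trial.  Each trial carries a role:

* ``conditioning`` — a rewarded CS–US pairing,
* ``cs_only``      — an unrewarded CS presentation during the training phase,
* ``retention``    — an unrewarded CS presentation used as a memory test.

Optional per-response durations (seconds; recorded only when the response
occurred), a per-animal gustatory response score (GRS, 0–10) and free-form
metadata travel with the matrix.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ROLE_CONDITIONING = "conditioning"
ROLE_CS_ONLY = "cs_only"
ROLE_RETENTION = "retention"
VALID_ROLES = (ROLE_CONDITIONING, ROLE_CS_ONLY, ROLE_RETENTION)

# header tokens accepted when reading / emitted when writing
_ROLE_ALIASES = {
    "cond": ROLE_CONDITIONING,
    "conditioning": ROLE_CONDITIONING,
    "cs": ROLE_CS_ONLY,
    "cs_only": ROLE_CS_ONLY,
    "ret": ROLE_RETENTION,
    "retention": ROLE_RETENTION,
}
_ROLE_TOKENS = {
    ROLE_CONDITIONING: "cond",
    ROLE_CS_ONLY: "cs_only",
    ROLE_RETENTION: "retention",
}


class CRDataError(ValueError):
    """Base class for CR-matrix validation and parsing errors."""


class ShapeMismatchError(CRDataError):
    """Inconsistent dimensions between responses and companion fields."""


class NonBinaryResponseError(CRDataError):
    """A response entry is not exactly 0 or 1."""


class DurationMismatchError(CRDataError):
    """Durations present/absent inconsistently with the 0/1 responses."""


class RoleError(CRDataError):
    """Invalid trial-role sequence."""


class GRSError(CRDataError):
    """Invalid gustatory response score covariate."""


class HistoryParseError(CRDataError):
    """Malformed CR-history string."""


class CSVFormatError(CRDataError):
    """Malformed CR-matrix CSV file."""


@dataclass(frozen=True)
class CRMatrix:
    """Animals x trials binary CR matrix with trial roles and covariates.

    Attributes
    ----------
    responses : (N, K) int array of 0/1 entries.
    trial_roles : length-K tuple of trial roles.
    animal_ids : length-N tuple of unique labels.
    durations : optional (N, K) float array; NaN marks "no duration recorded"
        and must coincide exactly with ``responses == 0``.
    grs : optional length-N int array of gustatory response scores in [0, 10].
    meta : free-form mapping (e.g. ``iti_minutes``, ``retention_delay_hours``,
        ``cs_label``); round-tripped through the CSV writer.
    """

    responses: np.ndarray
    trial_roles: tuple
    animal_ids: tuple
    durations: Optional[np.ndarray] = None
    grs: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    def role_mask(self, roles: Iterable[str]) -> np.ndarray:
        roles = set(roles)
        return np.array([r in roles for r in self.trial_roles], dtype=bool)

    @property
    def conditioning_columns(self) -> np.ndarray:
        return np.flatnonzero(self.role_mask({ROLE_CONDITIONING}))

    @property
    def retention_columns(self) -> np.ndarray:
        return np.flatnonzero(self.role_mask({ROLE_RETENTION}))

    def select_animals(self, indices) -> "CRMatrix":
        """Sub-matrix with the given animal rows, order preserved."""
        indices = np.asarray(indices, dtype=int)
        return CRMatrix(
            responses=self.responses[indices].copy(),
            trial_roles=self.trial_roles,
            animal_ids=tuple(self.animal_ids[i] for i in indices),
            durations=None if self.durations is None else self.durations[indices].copy(),
            grs=None if self.grs is None else self.grs[indices].copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CRMatrix):
            return NotImplemented
        if self.trial_roles != other.trial_roles or self.animal_ids != other.animal_ids:
            return False
        if not np.array_equal(self.responses, other.responses):
            return False
        if (self.durations is None) != (other.durations is None):
            return False
        if self.durations is not None and not np.array_equal(
            self.durations, other.durations, equal_nan=True
        ):
            return False
        if (self.grs is None) != (other.grs is None):
            return False
        if self.grs is not None and not np.array_equal(self.grs, other.grs):
            return False
        return self.meta == other.meta

    __hash__ = None  # mutable arrays inside


@dataclass(frozen=True)
class CRHistory:
    """Per-animal trial-by-trial record: (response, rewarded) tokens.

    The text form writes one digit per trial, wrapping digits of unrewarded
    (CS-only) trials in parentheses: ``"0111"``, ``"0(1)"``.
    """

    tokens: tuple

    def __str__(self) -> str:
        return "".join(
            str(int(r)) if rewarded else f"({int(r)})" for r, rewarded in self.tokens
        )

    @property
    def responses(self) -> tuple:
        return tuple(r for r, _ in self.tokens)

    @property
    def rewarded(self) -> tuple:
        return tuple(w for _, w in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# construction / validation
# ---------------------------------------------------------------------------

def build_cr_matrix(
    responses,
    trial_roles: Sequence[str],
    *,
    animal_ids: Optional[Sequence] = None,
    durations=None,
    grs=None,
    meta: Optional[dict] = None,
) -> CRMatrix:
    """Validate raw arrays and assemble a :class:`CRMatrix`.

    Raises a specific :class:`CRDataError` subclass naming the offending
    row/column on any invariant violation.
    """
    responses = np.asarray(responses)
    if responses.ndim != 2:
        raise ShapeMismatchError(f"responses must be 2-D, got shape {responses.shape}")
    n, k = responses.shape

    bad = np.argwhere(~np.isin(responses, (0, 1)))
    if bad.size:
        r, c = bad[0]
        raise NonBinaryResponseError(
            f"response at row {r}, column {c} is {responses[r, c]!r}; entries must be 0 or 1"
        )
    responses = responses.astype(np.int8)

    trial_roles = tuple(trial_roles)
    if len(trial_roles) != k:
        raise ShapeMismatchError(
            f"{len(trial_roles)} trial roles for {k} trial columns"
        )
    for i, role in enumerate(trial_roles):
        if role not in VALID_ROLES:
            raise RoleError(f"unknown trial role {role!r} at trial {i + 1}")
    if ROLE_CONDITIONING not in trial_roles:
        raise RoleError("at least one trial must have role 'conditioning'")
    ret_cols = [i for i, r in enumerate(trial_roles) if r == ROLE_RETENTION]
    cond_cols = [i for i, r in enumerate(trial_roles) if r == ROLE_CONDITIONING]
    if ret_cols and min(ret_cols) < max(cond_cols):
        raise RoleError("retention trials must come after all conditioning trials")

    if animal_ids is None:
        animal_ids = tuple(f"a{i + 1}" for i in range(n))
    else:
        animal_ids = tuple(str(a) for a in animal_ids)
        if len(animal_ids) != n:
            raise ShapeMismatchError(f"{len(animal_ids)} animal ids for {n} rows")
        if len(set(animal_ids)) != n:
            raise ShapeMismatchError("animal ids must be unique")

    if durations is not None:
        durations = np.asarray(durations, dtype=float)
        if durations.shape != (n, k):
            raise ShapeMismatchError(
                f"durations shape {durations.shape} != responses shape {(n, k)}"
            )
        missing = np.isnan(durations)
        mism = np.argwhere(missing != (responses == 0))
        if mism.size:
            r, c = mism[0]
            what = (
                "duration present where response is 0"
                if responses[r, c] == 0
                else "duration missing where response is 1"
            )
            raise DurationMismatchError(f"{what} at row {r}, column {c}")
        if np.any(durations[~missing] < 0):
            r, c = np.argwhere(~missing & (durations < 0))[0]
            raise DurationMismatchError(f"negative duration at row {r}, column {c}")

    if grs is not None:
        grs = np.asarray(grs)
        if grs.shape != (n,):
            raise GRSError(f"grs shape {grs.shape} != ({n},)")
        if np.any((grs < 0) | (grs > 10)) or not np.issubdtype(grs.dtype, np.integer):
            if not np.issubdtype(grs.dtype, np.integer):
                raise GRSError("grs values must be integers")
            bad_i = int(np.argwhere((grs < 0) | (grs > 10))[0][0])
            raise GRSError(f"grs out of [0, 10] at animal {bad_i}")
        grs = grs.astype(np.int64)

    return CRMatrix(
        responses=responses,
        trial_roles=trial_roles,
        animal_ids=animal_ids,
        durations=durations,
        grs=grs,
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect is fixed: comma-separated, UTF-8, '.' decimal, LF newlines, no
# quoting required.  Header: animal_id[,grs],t1:cond,...,tK:retention.
# Metadata is carried in a single '#meta {json}' comment line.  Durations go
# to a sidecar '<stem>.durations.csv' with header animal_id,d1,...,dK and
# empty cells for missing values.
# ---------------------------------------------------------------------------

def _durations_path(path: Path) -> Path:
    return path.with_name(path.stem + ".durations.csv")


def write_cr_csv(m: CRMatrix, path) -> None:
    """Write ``m`` to ``path`` deterministically (identical bytes on rewrite)."""
    path = Path(path)
    lines = []
    if m.meta:
        lines.append("#meta " + json.dumps(m.meta, sort_keys=True))
    header = ["animal_id"]
    if m.grs is not None:
        header.append("grs")
    header += [f"t{i + 1}:{_ROLE_TOKENS[r]}" for i, r in enumerate(m.trial_roles)]
    lines.append(",".join(header))
    for i, aid in enumerate(m.animal_ids):
        row = [aid]
        if m.grs is not None:
            row.append(str(int(m.grs[i])))
        row += [str(int(v)) for v in m.responses[i]]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")

    if m.durations is not None:
        dlines = ["animal_id," + ",".join(f"d{i + 1}" for i in range(m.n_trials))]
        for i, aid in enumerate(m.animal_ids):
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in m.durations[i]
            ]
            dlines.append(aid + "," + ",".join(cells))
        _durations_path(path).write_text(
            "\n".join(dlines) + "\n", encoding="utf-8", newline="\n"
        )


def read_cr_csv(path) -> CRMatrix:
    """Read a CR matrix written by :func:`write_cr_csv` (round-trip identity).

    A duration sidecar file, if present next to ``path``, is loaded
    automatically.  Errors cite the 1-based line number.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        lineno = 0
        header = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#meta "):
                meta = json.loads(line[len("#meta "):])
                continue
            if line.startswith("#"):
                continue
            cells = next(csv.reader([line]))
            if header is None:
                header = cells
                header_lineno = lineno
            else:
                rows.append((lineno, cells))
    if header is None:
        raise CSVFormatError(f"{path}: no header row found")

    if header[0] != "animal_id":
        raise CSVFormatError(
            f"{path}:{header_lineno}: first header column must be 'animal_id'"
        )
    has_grs = len(header) > 1 and header[1] == "grs"
    first_trial_col = 2 if has_grs else 1
    roles = []
    for j, cell in enumerate(header[first_trial_col:], start=1):
        mobj = re.fullmatch(r"t(\d+):(\w+)", cell)
        if not mobj or int(mobj.group(1)) != j or mobj.group(2) not in _ROLE_ALIASES:
            raise CSVFormatError(
                f"{path}:{header_lineno}: trial column {cell!r} must look like "
                f"'t{j}:cond' with a role annotation"
            )
        roles.append(_ROLE_ALIASES[mobj.group(2)])
    k = len(roles)
    if k == 0:
        raise CSVFormatError(f"{path}:{header_lineno}: no trial columns in header")

    ids, grs_vals, resp = [], [], []
    for lineno, cells in rows:
        if len(cells) != first_trial_col + k:
            raise CSVFormatError(
                f"{path}:{lineno}: expected {first_trial_col + k} cells, got {len(cells)}"
            )
        ids.append(cells[0])
        if has_grs:
            try:
                grs_vals.append(int(cells[1]))
            except ValueError:
                raise CSVFormatError(f"{path}:{lineno}: non-integer grs {cells[1]!r}")
        vals = []
        for j, cell in enumerate(cells[first_trial_col:]):
            if cell not in ("0", "1"):
                raise CSVFormatError(
                    f"{path}:{lineno}: non-binary response {cell!r} in trial {j + 1}"
                )
            vals.append(int(cell))
        resp.append(vals)
    if not resp:
        raise CSVFormatError(f"{path}: no animal rows")

    durations = None
    dpath = _durations_path(path)
    if dpath.exists():
        durations = _read_durations_csv(dpath, ids, k)

    return build_cr_matrix(
        np.array(resp),
        roles,
        animal_ids=ids,
        durations=durations,
        grs=np.array(grs_vals) if has_grs else None,
        meta=meta,
    )


def _read_durations_csv(dpath: Path, ids, k: int) -> np.ndarray:
    durations = np.full((len(ids), k), np.nan)
    with open(dpath, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        expected = ["animal_id"] + [f"d{i + 1}" for i in range(k)]
        if header != expected:
            raise CSVFormatError(f"{dpath}:1: malformed duration header")
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue
            if len(cells) != k + 1:
                raise CSVFormatError(f"{dpath}:{lineno}: ragged row")
            try:
                i = ids.index(cells[0])
            except ValueError:
                raise CSVFormatError(
                    f"{dpath}:{lineno}: unknown animal id {cells[0]!r}"
                )
            for j, cell in enumerate(cells[1:]):
                if cell != "":
                    durations[i, j] = float(cell)
    return durations


# ---------------------------------------------------------------------------
# CR-history notation
# ---------------------------------------------------------------------------

_HISTORY_RE = re.compile(r"[01]|\([01]\)")


def parse_cr_history(text: str) -> CRHistory:
    """Parse a CR-history string such as ``"0111"`` or ``"0(1)"``.

    Plain digits are rewarded conditioning trials; a parenthesised digit is an
    unrewarded CS-only trial.  The leftmost token is trial 1.
    """
    tokens = []
    pos = 0
    while pos < len(text):
        mobj = _HISTORY_RE.match(text, pos)
        if not mobj:
            raise HistoryParseError(
                f"illegal character at position {pos} in {text!r}"
            )
        tok = mobj.group(0)
        if tok.startswith("("):
            tokens.append((int(tok[1]), False))
        else:
            tokens.append((int(tok), True))
        pos = mobj.end()
    if not tokens:
        raise HistoryParseError("empty CR-history string")
    return CRHistory(tokens=tuple(tokens))


def history_of_animal(m: CRMatrix, animal_index: int, *, stop_before_retention: bool = True) -> CRHistory:
    """CR-history of one animal; by default only the training-phase trials
    (everything before the first retention trial)."""
    k = m.n_trials
    if stop_before_retention:
        ret = m.retention_columns
        k = int(ret[0]) if ret.size else k
    tokens = tuple(
        (int(m.responses[animal_index, j]), m.trial_roles[j] == ROLE_CONDITIONING)
        for j in range(k)
    )
    return CRHistory(tokens=tokens)


# ---------------------------------------------------------------------------
# filtering, first responses, permutation, GRS subgroups
# ---------------------------------------------------------------------------

def filter_spontaneous_responders(m: CRMatrix):
    """Split off animals that responded already on the very first trial.

    Returns ``(kept, removed)``; together they partition ``m`` preserving
    animal order.  Mirrors the common exclusion of bees responding to the
    first CS before any CS-US pairing.
    """
    spont = m.responses[:, 0] == 1
    return m.select_animals(np.flatnonzero(~spont)), m.select_animals(np.flatnonzero(spont))


def first_cr_trials(m: CRMatrix, scope: Optional[Iterable[str]] = None):
    """Per-animal 1-based trial index of the first CR, or None.

    ``scope`` restricts which trial roles are scanned (default: all trials,
    including the memory test).  The returned index is the position within
    the *full* trial sequence.  Animals with an all-zero row within scope are
    non-responders and map to None.
    """
    if scope is None:
        mask = np.ones(m.n_trials, dtype=bool)
    else:
        mask = m.role_mask(scope)
    out = []
    cols = np.flatnonzero(mask)
    sub = m.responses[:, cols]
    for row in sub:
        nz = np.flatnonzero(row)
        out.append(int(cols[nz[0]]) + 1 if nz.size else None)
    return out


def permute_within_trials(m: CRMatrix, seed: int) -> CRMatrix:
    """Surrogate matrix: independently permute each trial column across animals.

    Per-trial response counts are exactly preserved, so the group-average
    learning curve is unchanged, while any within-animal serial dependence is
    destroyed.  Durations travel with their responses.  Deterministic under
    ``seed``; columns are permuted left-to-right with a single
    ``numpy.random.default_rng`` (PCG64) generator.
    """
    rng = np.random.default_rng(seed)
    responses = m.responses.copy()
    durations = None if m.durations is None else m.durations.copy()
    n = m.n_animals
    for j in range(m.n_trials):
        perm = rng.permutation(n)
        responses[:, j] = responses[perm, j]
        if durations is not None:
            durations[:, j] = durations[perm, j]
    return CRMatrix(
        responses=responses,
        trial_roles=m.trial_roles,
        animal_ids=m.animal_ids,
        durations=durations,
        grs=None if m.grs is None else m.grs.copy(),
        meta=dict(m.meta),
    )


def subgroup_by_grs(m: CRMatrix, ranges: Sequence[Sequence[int]]):
    """Split animals into subgroups by inclusive GRS intervals.

    ``ranges`` is a list of ``(low, high)`` integer intervals; they must be
    disjoint.  Animals outside every range are dropped (count logged).
    """
    if m.grs is None:
        raise GRSError("matrix has no grs covariate")
    ranges = [(int(lo), int(hi)) for lo, hi in ranges]
    for lo, hi in ranges:
        if lo > hi:
            raise CRDataError(f"empty-by-construction range ({lo}, {hi})")
    for i, (lo1, hi1) in enumerate(ranges):
        for lo2, hi2 in ranges[i + 1:]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise CRDataError(
                    f"overlapping GRS ranges ({lo1},{hi1}) and ({lo2},{hi2})"
                )
    groups = []
    assigned = np.zeros(m.n_animals, dtype=bool)
    for lo, hi in ranges:
        sel = (m.grs >= lo) & (m.grs <= hi)
        assigned |= sel
        groups.append(m.select_animals(np.flatnonzero(sel)))
    dropped = int((~assigned).sum())
    if dropped:
        logger.info("subgroup_by_grs: %d animals outside all ranges dropped", dropped)
    return groups
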