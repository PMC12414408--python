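"""Pedigree handling and the numerator additive relationship matrix.

The additive (numerator) relationship matrix ``A`` holds expected additive
genetic relationships between animals implied by the pedigree: the additive
genetic covariance in the animal model is ``G = A * sigma_u2``.  ``A`` is
built with the tabular method, which also yields inbreeding coefficients on
the diagonal (``a_ii = 1 + F_i``).

Pedigrees are desk-scale here (hundreds to a few thousand animals), so both
``A`` and its inverse are computed dense.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

UNKNOWN = ""


class PedigreeError(ValueError):
    """Raised for malformed or cyclic pedigrees."""


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically sorted pedigree: every known parent precedes its offspring.

    Each record is ``(animal, sire, dam)``; unknown parents are the empty
    string :data:`UNKNOWN` and are treated as unrelated, non-inbred founders.
    """

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for animal, sire, dam in self.records:
            for parent in (sire, dam):
                if parent != UNKNOWN and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {animal!r} not listed before its offspring"
                    )
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            seen.add(animal)

    @property
    def ids(self) -> list[str]:
        return [rec[0] for rec in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions; -1 codes an unknown parent."""
        pos = {a: i for i, a in enumerate(self.ids)}
        out = np.full((self.n, 2), -1, dtype=np.int64)
        for i, (_, sire, dam) in enumerate(self.records):
            if sire != UNKNOWN:
                out[i, 0] = pos[sire]
            if dam != UNKNOWN:
                out[i, 1] = pos[dam]
        return out


@dataclass(frozen=True)
class RelationshipMatrix:
    """Square additive relationship matrix with its animal-id ordering."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        object.__setattr__(self, "values", v)

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids], dtype=np.int64)
        return RelationshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def _normalize_parent(token: str) -> str:
    token = token.strip()
    return UNKNOWN if token in ("", "0") else token


def sort_pedigree(
    records: list[tuple[str, str, str]],
) -> tuple[tuple[str, str, str], ...]:
    """Topologically sort pedigree records (parents before offspring).

    Raises :class:`PedigreeError` on self-parenting or ancestry cycles.
    """
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise PedigreeError(f"duplicate animal id {dup.index[0]!r}")
    known = set(ids)
    # parents absent from the animal column are treated as unknown founders
    cleaned = {
        a: (a, s if s in known else UNKNOWN, d if d in known else UNKNOWN)
        for a, s, d in records
    }
    for a, s, d in cleaned.values():
        if a in (s, d):
            raise PedigreeError(f"animal {a!r} is its own parent")

    # Kahn's algorithm with a heap gives a canonical order (id within wave)
    # independent of the input row order.
    children: dict[str, list[str]] = {a: [] for a in ids}
    pending = {}
    for a, s, d in cleaned.values():
        parents = {p for p in (s, d) if p != UNKNOWN}
        pending[a] = len(parents)
        for p in parents:
            children[p].append(a)
    ready = [a for a, k in pending.items() if k == 0]
    heapq.heapify(ready)
    order: list[tuple[str, str, str]] = []
    while ready:
        a = heapq.heappop(ready)
        order.append(cleaned[a])
        for child in children[a]:
            pending[child] -= 1
            if pending[child] == 0:
                heapq.heappush(ready, child)
    if len(order) != len(ids):
        stuck = sorted(a for a, k in pending.items() if k > 0)
        raise PedigreeError(f"pedigree cycle involving animals {stuck[:5]}")
    return tuple(order)


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV with header ``animal,sire,dam``.

    ``0`` or an empty field marks an unknown parent.  The returned table is
    topologically sorted regardless of the file's row order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns animal,sire,dam; got {list(df.columns)}"
        )
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        animal = str(getattr(row, "animal")).strip()
        if animal in ("", "0"):
            raise PedigreeError(f"line {lineno}: missing animal id")
        records.append(
            (animal, _normalize_parent(str(row.sire)), _normalize_parent(str(row.dam)))
        )
    return PedigreeTable(sort_pedigree(records))


def pedigree_from_arrays(animals, sires, dams) -> PedigreeTable:
    """Build a sorted :class:`PedigreeTable` from parallel id sequences."""
    records = [
        (str(a), _normalize_parent(str(s)), _normalize_parent(str(d)))
        for a, s, d in zip(animals, sires, dams)
    ]
    return PedigreeTable(sort_pedigree(records))


def a_matrix(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix via the tabular method.

    For animal ``i`` with parents ``s, d``:
    ``a_ij = (a_js + a_jd) / 2`` for ``j < i`` and
    ``a_ii = 1 + a_sd / 2`` (so ``a_ii = 1 + F_i``).  Unknown parents
    contribute zero relationship and no inbreeding.
    """
    n = ped.n
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(tuple(ped.ids), A)


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients ``F_i = a_ii - 1``."""
    return np.diag(a_matrix(ped).values) - 1.0


def a_inverse(ped: PedigreeTable) -> RelationshipMatrix:
    """Dense inverse of the numerator relationship matrix.

    Solved by Cholesky factorization; raises :class:`PedigreeError` if A is
    numerically singular.
    """
    A = a_matrix(ped)
    try:
        c, low = cho_factor(A.values)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - A is PD by construction
        raise PedigreeError(f"relationship matrix is singular: {exc}") from exc
    inv = cho_solve((c, low), np.eye(ped.n))
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(tuple(ped.ids), inv)
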