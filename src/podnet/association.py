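"""Gambit-of-the-group dyad counting and the half-weight association index.

Two individuals are considered associated whenever they are identified
in the same group encounter (the "gambit of the group"). For a dyad
(a, b), over the analysed encounter set, X counts encounters containing
both, Ya those containing a but not b, and Yb those containing b but not
a. The half-weight association index

    HWI = X / (X + 0.5 (Ya + Yb))

ranges from 0 (never associated) to 1 (always associated) and is the
standard choice in cetacean photo-ID studies because it down-weights the
bias from incomplete identification within groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import MarkGrade, SightingDatabase

__all__ = [
    "DyadCounts",
    "AssociationMatrix",
    "AnalysisError",
    "half_weight_index",
    "pairwise_counts",
    "association_matrix",
]


class AnalysisError(ValueError):
    """An analysis precondition is not met (e.g. too few individuals)."""


@dataclass(frozen=True)
class DyadCounts:
    """Per-dyad encounter counts for an unordered pair (id_a, id_b)."""

    id_a: str
    id_b: str
    x: int
    y_a: int
    y_b: int

    @property
    def hwi(self) -> float:
        return half_weight_index(self)


def half_weight_index(c: DyadCounts) -> float:
    """HWI = X / (X + 0.5 (Ya + Yb)).

    Returns 1 iff the pair was always together (X > 0, Ya = Yb = 0) and
    0 iff never together (X = 0). A dyad with all three counts zero has
    no defined index; by convention 0.0 is returned (callers that need
    the distinction should test the counts).
    """
    if min(c.x, c.y_a, c.y_b) < 0:
        raise ValueError(f"negative dyad counts for ({c.id_a}, {c.id_b})")
    denom = c.x + 0.5 * (c.y_a + c.y_b)
    if denom == 0:
        return 0.0
    return c.x / denom


def pairwise_counts(db: SightingDatabase, ids: Sequence[str]) -> list[DyadCounts]:
    """Dyad counts for every unordered pair of ``ids``.

    The counting unit is the encounter: each encounter contributes at
    most one to any of X, Ya, Yb for a given dyad.
    """
    ids = list(ids)
    unknown = [i for i in ids if i not in db.individuals]
    if unknown:
        raise KeyError(f"unknown individual id(s): {unknown}")
    if len(set(ids)) != len(ids):
        raise AnalysisError("duplicate ids in analysis subset")
    if len(ids) < 2:
        raise AnalysisError("need at least 2 individuals for dyad counting")
    inc = _incidence(db, ids)
    x = inc @ inc.T
    n = inc.sum(axis=1)
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            xij = int(x[i, j])
            out.append(DyadCounts(ids[i], ids[j], xij, int(n[i]) - xij, int(n[j]) - xij))
    return out


def _incidence(db: SightingDatabase, ids: Sequence[str]) -> np.ndarray:
    """0/1 matrix, individuals x encounters."""
    index = {iid: k for k, iid in enumerate(ids)}
    inc = np.zeros((len(ids), db.n_encounters), dtype=np.int64)
    for j, e in enumerate(db.encounters):
        for iid in e.identified_ids:
            k = index.get(iid)
            if k is not None:
                inc[k, j] = 1
    return inc


@dataclass
class AssociationMatrix:
    """Symmetric HWI matrix over an ordered id list, with dyad counts.

    ``x`` holds pairwise together-counts (diagonal = individual sighting
    counts within the analysed encounter set); ``sightings`` the per-id
    encounter counts. HWI values are kept at full float precision.
    """

    ids: list[str]
    x: np.ndarray
    sightings: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.sightings = np.asarray(self.sightings, dtype=np.int64)
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def hwi_matrix(self) -> np.ndarray:
        """Dense symmetric HWI matrix with a zero diagonal."""
        denom = self.sightings[:, None] + self.sightings[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(denom > 0, 2.0 * self.x / np.where(denom == 0, 1, denom), 0.0)
        np.fill_diagonal(h, 0.0)
        return h

    def counts(self, a: str, b: str) -> DyadCounts:
        i, j = self._index[a], self._index[b]
        if i == j:
            raise KeyError("a dyad needs two distinct individuals")
        xij = int(self.x[i, j])
        return DyadCounts(a, b, xij, int(self.sightings[i]) - xij, int(self.sightings[j]) - xij)

    def hwi(self, a: str, b: str) -> float:
        return half_weight_index(self.counts(a, b))

    def dyads(self) -> list[DyadCounts]:
        return [
            self.counts(self.ids[i], self.ids[j])
            for i in range(self.n)
            for j in range(i + 1, self.n)
        ]

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (d.id_a, d.id_b, d.x, d.y_a, d.y_b, d.hwi)
            for d in self.dyads()
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "X", "Y_a", "Y_b", "HWI"])

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hwi_matrix(), index=self.ids, columns=self.ids)

    def write_long_csv(self, path: Union[str, Path]) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def write_square_csv(self, path: Union[str, Path]) -> None:
        self.to_square_frame().to_csv(path, index_label="id")


def association_matrix(
    db: SightingDatabase,
    grade_filter: Optional[Iterable[MarkGrade]] = None,
    ids: Optional[Sequence[str]] = None,
) -> AssociationMatrix:
    """HWI matrix over a subset of the catalogue.

    ``grade_filter`` restricts the analysis to the given mark grades
    (the conventional network analysis uses permanently marked
    individuals only, so that identities are stable across years); all
    individuals passing the filter are included regardless of sighting
    frequency. ``ids`` gives an explicit subset instead.
    """
    if ids is not None and grade_filter is not None:
        raise AnalysisError("give either grade_filter or ids, not both")
    if ids is None:
        if grade_filter is None:
            ids = sorted(db.individuals)
        else:
            ids = db.ids_with_grade(grade_filter)
    else:
        ids = list(ids)
        unknown = [i for i in ids if i not in db.individuals]
        if unknown:
            raise KeyError(f"unknown individual id(s): {unknown}")
    if len(ids) < 2:
        raise AnalysisError(
            f"association analysis needs >= 2 individuals, got {len(ids)} after filtering"
        )
    inc = _incidence(db, ids)
    return AssociationMatrix(ids=list(ids), x=inc @ inc.T, sightings=inc.sum(axis=1))
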