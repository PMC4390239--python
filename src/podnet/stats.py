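"""Contingency-table statistics for community composition comparisons.

Pearson chi-square (no continuity correction) on r x c count tables,
upper-tail p-values, and Bonferroni-corrected pairwise 2 x 2 tests
between communities on a binary fin-marking feature (permanent vs other
grade, or dorsal-tip damage). Also composition tables of mark severity,
tip damage and resighting rates per community grouping.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import MarkGrade, SightingDatabase, _pct
from .community import UNASSIGNED, CommunityPartition

__all__ = [
    "ContingencyResult",
    "PairwiseTest",
    "PairwiseTestTable",
    "DegenerateTableError",
    "pearson_chi_square",
    "chi_square_upper_tail",
    "community_feature_counts",
    "pairwise_tests_from_counts",
    "pairwise_network_tests",
    "mark_severity_table",
]


class DegenerateTableError(ValueError):
    """A contingency table with a zero row or column margin."""


def chi_square_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability P(X >= x) for a chi-square variate with ``df`` d.f."""
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    return float(sps.chi2.sf(x, df))


@dataclass
class ContingencyResult:
    """Observed/expected tables with the Pearson chi-square statistic."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.to_dict(),
            "expected": self.expected.to_dict(),
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
        }


def pearson_chi_square(
    observed: Union[pd.DataFrame, Sequence[Sequence[int]], np.ndarray],
) -> ContingencyResult:
    """Pearson chi-square test of independence, without continuity correction.

    expected[i, j] = row_i * col_j / N; chi2 = sum (obs - exp)^2 / exp;
    df = (r - 1)(c - 1); p is the chi-square upper tail.

    Raises
    ------
    ValueError
        For negative or non-integer cells, or tables smaller than 2 x 2.
    DegenerateTableError
        If any row or column total is zero.
    """
    if isinstance(observed, pd.DataFrame):
        frame = observed.copy()
    else:
        frame = pd.DataFrame(np.asarray(observed))
    arr = frame.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("cell counts must be integers")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("zero row or column total")
    n = arr.sum()
    expected = np.outer(rows, cols) / n
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    return ContingencyResult(
        observed=frame,
        expected=pd.DataFrame(expected, index=frame.index, columns=frame.columns),
        chi2=chi2,
        df=df,
        p=chi_square_upper_tail(chi2, df),
    )


@dataclass
class PairwiseTest:
    """One 2 x 2 comparison between two communities."""

    label_a: str
    label_b: str
    result: Optional[ContingencyResult]
    untestable: Optional[str] = None
    significant: Optional[bool] = None


@dataclass
class PairwiseTestTable:
    """All pairwise community comparisons with a multiplicity correction.

    ``n_comparisons`` is the Bonferroni denominator (by default, the
    number of pairs actually tested); significance compares each
    full-precision p against ``corrected_alpha``.
    """

    tests: list[PairwiseTest]
    alpha: float
    correction: str
    n_comparisons: int
    corrected_alpha: float
    feature: str = ""

    def get(self, a: str, b: str) -> PairwiseTest:
        for t in self.tests:
            if {t.label_a, t.label_b} == {a, b}:
                return t
        raise KeyError((a, b))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests:
            rows.append(
                {
                    "label_a": t.label_a,
                    "label_b": t.label_b,
                    "chi2": None if t.result is None else t.result.chi2,
                    "df": None if t.result is None else t.result.df,
                    "p": None if t.result is None else t.result.p,
                    "significant": t.significant,
                    "untestable": t.untestable,
                }
            )
        return pd.DataFrame(rows)

    def to_lower_triangular(self, round_to: int = 1) -> pd.DataFrame:
        """Lower-triangular chi2/p layout, one row/column per community."""
        labels = sorted({t.label_a for t in self.tests} | {t.label_b for t in self.tests})
        out = pd.DataFrame("", index=labels[1:], columns=labels[:-1])
        for t in self.tests:
            a, b = sorted((t.label_a, t.label_b))
            if t.result is None:
                cell = f"untestable: {t.untestable}"
            else:
                stat = round(t.result.chi2, round_to)
                cell = f"chi2 = {stat:g}, p = {t.result.p:.3f}"
                if t.significant:
                    cell += " *"
            out.loc[b, a] = cell
        return out

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_lower_triangular().to_csv(path, index_label="network")

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        d = {
            "feature": self.feature,
            "alpha": self.alpha,
            "correction": self.correction,
            "n_comparisons": self.n_comparisons,
            "corrected_alpha": self.corrected_alpha,
            "tests": [
                {
                    "label_a": t.label_a,
                    "label_b": t.label_b,
                    "chi2": None if t.result is None else t.result.chi2,
                    "df": None if t.result is None else t.result.df,
                    "p": None if t.result is None else t.result.p,
                    "significant": t.significant,
                    "untestable": t.untestable,
                }
                for t in self.tests
            ],
        }
        return json.dumps(d, **kwargs)


def community_feature_counts(
    db: SightingDatabase,
    p: CommunityPartition,
    feature: str = "permanent_mark",
) -> pd.DataFrame:
    """Per-community 2-column count table for a binary fin feature.

    ``feature`` is ``"permanent_mark"`` (permanently marked vs other
    grades; requires the extended partition so non-permanent members are
    counted) or ``"tip_damage"``. UNASSIGNED individuals are excluded.
    """
    if feature not in {"permanent_mark", "tip_damage"}:
        raise ValueError(f"unknown feature {feature!r}")
    rows = {}
    for label in p.labels:
        yes = no = 0
        for iid in p.members(label):
            rec = db.individuals[iid]
            flag = (
                rec.mark_grade is MarkGrade.PERMANENT
                if feature == "permanent_mark"
                else rec.tip_damage
            )
            if flag:
                yes += 1
            else:
                no += 1
        rows[label] = (yes, no)
    cols = ["permanent", "other"] if feature == "permanent_mark" else ["tip_damage", "no_tip_damage"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def pairwise_tests_from_counts(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_comparisons_override: Optional[int] = None,
    feature: str = "",
) -> PairwiseTestTable:
    """All unordered pairwise 2 x 2 chi-square tests between table rows.

    ``counts`` has one row per community and two columns of counts.
    Pairs producing a zero margin are reported as untestable rather than
    silently dropped; they do not enter the Bonferroni denominator
    unless ``n_comparisons_override`` fixes it.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in {"bonferroni", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    labels = list(counts.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 communities")
    tests: list[PairwiseTest] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            sub = counts.loc[[a, b]]
            try:
                res = pearson_chi_square(sub)
                tests.append(PairwiseTest(a, b, res))
            except DegenerateTableError as exc:
                tests.append(PairwiseTest(a, b, None, untestable=str(exc)))
    n_tested = sum(1 for t in tests if t.result is not None)
    n_comp = n_comparisons_override if n_comparisons_override is not None else n_tested
    if n_comp < 1:
        raise ValueError("no testable pairs")
    corrected = alpha / n_comp if correction == "bonferroni" else alpha
    for t in tests:
        if t.result is not None:
            t.significant = t.result.p < corrected
    return PairwiseTestTable(
        tests=tests,
        alpha=alpha,
        correction=correction,
        n_comparisons=n_comp,
        corrected_alpha=corrected,
        feature=feature,
    )


def pairwise_network_tests(
    db: SightingDatabase,
    p: CommunityPartition,
    feature: str = "permanent_mark",
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_comparisons_override: Optional[int] = None,
) -> PairwiseTestTable:
    """Pairwise chi-square comparisons of a binary fin feature between communities."""
    counts = community_feature_counts(db, p, feature)
    return pairwise_tests_from_counts(
        counts,
        alpha=alpha,
        correction=correction,
        n_comparisons_override=n_comparisons_override,
        feature=feature,
    )


def mark_severity_table(
    db: SightingDatabase,
    p: CommunityPartition,
    grouping: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Composition table per community grouping (mark grades, tip damage, resighting).

    ``grouping`` maps a group name to the set of community labels pooled
    into it, e.g. ``{"A": {"A"}, "B-E": {"B", "C", "D", "E"}}``. The
    partition should be the extended one so secondary assignments are
    counted; percentages are over all individuals in the group (all
    grades), rounded half-up, with raw counts alongside. Empty groups
    report zero counts and missing percentages.
    """
    sightings = db.sighting_counts()
    rows = {}
    for name, labels in grouping.items():
        labels = set(labels)
        members = [i for i, l in p.label_of.items() if l in labels and i in db.individuals]
        n = len(members)
        grade_counts = {g.value: 0 for g in MarkGrade}
        tip = once = multi = 0
        for iid in members:
            rec = db.individuals[iid]
            grade_counts[rec.mark_grade.value] += 1
            if rec.tip_damage:
                tip += 1
            if sightings.get(iid, 0) == 1:
                once += 1
            elif sightings.get(iid, 0) >= 2:
                multi += 1
        rows[name] = {
            "n": n,
            "permanent": grade_counts["PERMANENT"],
            "temporary": grade_counts["TEMPORARY"],
            "superficial": grade_counts["SUPERFICIAL"],
            "pct_permanent": _pct(grade_counts["PERMANENT"], n),
            "pct_tip_damage": _pct(tip, n),
            "pct_sighted_once": _pct(once, n),
            "pct_sighted_multi": _pct(multi, n),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
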