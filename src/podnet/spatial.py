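"""Distance-from-shore computation and inshore/offshore segregation tests.

Distances are great-circle kilometres on a sphere of radius 6371.0088 km
(IUGG mean Earth radius). Point-to-coastline distance is the minimum
over polyline segments, each evaluated in a local equirectangular
projection centred on the query point — accurate to well under a percent
at the few-to-tens-of-km scales of coastal survey data.

The spatial comparison treats the encounter (not the individual) as the
sampling unit: each encounter is attributed to a community grouping by
the majority community of its identified members, and the distance
distributions of the two groupings are compared with a two-sided
Mann-Whitney U test.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import AnalysisError
from .catalog import SightingDatabase
from .community import UNASSIGNED, CommunityPartition

__all__ = [
    "EARTH_RADIUS_KM",
    "Coastline",
    "RankTestResult",
    "DistanceSummary",
    "haversine_km",
    "load_coastline",
    "distance_to_coast",
    "mann_whitney_u",
    "compare_group_distances",
    "compare_area_group_sizes",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius
_DEG_KM = EARTH_RADIUS_KM * math.pi / 180.0


def _check_lonlat(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise ValueError(f"coordinates out of range: lon={lon}, lat={lat}")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) points in degrees."""
    _check_lonlat(*a)
    _check_lonlat(*b)
    lon1, lat1, lon2, lat2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class Coastline:
    """A coastline polyline: one or more parts of (lon, lat) vertices."""

    parts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        parts = []
        for p in self.parts:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError("each coastline part needs >= 2 (lon, lat) vertices")
            if (np.abs(arr[:, 0]) > 180).any() or (np.abs(arr[:, 1]) > 90).any():
                raise ValueError("coastline coordinates out of lon/lat range")
            parts.append(arr)
        self.parts = parts

    @property
    def n_vertices(self) -> int:
        return sum(len(p) for p in self.parts)


def load_coastline(path: Union[str, Path]) -> Coastline:
    """Load a coastline from GeoJSON (LineString/MultiLineString) or 2-column CSV."""
    path = Path(path)
    text = path.read_text().lstrip()
    if text.startswith("{"):
        obj = json.loads(text)
        geom = obj.get("geometry", obj) if obj.get("type") == "Feature" else obj
        if geom.get("type") == "LineString":
            return Coastline([np.asarray(geom["coordinates"], dtype=float)])
        if geom.get("type") == "MultiLineString":
            return Coastline([np.asarray(p, dtype=float) for p in geom["coordinates"]])
        raise ValueError(f"unsupported GeoJSON geometry {geom.get('type')!r}")
    rows = []
    with path.open() as fh:
        for rec in csv.reader(fh):
            if not rec or not rec[0].strip():
                continue
            try:
                rows.append((float(rec[0]), float(rec[1])))
            except ValueError:
                continue  # header line
    return Coastline([np.asarray(rows, dtype=float)])


def distance_to_coast(pt: tuple[float, float], coast: Coastline) -> float:
    """Minimum km from a (lon, lat) point to a coastline polyline.

    Each segment is evaluated in a local equirectangular projection
    centred on the point (x scaled by cos latitude); exact at vertices.
    """
    _check_lonlat(*pt)
    if not coast.parts:
        raise ValueError("empty coastline")
    lon0, lat0 = pt
    cos0 = math.cos(math.radians(lat0))
    best = math.inf
    for part in coast.parts:
        x = (part[:, 0] - lon0) * cos0 * _DEG_KM
        y = (part[:, 1] - lat0) * _DEG_KM
        ax, ay = x[:-1], y[:-1]
        dx, dy = np.diff(x), np.diff(y)
        seg2 = dx * dx + dy * dy
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(seg2 > 0, -(ax * dx + ay * dy) / np.where(seg2 == 0, 1, seg2), 0.0)
        t = np.clip(t, 0.0, 1.0)
        px, py = ax + t * dx, ay + t * dy
        best = min(best, float(np.sqrt(px * px + py * py).min()))
        # the projection slightly overestimates at long range; vertex
        # distances are exact on the sphere, so never exceed them
        for v in part:
            best = min(best, haversine_km(pt, (float(v[0]), float(v[1]))))
    return best


@dataclass
class RankTestResult:
    """Two-sided Mann-Whitney U result; U counts wins of the first sample."""

    u: float
    n1: int
    n2: int
    p: float
    method: str

    def to_dict(self) -> dict:
        return {"U": self.u, "n1": self.n1, "n2": self.n2, "p": self.p, "method": self.method}


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    U = number of (x_i, y_j) pairs with x_i > y_j, counting ties as 0.5.
    ``method="auto"`` uses the exact null distribution when
    n1 * n2 <= 400 and the pooled sample is tie-free, else the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in {"auto", "exact", "normal"}:
        raise ValueError(f"unknown method {method!r}")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if method == "auto":
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "normal"
    if method == "exact" and has_ties:
        raise ValueError("exact method is not defined for tied samples")
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method)
    label = "exact" if method == "exact" else "normal-approximation"
    return RankTestResult(
        u=float(res.statistic), n1=int(x.size), n2=int(y.size), p=float(res.pvalue), method=label
    )


@dataclass
class DistanceSummary:
    """Per-grouping distance-from-shore summary (encounter level)."""

    groups: dict[str, dict] = field(default_factory=dict)
    n_excluded_missing: int = 0
    n_excluded_tied: int = 0

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_tied": self.n_excluded_tied,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.groups, orient="index")


def _summary_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {
        "n": int(values.size),
        "mean": mean,
        "sd": sd,
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_low": mean - sd,
        "whisker_high": mean + sd,
    }


def assign_encounters(
    db: SightingDatabase,
    p: CommunityPartition,
    grouping: dict[str, Iterable[str]],
) -> tuple[dict[str, str], int]:
    """Attribute each encounter to a grouping side by majority membership.

    Individuals whose community label falls in a side vote for that
    side; the majority wins. Returns (encounter_id -> group name,
    number of encounters excluded for an exact tie or no votes).
    """
    side_of_label = {}
    for name, labels in grouping.items():
        for l in labels:
            side_of_label[l] = name
    assignment: dict[str, str] = {}
    excluded = 0
    for e in db.encounters:
        votes: dict[str, int] = {}
        for iid in e.identified_ids:
            label = p.label_of.get(iid)
            side = side_of_label.get(label)
            if side is not None:
                votes[side] = votes.get(side, 0) + 1
        if not votes:
            excluded += 1
            continue
        top = max(votes.values())
        winners = [s for s, v in votes.items() if v == top]
        if len(winners) > 1:
            excluded += 1
            continue
        assignment[e.encounter_id] = winners[0]
    return assignment, excluded


def compare_group_distances(
    db: SightingDatabase,
    p: CommunityPartition,
    grouping: dict[str, Iterable[str]],
) -> tuple[DistanceSummary, RankTestResult]:
    """Compare encounter distances from shore between two community groupings.

    ``grouping`` maps exactly two group names to sets of community
    labels. Encounters without a recorded distance, with no labelled
    members, or with an exact membership tie are excluded (and counted
    in the summary). Raises :class:`AnalysisError` if either side ends
    up with no encounters.
    """
    if len(grouping) != 2:
        raise AnalysisError("distance comparison needs exactly 2 groupings")
    assignment, tied = assign_encounters(db, p, grouping)
    values: dict[str, list[float]] = {name: [] for name in grouping}
    missing = 0
    for e in db.encounters:
        side = assignment.get(e.encounter_id)
        if side is None:
            continue
        if e.distance_from_shore_km is None:
            missing += 1
            continue
        values[side].append(e.distance_from_shore_km)
    names = list(grouping)
    for name in names:
        if not values[name]:
            raise AnalysisError(f"grouping {name!r} has no encounters with distances")
    summary = DistanceSummary(
        groups={name: _summary_stats(np.asarray(values[name])) for name in names},
        n_excluded_missing=missing,
        n_excluded_tied=tied,
    )
    test = mann_whitney_u(values[names[0]], values[names[1]])
    # report U for the side with the larger rank sum, the convention under
    # which complete separation prints the maximal U = n1 * n2
    test.u = max(test.u, test.n1 * test.n2 - test.u)
    return summary, test


def compare_area_group_sizes(
    db: SightingDatabase, area_a: str, area_b: str
) -> RankTestResult:
    """Mann-Whitney comparison of encounter group sizes between two areas."""

    def sizes(area: str) -> list[int]:
        return [
            e.group_size_estimate if e.group_size_estimate is not None else len(e.identified_ids)
            for e in db.encounters
            if e.area == area
        ]

    xa, xb = sizes(area_a), sizes(area_b)
    if not xa or not xb:
        raise AnalysisError("both areas need at least one encounter")
    return mann_whitney_u(xa, xb)
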