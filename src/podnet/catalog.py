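"""Photo-identification sighting catalogues.

Data model and CSV I/O for photo-ID sighting databases: one row per
individual identification within a group encounter, with encounter
metadata (date, area, position, distance from shore) and individual
metadata (mark-severity grade, dorsal-tip-damage flag, photo quality).

Mark severity reflects how reliably a dorsal fin can be re-identified:
permanently marked fins carry deep cuts and scars stable across years,
temporarily marked fins carry small cuts and rakes that may heal within
a year, and superficially marked fins carry rakes or lesions only.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "MarkGrade",
    "IndividualRecord",
    "Encounter",
    "SightingDatabase",
    "CatalogSummary",
    "SchemaError",
    "ConsistencyError",
    "read_sightings",
    "write_sightings",
    "validate_database",
    "summarize_catalog",
    "filter_by_quality",
]


class MarkGrade(str, Enum):
    """Severity grade of dorsal-fin marking (re-identification reliability)."""

    PERMANENT = "PERMANENT"
    TEMPORARY = "TEMPORARY"
    SUPERFICIAL = "SUPERFICIAL"


class SchemaError(ValueError):
    """The input table does not match the documented column schema."""


class ConsistencyError(ValueError):
    """Rows of the input table contradict each other."""


REQUIRED_COLUMNS = (
    "encounter_id",
    "date",
    "area",
    "individual_id",
    "mark_grade",
    "tip_damage",
)
OPTIONAL_COLUMNS = (
    "latitude",
    "longitude",
    "distance_from_shore_km",
    "group_size_estimate",
    "photo_quality",
)
ALL_COLUMNS = REQUIRED_COLUMNS[:3] + OPTIONAL_COLUMNS[:4] + REQUIRED_COLUMNS[3:] + OPTIONAL_COLUMNS[4:]


@dataclass(frozen=True)
class IndividualRecord:
    """A catalogued individual with static fin-marking attributes."""

    individual_id: str
    mark_grade: MarkGrade
    tip_damage: bool


@dataclass
class Encounter:
    """One group encounter: all dolphins within a 100 m radius, photographed together.

    ``photo_quality`` maps individual_id -> quality rank (1 = best) for
    identifications that carry one; identifications without a recorded
    quality are absent from the mapping.
    """

    encounter_id: str
    date: dt.date
    area: str
    identified_ids: frozenset[str]
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    distance_from_shore_km: Optional[float] = None
    group_size_estimate: Optional[int] = None
    photo_quality: dict[str, int] = field(default_factory=dict)

    @property
    def n_identified(self) -> int:
        return len(self.identified_ids)


@dataclass
class SightingDatabase:
    """A photo-ID catalogue: individuals plus the encounters identifying them."""

    individuals: dict[str, IndividualRecord] = field(default_factory=dict)
    encounters: list[Encounter] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def encounter(self, encounter_id: str) -> Encounter:
        for e in self.encounters:
            if e.encounter_id == encounter_id:
                return e
        raise KeyError(encounter_id)

    def sighting_counts(self) -> dict[str, int]:
        """Number of encounters each catalogued individual appears in."""
        counts = {i: 0 for i in self.individuals}
        for e in self.encounters:
            for i in e.identified_ids:
                if i in counts:
                    counts[i] += 1
        return counts

    def ids_with_grade(self, grades: Iterable[MarkGrade]) -> list[str]:
        grades = set(grades)
        return sorted(i for i, r in self.individuals.items() if r.mark_grade in grades)


def _parse_bool(v, *, row: int, col: str) -> bool:
    s = str(v).strip()
    if s in {"0", "False", "false"}:
        return False
    if s in {"1", "True", "true"}:
        return True
    raise SchemaError(f"row {row}: column {col!r} must be 0/1, got {v!r}")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def read_sightings(path: Union[str, Path]) -> SightingDatabase:
    """Read a long-format sighting table (one CSV row per identification).

    Rows sharing an ``encounter_id`` are merged into one encounter; their
    encounter metadata must agree. Individual metadata (mark grade, tip
    damage) must be consistent across all rows for the same individual.

    Raises
    ------
    SchemaError
        If a required column is missing or a value cannot be parsed.
    ConsistencyError
        If the same individual carries conflicting metadata, encounter
        metadata conflicts between rows, or the same (encounter,
        individual) pair appears twice.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    individuals: dict[str, IndividualRecord] = {}
    enc_meta: dict[str, dict] = {}
    enc_members: dict[str, dict[str, Optional[int]]] = {}
    order: list[str] = []

    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        eid = rec["encounter_id"].strip()
        iid = rec["individual_id"].strip()
        if not eid or not iid:
            raise SchemaError(f"row {row_no}: empty encounter_id or individual_id")
        try:
            grade = MarkGrade(rec["mark_grade"].strip())
        except ValueError as exc:
            raise SchemaError(f"row {row_no}: unknown mark_grade {rec['mark_grade']!r}") from exc
        tip = _parse_bool(rec["tip_damage"], row=row_no, col="tip_damage")
        ind = IndividualRecord(iid, grade, tip)
        if iid in individuals and individuals[iid] != ind:
            raise ConsistencyError(
                f"individual {iid!r}: conflicting metadata between rows "
                f"({individuals[iid].mark_grade.value}/{individuals[iid].tip_damage} vs "
                f"{grade.value}/{tip})"
            )
        individuals[iid] = ind

        try:
            date = dt.date.fromisoformat(rec["date"].strip())
        except ValueError as exc:
            raise SchemaError(f"row {row_no}: bad date {rec['date']!r} (expect YYYY-MM-DD)") from exc
        meta = {
            "date": date,
            "area": rec["area"].strip(),
            "latitude": _opt_float(rec.get("latitude")),
            "longitude": _opt_float(rec.get("longitude")),
            "distance_from_shore_km": _opt_float(rec.get("distance_from_shore_km")),
            "group_size_estimate": _opt_int(rec.get("group_size_estimate")),
        }
        if eid not in enc_meta:
            enc_meta[eid] = meta
            enc_members[eid] = {}
            order.append(eid)
        elif enc_meta[eid] != meta:
            raise ConsistencyError(f"encounter {eid!r}: conflicting encounter metadata between rows")
        if iid in enc_members[eid]:
            raise ConsistencyError(f"duplicate identification of {iid!r} in encounter {eid!r}")
        enc_members[eid][iid] = _opt_int(rec.get("photo_quality"))

    encounters = []
    for eid in order:
        meta = enc_meta[eid]
        quality = {i: q for i, q in enc_members[eid].items() if q is not None}
        encounters.append(
            Encounter(
                encounter_id=eid,
                identified_ids=frozenset(enc_members[eid]),
                photo_quality=quality,
                **meta,
            )
        )
    return SightingDatabase(individuals=individuals, encounters=encounters)


def write_sightings(db: SightingDatabase, path: Union[str, Path]) -> None:
    """Write ``db`` as a long-format CSV; inverse of :func:`read_sightings`.

    Rows are emitted encounter by encounter (database order), individuals
    sorted within each encounter, so repeated writes are byte-identical.
    """
    rows = []
    for e in db.encounters:
        for iid in sorted(e.identified_ids):
            ind = db.individuals[iid]
            rows.append(
                {
                    "encounter_id": e.encounter_id,
                    "date": e.date.isoformat(),
                    "area": e.area,
                    "latitude": "" if e.latitude is None else repr(e.latitude),
                    "longitude": "" if e.longitude is None else repr(e.longitude),
                    "distance_from_shore_km": (
                        "" if e.distance_from_shore_km is None else repr(e.distance_from_shore_km)
                    ),
                    "group_size_estimate": (
                        "" if e.group_size_estimate is None else str(e.group_size_estimate)
                    ),
                    "individual_id": iid,
                    "mark_grade": ind.mark_grade.value,
                    "tip_damage": "1" if ind.tip_damage else "0",
                    "photo_quality": (
                        str(e.photo_quality[iid]) if iid in e.photo_quality else ""
                    ),
                }
            )
    pd.DataFrame(rows, columns=list(ALL_COLUMNS)).to_csv(path, index=False)


def validate_database(db: SightingDatabase) -> list[str]:
    """Check type invariants; return a list of human-readable violations.

    Returns an empty list iff the database is valid. Data problems are
    reported, never raised.
    """
    report: list[str] = []
    seen_eids: set[str] = set()
    for e in db.encounters:
        if e.encounter_id in seen_eids:
            report.append(f"encounter {e.encounter_id!r}: duplicate encounter_id")
        seen_eids.add(e.encounter_id)
        if not e.identified_ids:
            report.append(f"encounter {e.encounter_id!r}: no identified individuals")
        for iid in sorted(e.identified_ids):
            if iid not in db.individuals:
                report.append(
                    f"encounter {e.encounter_id!r}: references unknown individual {iid!r}"
                )
        if e.distance_from_shore_km is not None and e.distance_from_shore_km < 0:
            report.append(f"encounter {e.encounter_id!r}: negative distance_from_shore_km")
        if e.group_size_estimate is not None and e.group_size_estimate < len(e.identified_ids):
            report.append(
                f"encounter {e.encounter_id!r}: group_size_estimate "
                f"{e.group_size_estimate} < {len(e.identified_ids)} identified"
            )
        if e.latitude is not None and not -90 <= e.latitude <= 90:
            report.append(f"encounter {e.encounter_id!r}: latitude out of range")
        if e.longitude is not None and not -180 <= e.longitude <= 180:
            report.append(f"encounter {e.encounter_id!r}: longitude out of range")
    for iid, rec in db.individuals.items():
        if rec.individual_id != iid:
            report.append(f"individual {iid!r}: key does not match record id")
        if not isinstance(rec.mark_grade, MarkGrade):
            report.append(f"individual {iid!r}: invalid mark grade {rec.mark_grade!r}")
    return report


def _pct(numerator: float, denominator: float) -> Optional[int]:
    """Percentage rounded half-up to the nearest integer; None for 0 denominator."""
    if denominator == 0:
        return None
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass
class CatalogSummary:
    """Catalogue-level descriptive statistics.

    Percentages are integers rounded half-up (reporting style); the raw
    fractions are retained alongside for exact downstream use.
    """

    n_individuals: int
    n_encounters: int
    identifications_total: int
    grade_counts: dict[str, int]
    grade_percent: dict[str, Optional[int]]
    grade_fraction: dict[str, float]
    sighting_histogram: dict[int, int]
    n_sighted_once: int
    n_resighted: int
    n_multi_year: int
    area_individual_counts: dict[str, int]
    cross_area_individuals: int
    area_overlap_percent: dict[str, Optional[int]]
    group_size_mean: Optional[float]
    group_size_sd: Optional[float]
    group_size_range: Optional[tuple[int, int]]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sighting_histogram"] = {str(k): v for k, v in sorted(self.sighting_histogram.items())}
        if self.group_size_range is not None:
            d["group_size_range"] = list(self.group_size_range)
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def summarize_catalog(db: SightingDatabase) -> CatalogSummary:
    """Descriptive catalogue summary.

    "Resighted" means identified in >= 2 encounters; "multi-year" means
    identified in >= 2 distinct calendar years; the cross-area overlap
    counts individuals identified in >= 2 distinct area labels. Group
    size uses ``group_size_estimate`` when present, else the number of
    identified individuals; the SD is the sample SD (ddof=1).
    """
    counts = db.sighting_counts()
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1

    years: dict[str, set[int]] = {i: set() for i in db.individuals}
    areas_of: dict[str, set[str]] = {i: set() for i in db.individuals}
    area_sets: dict[str, set[str]] = {}
    sizes: list[int] = []
    total_ids = 0
    for e in db.encounters:
        total_ids += len(e.identified_ids)
        sizes.append(
            e.group_size_estimate if e.group_size_estimate is not None else len(e.identified_ids)
        )
        area_sets.setdefault(e.area, set()).update(e.identified_ids)
        for iid in e.identified_ids:
            if iid in years:
                years[iid].add(e.date.year)
                areas_of[iid].add(e.area)

    grade_counts = {g.value: 0 for g in MarkGrade}
    for rec in db.individuals.values():
        grade_counts[rec.mark_grade.value] += 1
    n = db.n_individuals
    grade_fraction = {g: (c / n if n else 0.0) for g, c in grade_counts.items()}
    grade_percent = {g: _pct(c, n) for g, c in grade_counts.items()}

    cross_area = {i for i, a in areas_of.items() if len(a) >= 2}
    area_counts = {a: len(ids) for a, ids in sorted(area_sets.items())}
    area_overlap_percent = {
        a: _pct(len(ids & cross_area), len(ids)) for a, ids in sorted(area_sets.items())
    }

    if sizes:
        import statistics

        mean = statistics.fmean(sizes)
        sd = statistics.stdev(sizes) if len(sizes) > 1 else 0.0
        rng = (min(sizes), max(sizes))
    else:
        mean = sd = rng = None

    return CatalogSummary(
        n_individuals=n,
        n_encounters=db.n_encounters,
        identifications_total=total_ids,
        grade_counts=grade_counts,
        grade_percent=grade_percent,
        grade_fraction=grade_fraction,
        sighting_histogram=hist,
        n_sighted_once=sum(1 for c in counts.values() if c == 1),
        n_resighted=sum(1 for c in counts.values() if c >= 2),
        n_multi_year=sum(1 for y in years.values() if len(y) >= 2),
        area_individual_counts=area_counts,
        cross_area_individuals=len(cross_area),
        area_overlap_percent=area_overlap_percent,
        group_size_mean=mean,
        group_size_sd=sd,
        group_size_range=rng,
    )


def filter_by_quality(db: SightingDatabase, worst_rank: int) -> SightingDatabase:
    """Drop identifications whose photo-quality rank is worse than ``worst_rank``.

    Quality rank 1 is best; an identification with rank > ``worst_rank``
    is removed. Identifications without a recorded quality are kept.
    Encounters left empty are dropped, as are individuals left with no
    sightings. The input database is not modified.
    """
    encounters: list[Encounter] = []
    kept_ids: set[str] = set()
    for e in db.encounters:
        keep = frozenset(
            i for i in e.identified_ids if e.photo_quality.get(i) is None or e.photo_quality[i] <= worst_rank
        )
        if not keep:
            continue
        kept_ids.update(keep)
        encounters.append(
            Encounter(
                encounter_id=e.encounter_id,
                date=e.date,
                area=e.area,
                identified_ids=keep,
                latitude=e.latitude,
                longitude=e.longitude,
                distance_from_shore_km=e.distance_from_shore_km,
                group_size_estimate=e.group_size_estimate,
                photo_quality={i: q for i, q in e.photo_quality.items() if i in keep},
            )
        )
    individuals = {i: r for i, r in db.individuals.items() if i in kept_ids}
    return SightingDatabase(individuals=individuals, encounters=encounters)
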