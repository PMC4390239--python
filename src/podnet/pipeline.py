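"""End-to-end analysis pipeline: sightings CSV in, report bundle out.

Stages, in order: read + validate, optional photo-quality filter,
association matrix over the grade-filtered subset, sociogram, community
detection, secondary assignment, composition tables, pairwise
contingency tests, and (when distances are available) the
inshore/offshore distance comparison. All analytic outputs are
deterministic functions of the input and configuration; the manifest
records provenance.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .association import AnalysisError, association_matrix
from .catalog import (
    MarkGrade,
    SightingDatabase,
    filter_by_quality,
    read_sightings,
    summarize_catalog,
    validate_database,
)
from .community import (
    CommunityPartition,
    assign_unmarked,
    build_sociogram,
    detect_communities,
    write_graphml,
)
from .spatial import (
    Coastline,
    compare_group_distances,
    distance_to_coast,
    load_coastline,
)
from .stats import mark_severity_table, pairwise_network_tests

log = logging.getLogger("podnet")

__all__ = ["PipelineConfig", "ReportBundle", "ValidationFailure", "run_pipeline"]


class ValidationFailure(ValueError):
    """The input database violates catalogue invariants."""

    def __init__(self, violations: list[str]):
        super().__init__(f"{len(violations)} validation violation(s)")
        self.violations = violations


@dataclass
class PipelineConfig:
    """Settings for one analysis run."""

    sightings: Union[str, Path]
    out_dir: Union[str, Path]
    coastline: Optional[Union[str, Path]] = None
    grade_filter: tuple[str, ...] = ("PERMANENT",)
    hwi_threshold: float = 0.0
    quality_threshold: Optional[int] = None
    alpha: float = 0.05
    correction: str = "bonferroni"
    n_comparisons_override: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sightings"] = str(self.sightings)
        d["out_dir"] = str(self.out_dir)
        d["coastline"] = None if self.coastline is None else str(self.coastline)
        d["grade_filter"] = list(self.grade_filter)
        return d


@dataclass
class ReportBundle:
    """Paths and key results of a pipeline run."""

    out_dir: Path
    manifest: dict
    db: SightingDatabase
    partition: CommunityPartition
    files: dict[str, Path] = field(default_factory=dict)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Raises :class:`ValidationFailure` (listing every violation) if the
    input database is invalid. The spatial stage is skipped, and flagged
    in the manifest, when no encounter distances are available and no
    coastline is supplied.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    db = read_sightings(cfg.sightings)
    violations = validate_database(db)
    if violations:
        raise ValidationFailure(violations)
    if cfg.quality_threshold is not None:
        db = filter_by_quality(db, cfg.quality_threshold)
        log.info("quality filter <= %d: %d individuals, %d encounters remain",
                 cfg.quality_threshold, db.n_individuals, db.n_encounters)

    summary = summarize_catalog(db)
    files["catalog_summary"] = out / "catalog_summary.json"
    files["catalog_summary"].write_text(summary.to_json() + "\n")

    grades = {MarkGrade(g) for g in cfg.grade_filter}
    m = association_matrix(db, grade_filter=grades)
    files["association_long"] = out / "association_long.csv"
    files["association_square"] = out / "association_matrix.csv"
    m.write_long_csv(files["association_long"])
    m.write_square_csv(files["association_square"])

    g = build_sociogram(m, db, threshold=cfg.hwi_threshold)
    primary = detect_communities(g)
    partition = assign_unmarked(db, primary)
    files["sociogram"] = out / "sociogram.graphml"
    write_graphml(g, files["sociogram"], partition)
    files["partition"] = out / "partition.csv"
    partition.write_csv(files["partition"])
    files["edge_list"] = out / "edges.csv"
    with files["edge_list"].open("w") as fh:
        fh.write("id_a,id_b,hwi\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(f"{a},{b},{d['hwi']!r}\n")

    labels = primary.labels
    grouping = {labels[0]: {labels[0]}}
    if len(labels) > 1:
        pooled = f"{labels[1]}-{labels[-1]}" if len(labels) > 2 else labels[1]
        grouping[pooled] = set(labels[1:])
    composition = mark_severity_table(db, partition, grouping)
    files["mark_severity"] = out / "mark_severity.csv"
    composition.to_csv(files["mark_severity"], index_label="group")

    skipped = []
    if len(labels) >= 2:
        for feature, stem in (("permanent_mark", "pairwise_tests"), ("tip_damage", "tip_damage_tests")):
            try:
                tests = pairwise_network_tests(
                    db,
                    partition,
                    feature=feature,
                    alpha=cfg.alpha,
                    correction=cfg.correction,
                    n_comparisons_override=cfg.n_comparisons_override,
                )
            except ValueError as exc:
                skipped.append(f"{stem}: {exc}")
                log.info("%s skipped: %s", stem, exc)
                continue
            files[stem] = out / f"{stem}.csv"
            tests.write_csv(files[stem])
            files[f"{stem}_json"] = out / f"{stem}.json"
            files[f"{stem}_json"].write_text(tests.to_json() + "\n")
    else:
        skipped.append("pairwise_tests: single community")

    db = _ensure_distances(db, cfg)
    have_distances = any(e.distance_from_shore_km is not None for e in db.encounters)
    if have_distances and len(labels) >= 2:
        try:
            dist_summary, rank_test = compare_group_distances(db, partition, grouping)
        except AnalysisError as exc:
            skipped.append(f"spatial: {exc}")
        else:
            files["distance_summary"] = out / "distance_summary.json"
            files["distance_summary"].write_text(dist_summary.to_json() + "\n")
            files["distance_test"] = out / "distance_test.json"
            files["distance_test"].write_text(json.dumps(rank_test.to_dict(), indent=2) + "\n")
            files["distance_table"] = out / "distance_table.csv"
            dist_summary.to_frame().to_csv(files["distance_table"], index_label="group")
    else:
        reason = "no distances available" if not have_distances else "single community"
        skipped.append(f"spatial: {reason}")
        log.info("spatial stage skipped: %s", reason)

    manifest = {
        "podnet_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_individuals": db.n_individuals,
        "n_encounters": db.n_encounters,
        "n_communities": primary.n_communities,
        "community_sizes": {l: len(primary.members(l)) for l in labels},
        "skipped_stages": skipped,
        "files": {k: p.name for k, p in files.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path
    return ReportBundle(out_dir=out, manifest=manifest, db=db, partition=partition, files=files)


def _ensure_distances(db: SightingDatabase, cfg: PipelineConfig) -> SightingDatabase:
    """Fill missing encounter distances from the coastline, never overwriting data."""
    if cfg.coastline is None:
        return db
    coast = load_coastline(cfg.coastline)
    for e in db.encounters:
        if (
            e.distance_from_shore_km is None
            and e.longitude is not None
            and e.latitude is not None
        ):
            e.distance_from_shore_km = distance_to_coast((e.longitude, e.latitude), coast)
    return db
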