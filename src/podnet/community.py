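"""Sociogram construction, community partitioning, secondary assignment.

A community is operationalised as a connected component of the HWI > 0
association graph: two individuals are in the same community iff they
are linked by a chain of co-occurrences. Components are labelled A, B,
C, ... in order of decreasing size (ties broken by smallest member id),
so the largest community is always "A".

Individuals excluded from the network analysis because their marks are
not permanent are afterwards assigned by the associate rule: a
temporarily or superficially marked individual joins a community iff
every permanently marked individual it ever co-occurred with belongs to
that one community; otherwise it stays UNASSIGNED.
"""
from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .association import AssociationMatrix
from .catalog import MarkGrade, SightingDatabase

__all__ = [
    "UNASSIGNED",
    "CommunityPartition",
    "build_sociogram",
    "detect_communities",
    "assign_unmarked",
    "write_graphml",
]

UNASSIGNED = "UNASSIGNED"

PRIMARY = "PRIMARY"
SECONDARY = "SECONDARY"


def _label_stream():
    """A, B, ..., Z, AA, AB, ... (spreadsheet order)."""
    for repeat in itertools.count(1):
        for tup in itertools.product(string.ascii_uppercase, repeat=repeat):
            yield "".join(tup)


def build_sociogram(
    m: AssociationMatrix,
    db: SightingDatabase,
    threshold: float = 0.0,
) -> nx.Graph:
    """Weighted association graph: edge (a, b) iff HWI(a, b) > ``threshold``.

    Node attributes: mark_grade, tip_damage, n_sightings (within the
    analysed encounter set). Edge attribute: hwi.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    g = nx.Graph()
    h = m.hwi_matrix()
    for k, iid in enumerate(m.ids):
        rec = db.individuals[iid]
        g.add_node(
            iid,
            mark_grade=rec.mark_grade.value,
            tip_damage=bool(rec.tip_damage),
            n_sightings=int(m.sightings[k]),
        )
    for i in range(m.n):
        for j in range(i + 1, m.n):
            if h[i, j] > threshold:
                g.add_edge(m.ids[i], m.ids[j], hwi=float(h[i, j]))
    return g


@dataclass
class CommunityPartition:
    """Mapping individual -> community label, with assignment provenance.

    Provenance is PRIMARY for individuals placed by the network analysis
    itself and SECONDARY for individuals placed afterwards through their
    permanently marked associates. Only secondary candidates may be
    UNASSIGNED.
    """

    label_of: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        """Assigned labels in A, B, C, ... order (UNASSIGNED excluded)."""
        seen = {l for l in self.label_of.values() if l != UNASSIGNED}
        return sorted(seen, key=lambda l: (len(l), l))

    def members(self, label: str) -> list[str]:
        return sorted(i for i, l in self.label_of.items() if l == label)

    def member_map(self) -> dict[str, list[str]]:
        return {l: self.members(l) for l in self.labels}

    @property
    def n_communities(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (iid, self.label_of[iid], self.provenance[iid])
            for iid in sorted(self.label_of)
        ]
        return pd.DataFrame(rows, columns=["individual_id", "label", "provenance"])

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_communities(g: nx.Graph) -> CommunityPartition:
    """Partition the sociogram into communities = connected components.

    Components are sorted by decreasing size, ties by lexicographically
    smallest member id, and labelled A, B, C, ... in that order. The
    ordering rule is total, so identical graphs always receive identical
    labels.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("sociogram has no nodes")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    p = CommunityPartition()
    for label, comp in zip(_label_stream(), comps):
        for iid in comp:
            p.label_of[iid] = label
            p.provenance[iid] = PRIMARY
    return p


def assign_unmarked(db: SightingDatabase, p: CommunityPartition) -> CommunityPartition:
    """Extend a primary partition to temporarily/superficially marked individuals.

    For each non-permanent individual, collect the labels of all
    permanently marked individuals sharing at least one encounter with
    it. Exactly one label -> assigned (SECONDARY); none or several ->
    UNASSIGNED. The input partition must already cover every permanently
    marked individual appearing in an encounter.
    """
    permanent = {
        i for i, r in db.individuals.items() if r.mark_grade is MarkGrade.PERMANENT
    }
    sighted = set()
    for e in db.encounters:
        sighted.update(e.identified_ids)
    missing = sorted(permanent & sighted - set(p.label_of))
    if missing:
        raise ValueError(
            f"partition does not cover permanently marked individual(s): {missing[:5]}"
        )
    out = CommunityPartition(label_of=dict(p.label_of), provenance=dict(p.provenance))
    associates: dict[str, set[str]] = {}
    for e in db.encounters:
        perm_labels = {p.label_of[i] for i in e.identified_ids if i in permanent and i in p.label_of}
        for iid in e.identified_ids:
            if iid not in permanent:
                associates.setdefault(iid, set()).update(perm_labels)
    for iid, rec in db.individuals.items():
        if rec.mark_grade is MarkGrade.PERMANENT or iid in out.label_of:
            continue
        labels = associates.get(iid, set())
        if len(labels) == 1:
            out.label_of[iid] = next(iter(labels))
        else:
            out.label_of[iid] = UNASSIGNED
        out.provenance[iid] = SECONDARY
    return out


def write_graphml(
    g: nx.Graph,
    path: Union[str, Path],
    partition: Optional[CommunityPartition] = None,
) -> None:
    """Export the sociogram as GraphML, optionally stamping community labels."""
    if partition is not None:
        g = g.copy()
        for n in g.nodes:
            g.nodes[n]["community"] = partition.label_of.get(n, UNASSIGNED)
    nx.write_graphml(g, str(path))
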