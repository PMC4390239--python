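import datetime as dt

import pytest

from podnet.catalog import (
    Encounter,
    IndividualRecord,
    MarkGrade,
    SightingDatabase,
)

GRADE = {
    "P": MarkGrade.PERMANENT,
    "T": MarkGrade.TEMPORARY,
    "S": MarkGrade.SUPERFICIAL,
}


def make_db(encounters, grades=None, tip=None, dates=None, areas=None, distances=None):
    """Build a SightingDatabase from a compact description.

    ``encounters``: list of iterables of individual ids (one per encounter).
    ``grades``: id -> "P"/"T"/"S" (default "P").
    Optional per-encounter ``dates``, ``areas``, ``distances`` lists.
    """
    grades = grades or {}
    tip = tip or {}
    ids = sorted({i for e in encounters for i in e})
    individuals = {
        i: IndividualRecord(i, GRADE[grades.get(i, "P")], bool(tip.get(i, False)))
        for i in ids
    }
    encs = []
    for k, members in enumerate(encounters):
        encs.append(
            Encounter(
                encounter_id=f"E{k + 1}",
                date=(dates[k] if dates else dt.date(2010, 6, 1) + dt.timedelta(days=k)),
                area=(areas[k] if areas else "MAYO"),
                identified_ids=frozenset(members),
                distance_from_shore_km=(distances[k] if distances else None),
            )
        )
    return SightingDatabase(individuals=individuals, encounters=encs)


@pytest.fixture(scope="session")
def default_db():
    """Default synthetic database, seed 1, with its ground truth."""
    from podnet.synthdata import default_config, generate

    return generate(default_config(), 1)
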