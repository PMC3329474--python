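from datetime import date

import pytest

from rasffnet import (
    Notification,
    NotificationLog,
    NType,
    Snapshot,
)


def note(d, det, trans, ntype="alert", hazard="aflatoxin"):
    return Notification(
        date=d, detector=det, transgressor=trans, ntype=NType(ntype),
        hazard_text=hazard,
    ).with_category()


@pytest.fixture
def toy_log():
    """5 records: 2 mycotoxin, 1 bacteria, 1 metal, 1 uncategorized."""
    return NotificationLog(
        [
            note(date(2007, 1, 10), "DEU", "IRN", "alert", "aflatoxin in pistachios"),
            note(date(2007, 3, 5), "ITA", "CHN", "information", "Ochratoxin A in raisins"),
            note(date(2007, 5, 20), "ESP", "BRA", "alert", "Salmonella enteritidis"),
            note(date(2007, 7, 1), "GBR", "IND", "information", "cadmium in squid"),
            note(date(2007, 9, 9), "NLD", "TUR", "alert", "incorrect labelling"),
        ],
        provenance="toy",
    )


def snapshot_from_edges(edges, query_date=date(2008, 1, 1), extra_nodes=()):
    """Hand-built snapshot for engine tests; edges: {(u, v): w}."""
    nodes = set(extra_nodes)
    for u, v in edges:
        nodes.add(u)
        nodes.add(v)
    return Snapshot(query_date=query_date, nodes=nodes, edges=dict(edges))


@pytest.fixture
def star_snapshot():
    """One detector reporting three transgressors with unit weights."""
    return snapshot_from_edges(
        {("DEU", "IRN"): 1.0, ("DEU", "CHN"): 1.0, ("DEU", "BRA"): 1.0}
    )
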