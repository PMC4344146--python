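"""Readers and writers for the package's plain-text interchange formats.

Detection streams travel as CSV (tag_id, timestamp, location_id, context,
access_granted; integer seconds); networks as weighted edge-list CSV and
GraphML with the parity node attribute; group-by-individual matrices as
MatrixMarket sparse files plus a roster text file; ground truth and
results as JSON. Every writer can attach a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from flocknet.groups import GatheringEvent, GroupByIndividual
from flocknet.networks import AssociationNetwork, parity_attrs
from flocknet.synthetic import DETECTION_COLUMNS, GroundTruth

CSV_COLUMNS = ["tag_id", "timestamp", "location_id", "context", "access_granted"]


def write_detections_csv(
    detections: pd.DataFrame, path: str | Path, include_truth: bool = False
) -> None:
    """Write a detection stream; timestamps are rounded to integer seconds."""
    cols = CSV_COLUMNS + (["true_event_id"] if include_truth else [])
    out = detections[cols].copy()
    out["timestamp"] = out["timestamp"].round().astype(np.int64)
    out["access_granted"] = out["access_granted"].astype(bool)
    out.to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    df["timestamp"] = df["timestamp"].astype(float)
    if df["access_granted"].dtype != bool:
        df["access_granted"] = (
            df["access_granted"].astype(str).str.lower().isin(("true", "1"))
        )
    if "true_event_id" not in df.columns:
        df["true_event_id"] = -1
    return df[DETECTION_COLUMNS]


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Events keyed by context/period; preference snapshots as lower triangles."""
    events: dict = {}
    for (context, period), grp in truth.events.groupby(["context", "period"]):
        events[f"{context}/{period}"] = [
            {
                "event_id": int(row.event_id),
                "location_id": row.location_id,
                "day": int(row.day),
                "members": list(row.members),
            }
            for row in grp.itertuples()
        ]
    snapshots = {
        str(day): np.round(P[np.tril_indices_from(P, k=-1)], 5).tolist()
        for day, P in truth.preference_snapshots.items()
    }
    payload = {"roster": truth.roster, "events": events,
               "preference_snapshots_tril": snapshots}
    Path(path).write_text(json.dumps(payload) + "\n")


def write_events_csv(events: list[GatheringEvent], path: str | Path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "location_id": e.location_id,
            "start_s": e.start_s,
            "end_s": e.end_s,
            "member_tags": ";".join(sorted(e.member_tags)),
            "n_detections": e.n_detections,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[GatheringEvent]:
    df = pd.read_csv(path, dtype={"event_id": str, "member_tags": str})
    return [
        GatheringEvent(
            event_id=row.event_id,
            location_id=row.location_id,
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            member_tags=frozenset(str(row.member_tags).split(";")),
            n_detections=int(row.n_detections),
        )
        for row in df.itertuples()
    ]


def write_gbi_mtx(gbi: GroupByIndividual, matrix_path: str | Path,
                  roster_path: str | Path) -> None:
    mmwrite(str(matrix_path), sparse.csr_matrix(gbi.matrix))
    Path(roster_path).write_text("\n".join(gbi.roster) + "\n")


def read_gbi_mtx(matrix_path: str | Path, roster_path: str | Path) -> GroupByIndividual:
    mat = np.asarray(mmread(str(matrix_path)).todense()).astype(np.uint8)
    roster = Path(roster_path).read_text().split()
    return GroupByIndividual(matrix=mat, roster=roster,
                             event_ids=[str(k) for k in range(mat.shape[0])])


def write_edgelist_csv(net: AssociationNetwork, path: str | Path) -> None:
    """Weighted edge list, tag_a < tag_b lexicographically, zero dyads omitted."""
    rows = []
    for i, a in enumerate(net.roster):
        for j in range(i + 1, len(net.roster)):
            w = net.W[i, j]
            if w > 0:
                rows.append({"tag_a": a, "tag_b": net.roster[j], "weight": w})
    pd.DataFrame(rows, columns=["tag_a", "tag_b", "weight"]).to_csv(path, index=False)


def read_edgelist_csv(path: str | Path, roster: list[str] | None = None
                      ) -> AssociationNetwork:
    df = pd.read_csv(path, dtype={"tag_a": str, "tag_b": str})
    if roster is None:
        roster = sorted(set(df["tag_a"]) | set(df["tag_b"]))
    index = {t: i for i, t in enumerate(roster)}
    W = np.zeros((len(roster), len(roster)))
    for row in df.itertuples():
        i, j = index[row.tag_a], index[row.tag_b]
        W[i, j] = W[j, i] = row.weight
    return AssociationNetwork(roster=roster, W=W, node_attrs=parity_attrs(roster))


def write_graphml(net: AssociationNetwork, path: str | Path) -> None:
    g = nx.Graph()
    parity = net.node_attrs.get("parity", {})
    for tag in net.roster:
        g.add_node(tag, parity=parity.get(tag, ""))
    for i, a in enumerate(net.roster):
        for j in range(i + 1, len(net.roster)):
            if net.W[i, j] > 0:
                g.add_edge(a, net.roster[j], weight=float(net.W[i, j]))
    nx.write_graphml(g, str(path))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_provenance(path: str | Path, inputs: dict, parameters: dict,
                     seed: int | None) -> None:
    """Sidecar recording how ``path`` was produced (no wall-clock, so runs
    with the same seed are byte-identical)."""
    from flocknet import __version__

    sidecar = Path(str(path) + ".prov.json")
    write_json(
        {"output": Path(path).name, "inputs": inputs, "parameters": parameters,
         "seed": seed, "version": __version__},
        sidecar,
    )
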