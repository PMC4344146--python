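"""Association networks from group-by-individual matrices.

Dyadic association is quantified with the half-weight index
HWI = x / (x + (yA + yB) / 2), where x counts events containing both
individuals and yA, yB events containing only one of them; equivalently
2x / (nA + nB). Each gathering event is its own sampling unit, so the
general index's "both seen apart in the same period" term is zero by
construction. Individuals with no events in a window are dropped from
that window's roster rather than kept as isolates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flocknet.config import SECONDS_PER_DAY, SegmentationConfig
from flocknet.groups import GroupByIndividual, detect_events, events_to_gbi

_PARITY_FEEDER_RE = re.compile(r"^(S\d+)[OE]$")


@dataclass
class AssociationNetwork:
    """Symmetric weighted association matrix plus node attributes."""

    roster: list[str]
    W: np.ndarray
    node_attrs: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.roster), len(self.roster)):
            raise ValueError("W shape must match roster length")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.roster)

    def attr_vector(self, name: str) -> np.ndarray:
        attr = self.node_attrs[name]
        return np.array([attr[tag] for tag in self.roster])


@dataclass
class SpatialOverlapMatrix:
    """Binary dyadic matrix: 1 iff two individuals shared >= 1 feeder site."""

    roster: list[str]
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B)
        if not np.array_equal(self.B, self.B.T):
            raise ValueError("B must be symmetric")


def parity_of_tag(tag_id: str) -> str:
    """Treatment class from the tag's last digit; 'unknown' for non-digit IDs."""
    last = str(tag_id)[-1]
    if not last.isdigit():
        return "unknown"
    return "odd" if int(last) % 2 == 1 else "even"


def parity_attrs(roster: list[str]) -> dict[str, dict[str, str]]:
    return {"parity": {tag: parity_of_tag(tag) for tag in roster}}


def hwi(gbi: GroupByIndividual, provenance: dict | None = None) -> AssociationNetwork:
    """Half-weight-index network from a binary group-by-individual matrix.

    Dyads never observed (nA + nB = 0) score 0. Individuals appearing in
    no event are dropped from the roster.
    """
    mat = np.asarray(gbi.matrix)
    if mat.size and not np.isin(mat, (0, 1)).all():
        raise ValueError("GBI matrix must be binary")
    mat = mat.astype(float)
    n_events_per_ind = mat.sum(axis=0)
    keep = n_events_per_ind > 0
    roster = [tag for tag, k in zip(gbi.roster, keep) if k]
    mat = mat[:, keep]
    x = mat.T @ mat  # co-occurrence counts; diag = per-individual event counts
    n_ind = np.diag(x).copy()
    denom = n_ind[:, None] + n_ind[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, 2.0 * x / denom, 0.0)
    np.fill_diagonal(W, 0.0)
    return AssociationNetwork(
        roster=roster, W=W, node_attrs=parity_attrs(roster),
        provenance=provenance or {},
    )


def window_networks(
    detections: pd.DataFrame,
    window_days: int = 6,
    segmentation: SegmentationConfig | None = None,
    start_day: int | None = None,
    include_denied: bool = True,
) -> list[AssociationNetwork]:
    """Consecutive non-overlapping time-window networks.

    Detections are partitioned into ``window_days``-day windows from
    ``start_day`` (default: the day of the earliest detection); each
    window runs segmentation -> GBI -> HWI. Windows with no detections
    yield empty networks so indices stay aligned with calendar time.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    det = detections if include_denied else detections[detections["access_granted"]]
    if len(det) == 0:
        return []
    if start_day is None:
        start_day = int(det["timestamp"].min() // SECONDS_PER_DAY)
    day = (det["timestamp"] // SECONDS_PER_DAY).astype(int)
    win = (day - start_day) // window_days
    n_windows = int(win.max()) + 1
    nets = []
    for w in range(n_windows):
        sub = det[win == w]
        prov = {
            "window": w,
            "window_start_day": start_day + w * window_days,
            "window_days": window_days,
        }
        if len(sub) == 0:
            nets.append(AssociationNetwork(roster=[], W=np.zeros((0, 0)),
                                           provenance=prov))
            continue
        events = detect_events(sub, segmentation)
        if not events:
            nets.append(AssociationNetwork(roster=[], W=np.zeros((0, 0)),
                                           provenance=prov))
            continue
        nets.append(hwi(events_to_gbi(events), provenance=prov))
    return nets


def site_of_location(location_id: str) -> str:
    """Collapse a parity-restricted feeder (e.g. 'S3O') to its parent site ('S3')."""
    m = _PARITY_FEEDER_RE.match(location_id)
    if m:
        return m.group(1)
    if not location_id.startswith("S"):
        raise ValueError(f"no site mapping for location {location_id!r}")
    return location_id


def spatial_overlap(
    detections: pd.DataFrame, roster: list[str] | None = None
) -> SpatialOverlapMatrix:
    """Binary spatial range overlap over selective-feeder detections.

    A dyad scores 1 iff both individuals were detected at at least one
    common feeder *site* in the supplied window (parity-split feeders map
    back to their parent site).
    """
    det = detections[detections["context"] == "selective_feeder"]
    sites = det["location_id"].map(site_of_location)
    if roster is None:
        roster = sorted(det["tag_id"].unique())
    index = {tag: i for i, tag in enumerate(roster)}
    site_ids = sorted(sites.unique())
    site_index = {s: j for j, s in enumerate(site_ids)}
    use = np.zeros((len(roster), len(site_ids)), dtype=bool)
    for tag, site in zip(det["tag_id"], sites):
        if tag in index:
            use[index[tag], site_index[site]] = True
    B = (use @ use.T).astype(np.uint8)
    np.fill_diagonal(B, 0)
    return SpatialOverlapMatrix(roster=list(roster), B=B)


def align_common(
    net_a: AssociationNetwork | SpatialOverlapMatrix,
    net_b: AssociationNetwork | SpatialOverlapMatrix,
) -> tuple:
    """Restrict two dyadic matrices to their common roster, same sorted order.

    Matrix comparisons are defined only over individuals observed in both
    matrices; fewer than 3 shared individuals is an error.
    """
    common = sorted(set(net_a.roster) & set(net_b.roster))
    if len(common) < 3:
        raise ValueError(
            f"rosters share only {len(common)} individuals; need >= 3"
        )
    return subset(net_a, common), subset(net_b, common)


def subset(net, roster: list[str]):
    """Restrict a dyadic matrix object to the given roster (in the given order)."""
    idx = [net.roster.index(t) for t in roster]
    if isinstance(net, SpatialOverlapMatrix):
        return SpatialOverlapMatrix(roster=list(roster), B=net.B[np.ix_(idx, idx)])
    return AssociationNetwork(
        roster=list(roster),
        W=net.W[np.ix_(idx, idx)],
        node_attrs={
            name: {t: vals[t] for t in roster if t in vals}
            for name, vals in net.node_attrs.items()
        },
        provenance=dict(net.provenance),
    )


def common_roster(*nets, min_size: int = 3) -> list[str]:
    """Sorted intersection of several rosters; error below ``min_size``."""
    rosters = [set(n.roster) for n in nets]
    common = sorted(set.intersection(*rosters))
    if len(common) < min_size:
        raise ValueError(
            f"rosters share only {len(common)} individuals; need >= {min_size}"
        )
    return common
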