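"""Gathering-event detection in timestamped detection streams.

Feeder and patch visitation arrives in intermittent bursts as flocks come
in to feed. Per location and day, a one-dimensional Gaussian mixture is
fitted to detection times; the number of components is chosen by BIC (or
a variational prune) and each detection is assigned to the component for
which it has the highest responsibility. Components whose time supports
overlap heavily are merged. Nest-box streams use the simpler rule of one
group per box per calendar day.

The resulting gathering events are the sampling units of the gambit of
the group: all members of an event are taken to be associating.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture

from flocknet.config import SECONDS_PER_DAY, SegmentationConfig


@dataclass
class GatheringEvent:
    """One detected foraging flock (or nest-box day-group)."""

    event_id: str
    location_id: str
    start_s: float
    end_s: float
    member_tags: frozenset[str]
    n_detections: int

    def __post_init__(self) -> None:
        if self.start_s > self.end_s:
            raise ValueError("start_s must be <= end_s")
        if not self.member_tags:
            raise ValueError("member_tags must be non-empty")


@dataclass
class GroupByIndividual:
    """K events x N individuals binary incidence matrix."""

    matrix: np.ndarray
    roster: list[str]
    event_ids: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]


def _derived_seed(location_id: str, day: int, root: int = 0) -> int:
    """Stable per-(location, day) seed: input order can never matter."""
    key = f"{location_id}:{day}:{root}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _k_cap(n: int, config: SegmentationConfig) -> int:
    # a component needs >= 2 supporting reads to be separable; K = n collapses
    return max(1, min(config.max_components_per_day, n // 2))


def _select_gmm(t: np.ndarray, config: SegmentationConfig, seed: int):
    """Fit mixtures of increasing order, return the BIC-best model."""
    k_max = _k_cap(t.shape[0], config)
    best, best_bic, since_best = None, np.inf, 0
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=config.n_init,
            init_params="k-means++",
            reg_covar=1.0,
            random_state=seed,
        ).fit(t)
        bic = gm.bic(t)
        if bic < best_bic - 1e-9:
            best, best_bic, since_best = gm, bic, 0
        else:
            since_best += 1
            if since_best >= config.bic_patience:
                break
    return best


def _variational_gmm(t: np.ndarray, config: SegmentationConfig, seed: int):
    k_max = _k_cap(t.shape[0], config)
    return BayesianGaussianMixture(
        n_components=k_max,
        covariance_type="full",
        weight_concentration_prior=1.0 / k_max,
        n_init=1,
        init_params="k-means++",
        reg_covar=1.0,
        max_iter=500,
        random_state=seed,
    ).fit(t)


def _merge_overlapping(labels: np.ndarray, t: np.ndarray, threshold: float):
    """Merge label groups whose time intervals overlap above threshold.

    Overlap fraction is overlap length over the shorter interval's length;
    a zero-length (single-detection) interval inside another counts as
    fully overlapping. Groups are scanned in chronological order and
    merging is transitive.
    """
    uniq = np.unique(labels)
    intervals = []
    for u in uniq:
        ts = t[labels == u]
        intervals.append((ts.min(), ts.max(), u))
    intervals.sort()

    merged_into = {u: u for u in uniq}
    cur_lo, cur_hi, cur_u = intervals[0]
    for lo, hi, u in intervals[1:]:
        overlap = min(cur_hi, hi) - max(cur_lo, lo)
        shorter = min(cur_hi - cur_lo, hi - lo)
        if shorter <= 0:
            frac = 1.0 if overlap >= 0 else 0.0
        else:
            frac = max(overlap, 0.0) / shorter
        if frac > threshold:
            merged_into[u] = merged_into[cur_u]
            cur_hi = max(cur_hi, hi)
        else:
            cur_lo, cur_hi, cur_u = lo, hi, u
    return np.array([merged_into[l] for l in labels])


def segment_stream(
    detections: pd.DataFrame,
    config: SegmentationConfig | None = None,
    event_prefix: str | None = None,
) -> list[GatheringEvent]:
    """Segment one location-day's detections into gathering events.

    Fits a 1-D Gaussian mixture to the timestamps, picks the order by the
    configured model-selection rule, assigns each detection to its
    maximum-responsibility component (ties broken toward the earlier, i.e.
    earlier-mean, component), merges components with heavily overlapping
    time supports, and drops events with fewer than
    ``min_event_detections`` detections. Event start/end are the min/max
    member detection times. An empty stream yields an empty list.
    """
    config = config or SegmentationConfig()
    if len(detections) == 0:
        return []
    if detections["location_id"].nunique() > 1:
        raise ValueError("segment_stream expects a single location")
    det = detections.sort_values(["timestamp", "tag_id"], kind="mergesort")
    try:
        t = det["timestamp"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("timestamps must be sortable numbers") from exc
    if np.any(~np.isfinite(t)):
        raise ValueError("timestamps must be finite")

    location = str(det["location_id"].iloc[0])
    day = int(t[0] // SECONDS_PER_DAY)
    seed = _derived_seed(location, day)
    prefix = event_prefix if event_prefix is not None else f"{location}-d{day}"

    if len(det) == 1 or np.ptp(t) == 0.0:
        labels = np.zeros(len(det), dtype=int)
    else:
        X = t.reshape(-1, 1)
        if config.model_selection == "bic":
            model = _select_gmm(X, config, seed)
        else:
            model = _variational_gmm(X, config, seed)
        resp = model.predict_proba(X)
        order = np.argsort(model.means_.ravel(), kind="stable")
        resp = resp[:, order]  # argmax takes the first max: earlier component wins ties
        labels = np.argmax(resp, axis=1)
        labels = _merge_overlapping(labels, t, config.merge_overlap_threshold)

    events: list[GatheringEvent] = []
    tags = det["tag_id"].to_numpy()
    k = 0
    for u in sorted(np.unique(labels), key=lambda u: t[labels == u].min()):
        mask = labels == u
        if int(mask.sum()) < config.min_event_detections:
            continue
        events.append(
            GatheringEvent(
                event_id=f"{prefix}-{k}",
                location_id=location,
                start_s=float(t[mask].min()),
                end_s=float(t[mask].max()),
                member_tags=frozenset(tags[mask]),
                n_detections=int(mask.sum()),
            )
        )
        k += 1
    return events


def detect_events(
    detections: pd.DataFrame, config: SegmentationConfig | None = None
) -> list[GatheringEvent]:
    """Run segmentation independently for every (location, day) in a stream."""
    if len(detections) == 0:
        return []
    det = detections.copy()
    det["_day"] = (det["timestamp"] // SECONDS_PER_DAY).astype(int)
    events: list[GatheringEvent] = []
    for (loc, day), grp in det.groupby(["location_id", "_day"], sort=True):
        events.extend(
            segment_stream(grp, config, event_prefix=f"{loc}-d{day}")
        )
    return events


def daily_nestbox_groups(detections: pd.DataFrame) -> list[GatheringEvent]:
    """One event per (nest-box, calendar day): members are that day's distinct visitors."""
    if len(detections) == 0:
        return []
    if not (detections["context"] == "nest_box").all():
        raise ValueError("daily_nestbox_groups expects nest_box context records")
    det = detections.copy()
    det["_day"] = (det["timestamp"] // SECONDS_PER_DAY).astype(int)
    events = []
    for (loc, day), grp in det.groupby(["location_id", "_day"], sort=True):
        events.append(
            GatheringEvent(
                event_id=f"{loc}-d{day}",
                location_id=str(loc),
                start_s=float(grp["timestamp"].min()),
                end_s=float(grp["timestamp"].max()),
                member_tags=frozenset(grp["tag_id"]),
                n_detections=len(grp),
            )
        )
    return events


def events_to_gbi(
    events: list[GatheringEvent], roster: list[str] | None = None
) -> GroupByIndividual:
    """Stack events into the K x N binary group-by-individual matrix.

    Roster defaults to the sorted union of member tags; row k has ones
    exactly at the members of event k.
    """
    ids = [e.event_id for e in events]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate event_ids")
    if roster is None:
        roster = sorted(set().union(*[e.member_tags for e in events])) if events else []
    else:
        roster = list(roster)
        missing = set().union(*[e.member_tags for e in events], set()) - set(roster)
        if missing:
            raise ValueError(f"member tags not in roster: {sorted(missing)[:5]}")
    index = {tag: j for j, tag in enumerate(roster)}
    mat = np.zeros((len(events), len(roster)), dtype=np.uint8)
    for k, e in enumerate(events):
        for tag in e.member_tags:
            mat[k, index[tag]] = 1
    return GroupByIndividual(matrix=mat, roster=roster, event_ids=ids)
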