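"""Synthetic RFID detection streams for the selective-feeder experiment.

Simulates a population of PIT-tagged birds visiting feeder sites in
fission-fusion flocks over three periods (pre / during / post
manipulation). During the manipulation each site is replaced by an
odd-only and an even-only feeder, imposing assortment by tag parity.
Two unmanipulated contexts — short-lived ephemeral food patches and
nest-box prospecting — are driven by the same latent social-preference
matrix, which is itself updated only by feeder co-foraging: that shared
matrix is the mechanism by which experimentally imposed structure carries
over into contexts with no restriction, and by which it dissolves again
within days once the restriction is lifted.

Two slower, parity-neutral processes give the networks realistic temporal
texture: spatial locality (each bird forages at 1-3 contiguous home
sites) and gradual home-range turnover (birds occasionally swap a home
site for a neighbouring one), so network structure drifts over weeks
independently of the treatment.

All randomness flows from ``ScenarioConfig.rng_seed`` through fixed
per-period / per-context stream offsets, so adding a context never
perturbs another's draws and identical configs give byte-identical
streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flocknet.config import (
    CONTEXT_FEEDER,
    CONTEXT_NESTBOX,
    CONTEXT_PATCH,
    PERIOD_DURING,
    PERIOD_POST,
    PERIOD_PRE,
    PERIODS,
    SECONDS_PER_DAY,
    ScenarioConfig,
)

# fixed stream offsets: adding a context never perturbs another stream
_STREAM_POPULATION = 0
_STREAM_PERIOD = {PERIOD_PRE: 1, PERIOD_DURING: 2, PERIOD_POST: 3}
_STREAM_MOBILITY = 4
_STREAM_PATCH = 10
_STREAM_NESTBOX = 11

DETECTION_COLUMNS = [
    "tag_id",
    "timestamp",
    "location_id",
    "context",
    "access_granted",
    "true_event_id",
]

_ODD_DIGITS = "13579"
_EVEN_DIGITS = "02468"


@dataclass(frozen=True)
class Individual:
    """One PIT-tagged bird; parity of the tag's last digit is its treatment class."""

    tag_id: str
    home_sites: tuple[str, ...]
    species_label: str | None = None

    @property
    def parity(self) -> str:
        return "odd" if int(self.tag_id[-1]) % 2 == 1 else "even"


@dataclass
class GroundTruth:
    """Generator-side truth: event memberships and latent preference snapshots."""

    events: pd.DataFrame  # event_id, context, period, location_id, day, t0, duration_s, members, n_detections
    preference_snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    preference_final: np.ndarray | None = None
    roster: list[str] = field(default_factory=list)


@dataclass
class ScenarioData:
    """Everything one simulated experiment produced."""

    config: ScenarioConfig
    population: list[Individual]
    detections: pd.DataFrame
    truth: GroundTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


# ---------------------------------------------------------------------------
# population and home-range drift
# ---------------------------------------------------------------------------

def make_population(config: ScenarioConfig) -> list[Individual]:
    """Create the tagged population with balanced parity classes.

    Tag IDs are unique digit strings whose last digit is assigned so the
    odd and even classes differ in size by at most one (the experiment
    splits the population into two equal random groups). Each individual
    holds 1-3 home sites chosen with spatial locality (contiguous on the
    ring of sites).
    """
    n = config.n_individuals
    if n < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = _rng(config.rng_seed, _STREAM_POPULATION)

    prefixes = rng.choice(np.arange(10_000, 100_000), size=n, replace=False)
    parities = np.arange(n) % 2  # 0 -> odd class, 1 -> even class; balanced
    rng.shuffle(parities)

    individuals = []
    for i in range(n):
        digit = rng.choice(list(_ODD_DIGITS if parities[i] == 0 else _EVEN_DIGITS))
        tag = f"{prefixes[i]:05d}{digit}"
        n_home = int(rng.integers(1, 4))
        centre = int(rng.integers(config.n_sites))
        sites = tuple(f"S{(centre + k) % config.n_sites}" for k in range(n_home))
        individuals.append(Individual(tag_id=tag, home_sites=sites))
    individuals.sort(key=lambda ind: ind.tag_id)
    return individuals


def home_site_timeline(
    population: list[Individual], config: ScenarioConfig
) -> np.ndarray:
    """Boolean [day, individual, site] array of home-site membership.

    Day 0 is the population's initial assignment; each subsequent day
    every individual swaps, with probability ``home_site_switch_rate``,
    one currently-used site for one of its ring neighbours. Membership is
    a deterministic function of (population, config), so independent
    period and context simulations always agree on who lives where.
    """
    n, s = len(population), config.n_sites
    days = config.total_days
    rng = _rng(config.rng_seed, _STREAM_MOBILITY)
    member = np.zeros((days, n, s), dtype=bool)
    cur = np.zeros((n, s), dtype=bool)
    for i, ind in enumerate(population):
        for site in ind.home_sites:
            cur[i, int(site[1:])] = True
    member[0] = cur
    for d in range(1, days):
        switch = rng.random(n) < config.home_site_switch_rate
        for i in np.nonzero(switch)[0]:
            used = np.nonzero(cur[i])[0]
            old = used[rng.integers(used.size)]
            new = (old + (1 if rng.random() < 0.5 else -1)) % s
            if not cur[i, new]:
                cur[i, old] = False
                cur[i, new] = True
        member[d] = cur
    return member


def _site_pools(member_day: np.ndarray) -> dict[str, np.ndarray]:
    return {
        f"S{j}": np.nonzero(member_day[:, j])[0]
        for j in range(member_day.shape[1])
    }


def _parity_vector(population: list[Individual]) -> np.ndarray:
    return np.array([ind.parity == "odd" for ind in population])


# ---------------------------------------------------------------------------
# preference dynamics
# ---------------------------------------------------------------------------

def update_preferences(
    P: np.ndarray, events: list[np.ndarray], rate: float
) -> np.ndarray:
    """Exponentially smooth the preference matrix toward today's co-memberships.

    ``P' = (1 - rate) * P + rate * C`` where C is the row-normalised (then
    symmetrised) co-membership count matrix of ``events`` (each event a
    sequence of member indices). Symmetry and the zero diagonal are
    preserved; rate 0 returns P unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P, P.T):
        raise ValueError("P must be symmetric")
    if rate == 0.0:
        return P.copy()

    n = P.shape[0]
    C = np.zeros((n, n))
    for members in events:
        m = np.asarray(members, dtype=int)
        if m.size >= 2:
            C[np.ix_(m, m)] += 1.0
    np.fill_diagonal(C, 0.0)
    row_sums = C.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Cn = np.where(row_sums > 0, C / row_sums, 0.0)
    Cn = 0.5 * (Cn + Cn.T)
    P_new = (1.0 - rate) * P + rate * Cn
    np.fill_diagonal(P_new, 0.0)
    return P_new


# ---------------------------------------------------------------------------
# flock composition
# ---------------------------------------------------------------------------

def _sample_flock(
    pool: np.ndarray,
    size: int,
    P: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequentially recruit a flock from ``pool``.

    The first member is uniform; each further candidate's weight is
    multiplied by ``1 + strength * P[c, m]`` for every member m already
    recruited, so social preference shapes composition multiplicatively.
    """
    if pool.size == 0:
        return np.empty(0, dtype=int)
    first = int(pool[rng.integers(pool.size)])
    members = [first]
    candidates = pool[pool != first]
    weights = 1.0 + strength * P[candidates, first]
    while len(members) < size and candidates.size > 0:
        probs = weights / weights.sum()
        j = rng.choice(candidates.size, p=probs)
        new = int(candidates[j])
        members.append(new)
        keep = np.arange(candidates.size) != j
        candidates = candidates[keep]
        weights = weights[keep] * (1.0 + strength * P[candidates, new])
    return np.array(members, dtype=int)


def _flock_size(mean_size: float, rng: np.random.Generator) -> int:
    """1 + Poisson(mean - 1): at least one bird, mean exactly ``mean_size``."""
    return 1 + int(rng.poisson(max(mean_size - 1.0, 0.0)))


def _sample_follower_set(
    off_pool: np.ndarray,
    flock: np.ndarray,
    n: int,
    P: np.ndarray,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mismatched-parity followers, weighted by preference toward the flock."""
    n = min(n, off_pool.size)
    weights = np.ones(off_pool.size)
    for m in flock:
        weights *= 1.0 + strength * P[off_pool, m]
    chosen = rng.choice(
        off_pool.size, size=n, replace=False, p=weights / weights.sum()
    )
    return off_pool[chosen]


def _emit_reads(
    rows: list,
    tags: list[str],
    member_idx: np.ndarray,
    granted: np.ndarray,
    t0: float,
    duration: float,
    event_id: int,
    location_id: str,
    context: str,
    reads_mean: float,
    rng: np.random.Generator,
) -> int:
    """Append antenna reads for one event; returns number of reads emitted."""
    n_reads_total = 0
    for idx, ok in zip(member_idx, granted):
        n_reads = 1 + int(rng.poisson(max(reads_mean - 1.0, 0.0)))
        times = t0 + rng.uniform(0.0, max(duration, 1e-9), size=n_reads)
        for t in times:
            rows.append((tags[idx], t, location_id, context, bool(ok), event_id))
        n_reads_total += n_reads
    return n_reads_total


# ---------------------------------------------------------------------------
# feeder-period simulation
# ---------------------------------------------------------------------------

def _simulate_feeder_day(
    day: int,
    restricted: bool,
    P: np.ndarray,
    parity_odd: np.ndarray,
    site_pools: dict[str, np.ndarray],
    tags: list[str],
    config: ScenarioConfig,
    rng: np.random.Generator,
    rows: list,
    event_rows: list,
    event_id_start: int,
    period: str,
    learning: bool,
) -> tuple[int, list[np.ndarray]]:
    """One day of feeder visitation; returns (next_event_id, day's event member lists)."""
    eid = event_id_start
    day_events: list[np.ndarray] = []
    for sid, pool in site_pools.items():
        if pool.size == 0:
            continue
        if not restricted:
            feeders = [(sid, None)]
            rate = config.event_rate_per_site_day
        else:
            feeders = [(f"{sid}O", True), (f"{sid}E", False)]
            rate = config.event_rate_per_site_day / 2.0
        for loc, odd_only in feeders:
            for _ in range(rng.poisson(rate)):
                t0 = day * SECONDS_PER_DAY + rng.uniform(0.0, SECONDS_PER_DAY)
                duration = rng.gamma(4.0, config.event_duration_s / 4.0)
                size = _flock_size(config.mean_flock_size, rng)
                if odd_only is None:
                    members = _sample_flock(
                        pool, size, P, config.preference_strength, rng
                    )
                    granted = np.ones(members.size, dtype=bool)
                else:
                    match_pool = pool[parity_odd[pool] == odd_only]
                    if match_pool.size == 0:
                        continue
                    members = _sample_flock(
                        match_pool, size, P, config.preference_strength, rng
                    )
                    # mismatched-parity birds occasionally follow flock-mates
                    # to a feeder that will not open for them
                    p_denied = 0.5 if learning else config.denied_visit_rate
                    n_denied = rng.binomial(members.size, p_denied)
                    granted = np.ones(members.size, dtype=bool)
                    if n_denied > 0:
                        off_pool = pool[parity_odd[pool] != odd_only]
                        if off_pool.size > 0:
                            denied = _sample_follower_set(
                                off_pool, members, n_denied, P,
                                config.preference_strength, rng,
                            )
                            members = np.concatenate([members, denied])
                            granted = np.concatenate(
                                [granted, np.zeros(denied.size, dtype=bool)]
                            )
                n_det = _emit_reads(
                    rows, tags, members, granted, t0, duration, eid, loc,
                    CONTEXT_FEEDER, config.reads_per_visit_mean, rng,
                )
                event_rows.append(
                    (eid, CONTEXT_FEEDER, period, loc, day, t0, duration,
                     tuple(tags[i] for i in members), n_det)
                )
                day_events.append(members)
                eid += 1
    return eid, day_events


def simulate_period(
    population: list[Individual],
    config: ScenarioConfig,
    period: str,
    P: np.ndarray,
    snapshot_days: tuple[int, ...] = (),
    _rng_override: np.random.Generator | None = None,
    _event_id_start: int = 0,
    _mobility: np.ndarray | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one feeder period and return (detections, ground truth).

    Events arise per site as Poisson bursts; flock composition is
    preference-weighted among the site's current residents. In the
    ``during`` period each site is replaced by an odd-only and an
    even-only feeder and the access flag records whether the feeder
    opened. The preference matrix is updated daily from realised
    (granted) co-foraging; requested ``snapshot_days`` (absolute scenario
    days) are stored in the returned ground truth, and
    ``preference_final`` holds the end-of-period matrix.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}")
    P = np.asarray(P, dtype=float)
    if not np.allclose(P, P.T) or np.any(np.diag(P) != 0):
        raise ValueError("P must be symmetric with zero diagonal")

    rng = _rng_override or _rng(config.rng_seed, _STREAM_PERIOD[period])
    parity_odd = _parity_vector(population)
    tags = [ind.tag_id for ind in population]
    mobility = (
        _mobility if _mobility is not None
        else home_site_timeline(population, config)
    )

    start_day = config.period_starts_days[period]
    n_days = dict(zip(PERIODS, config.period_lengths_days))[period]
    restricted = period == PERIOD_DURING

    rows: list = []
    event_rows: list = []
    snapshots: dict[int, np.ndarray] = {}
    P_cur = P.copy()
    eid = _event_id_start
    for d in range(n_days):
        day = start_day + d
        if day in snapshot_days:
            snapshots[day] = P_cur.copy()
        learning = restricted and d < config.relocation_lag_days
        eid, day_events = _simulate_feeder_day(
            day, restricted, P_cur, parity_odd, _site_pools(mobility[day]),
            tags, config, rng, rows, event_rows, eid, period, learning,
        )
        # denied reads do not feed the preference update: only realised
        # co-foraging (granted access) builds association
        granted_events = day_events if not restricted else [
            ev[parity_odd[ev] == parity_odd[ev[0]]] for ev in day_events
        ]
        P_cur = update_preferences(
            P_cur, granted_events, config.preference_update_rate
        )

    detections = _rows_to_frame(rows)
    truth = GroundTruth(
        events=_event_rows_to_frame(event_rows),
        preference_snapshots=snapshots,
        preference_final=P_cur,
        roster=tags,
    )
    return detections, truth


def _rows_to_frame(rows: list) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return df.sort_values(["timestamp", "tag_id"], kind="mergesort").reset_index(
        drop=True
    )


def _event_rows_to_frame(event_rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        event_rows,
        columns=[
            "event_id", "context", "period", "location_id", "day", "t0",
            "duration_s", "members", "n_detections",
        ],
    )


# ---------------------------------------------------------------------------
# unmanipulated contexts
# ---------------------------------------------------------------------------

def simulate_context(
    population: list[Individual],
    P: np.ndarray,
    context: str,
    config: ScenarioConfig,
    start_day: int = 0,
    n_days: int | None = None,
    deployment_id: int = 0,
    _rng_override: np.random.Generator | None = None,
    _event_id_start: int = 0,
    _mobility: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate an unmanipulated context driven by the preference matrix.

    ``ephemeral_patch``: ``config.n_patches`` short-lived feeding
    locations, each anchored at a random site, with burst events and
    preference-weighted recruitment but no access restriction.

    ``nest_box``: per box and calendar day a small visitor set (mean
    ``nestbox_mean_visitors`` conditional on any visit) sampled with
    preference-weighted joint-visit propensity — joint prospecting is a
    tie-driven activity, so its preference strength
    (``nestbox_preference_strength``) exceeds that of open foraging
    aggregations. Each landing emits one read. Boxes are assigned to
    sites round-robin.

    Ground-truth memberships are recoverable from ``true_event_id``.
    """
    if context not in (CONTEXT_PATCH, CONTEXT_NESTBOX):
        raise ValueError(f"unknown context {context!r}")
    P = np.asarray(P, dtype=float)
    tags = [ind.tag_id for ind in population]
    stream = _STREAM_PATCH if context == CONTEXT_PATCH else _STREAM_NESTBOX
    rng = _rng_override or _rng(
        config.rng_seed, stream + 100 * (deployment_id + 1) + start_day
    )
    mobility = (
        _mobility if _mobility is not None
        else home_site_timeline(population, config)
    )

    rows: list = []
    eid = _event_id_start
    if context == CONTEXT_PATCH:
        n_days = config.patch_days if n_days is None else n_days
        anchors = rng.integers(config.n_sites, size=config.n_patches)
        for d in range(n_days):
            day = min(start_day + d, mobility.shape[0] - 1)
            pools = _site_pools(mobility[day])
            for p in range(config.n_patches):
                loc = f"P{deployment_id}_{p}"
                pool = pools[f"S{anchors[p]}"]
                if pool.size == 0:
                    continue
                for _ in range(rng.poisson(config.patch_event_rate_per_day)):
                    t0 = (start_day + d) * SECONDS_PER_DAY + rng.uniform(
                        0, SECONDS_PER_DAY
                    )
                    duration = rng.gamma(4.0, config.event_duration_s / 4.0)
                    size = _flock_size(config.mean_flock_size, rng)
                    members = _sample_flock(
                        pool, size, P, config.preference_strength, rng
                    )
                    _emit_reads(
                        rows, tags, members, np.ones(members.size, bool), t0,
                        duration, eid, loc, CONTEXT_PATCH,
                        config.reads_per_visit_mean, rng,
                    )
                    eid += 1
    else:
        n_days = 1 if n_days is None else n_days
        for d in range(n_days):
            day = min(start_day + d, mobility.shape[0] - 1)
            pools = _site_pools(mobility[day])
            for b in range(config.n_nest_boxes):
                if rng.uniform() >= config.nestbox_occupancy:
                    continue
                loc = f"B{b:02d}"
                pool = pools[f"S{b % config.n_sites}"]
                if pool.size == 0:
                    continue
                n_vis = 1 + int(
                    rng.poisson(max(config.nestbox_mean_visitors - 1.0, 0.0))
                )
                members = _sample_flock(
                    pool, n_vis, P, config.nestbox_preference_strength, rng
                )
                for idx in members:
                    n_land = 1 + int(
                        rng.poisson(max(config.nestbox_landings_mean - 1.0, 0.0))
                    )
                    # prospecting concentrates in the morning hours
                    times = (start_day + d) * SECONDS_PER_DAY + rng.uniform(
                        8 * 3600, 16 * 3600, size=n_land
                    )
                    for t in times:
                        rows.append((tags[idx], t, loc, CONTEXT_NESTBOX, True, eid))
                eid += 1
    return _rows_to_frame(rows)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def true_events(detections: pd.DataFrame) -> pd.DataFrame:
    """Recover ground-truth event membership lists from true_event_id."""
    grouped = detections.groupby("true_event_id")
    return pd.DataFrame(
        {
            "event_id": grouped.size().index,
            "location_id": grouped["location_id"].first().values,
            "members": [tuple(sorted(set(g))) for _, g in grouped["tag_id"]],
            "n_detections": grouped.size().values,
        }
    ).reset_index(drop=True)


def simulate_scenario(config: ScenarioConfig) -> ScenarioData:
    """Run the full three-period experiment with both unmanipulated contexts.

    Feeder periods are simulated sequentially, threading the preference
    matrix (updated daily by co-foraging). Ephemeral-patch deployments use
    the preference snapshot at their start day; nest-box days use that
    day's snapshot, so carried-over (and subsequently dissolving) social
    structure is expressed faithfully in both contexts.
    """
    population = make_population(config)
    n = len(population)
    P = np.zeros((n, n))
    mobility = home_site_timeline(population, config)

    during_start = config.period_starts_days[PERIOD_DURING]
    post_start = config.period_starts_days[PERIOD_POST]

    nestbox_start = max(post_start - config.nestbox_days_before_post, during_start)
    nestbox_days = list(
        range(nestbox_start, min(nestbox_start + config.nestbox_total_days,
                                 config.total_days))
    )
    patch_starts = [(PERIOD_PRE, d) for d in config.patch_starts_pre] + [
        (PERIOD_DURING, during_start + d) for d in config.patch_starts_during
    ]

    want_snapshots = sorted(set(nestbox_days) | {d for _, d in patch_starts})

    frames = []
    event_frames = []
    snapshots: dict[int, np.ndarray] = {}
    eid = 0
    for period in PERIODS:
        det, truth = simulate_period(
            population, config, period, P,
            snapshot_days=tuple(want_snapshots), _event_id_start=eid,
            _mobility=mobility,
        )
        frames.append(det)
        event_frames.append(truth.events)
        snapshots.update(truth.preference_snapshots)
        P = truth.preference_final
        eid = int(truth.events["event_id"].max()) + 1 if len(truth.events) else eid

    def snap(day: int) -> np.ndarray:
        if day in snapshots:
            return snapshots[day]
        earlier = [d for d in snapshots if d <= day]
        if earlier:
            return snapshots[max(earlier)]
        return np.zeros((n, n))

    def _context_event_frame(det: pd.DataFrame, context: str) -> pd.DataFrame:
        if det.empty:
            return pd.DataFrame(columns=event_frames[0].columns)
        ev = true_events(det)
        g = det.groupby("true_event_id")["timestamp"]
        ev["t0"] = g.min().values
        ev["duration_s"] = (g.max() - g.min()).values
        ev["day"] = (ev["t0"] // SECONDS_PER_DAY).astype(int)
        ev["context"] = context
        ev["period"] = ev["day"].map(config.period_of_day)
        return ev[event_frames[0].columns]

    for k, (_period, day) in enumerate(patch_starts):
        det = simulate_context(
            population, snap(day), CONTEXT_PATCH, config,
            start_day=day, deployment_id=k, _event_id_start=eid,
            _mobility=mobility,
        )
        frames.append(det)
        event_frames.append(_context_event_frame(det, CONTEXT_PATCH))
        eid = int(det["true_event_id"].max()) + 1 if len(det) else eid

    for day in nestbox_days:
        det = simulate_context(
            population, snap(day), CONTEXT_NESTBOX, config,
            start_day=day, n_days=1, _event_id_start=eid,
            _mobility=mobility,
        )
        frames.append(det)
        event_frames.append(_context_event_frame(det, CONTEXT_NESTBOX))
        eid = int(det["true_event_id"].max()) + 1 if len(det) else eid

    detections = pd.concat(frames, ignore_index=True)
    detections = detections.sort_values(
        ["timestamp", "tag_id"], kind="mergesort"
    ).reset_index(drop=True)
    truth_all = GroundTruth(
        events=pd.concat(event_frames, ignore_index=True),
        preference_snapshots=snapshots,
        preference_final=P,
        roster=[ind.tag_id for ind in population],
    )
    return ScenarioData(
        config=config, population=population, detections=detections,
        truth=truth_all,
    )
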