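"""Configuration objects for simulation, event detection and analysis.

All configs are plain dataclasses that validate on construction and
round-trip to flat JSON, so every run can be reproduced from its sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

SECONDS_PER_DAY = 86_400

CONTEXT_FEEDER = "selective_feeder"
CONTEXT_PATCH = "ephemeral_patch"
CONTEXT_NESTBOX = "nest_box"
CONTEXTS = (CONTEXT_FEEDER, CONTEXT_PATCH, CONTEXT_NESTBOX)

PERIOD_PRE = "pre"
PERIOD_DURING = "during"
PERIOD_POST = "post"
PERIODS = (PERIOD_PRE, PERIOD_DURING, PERIOD_POST)


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic selective-feeder experiment.

    Defaults emulate the field deployment the package models: ~339 tagged
    birds using 6 feeder sites, a 40-day acclimation ("pre") period, 90
    days of parity-restricted access ("during", each site split into an
    odd-only and an even-only feeder) and a 6-day unrestricted "post"
    period; bursty flock visitation with mean flock size 3.8 and gathering
    events lasting about 191 s on average.

    Parameters
    ----------
    n_individuals:
        Number of PIT-tagged individuals in the population.
    n_sites:
        Number of feeder sites (each splits into two parity-restricted
        feeders during the manipulation).
    period_lengths_days:
        (pre, during, post) lengths in days.
    event_rate_per_site_day:
        Expected number of gathering events per feeder site per day
        (during the manipulation this rate is split evenly between the
        site's two parity feeders).
    mean_flock_size:
        Expected number of distinct individuals per gathering event.
    event_duration_s:
        Mean gathering-event duration in seconds (durations are gamma
        distributed around this mean).
    reads_per_visit_mean:
        Mean number of antenna reads an individual generates per event.
    preference_strength:
        Strength of social preference in flock recruitment: a candidate's
        sampling weight is multiplied by ``1 + strength * P[c, m]`` for
        every already-recruited member ``m``. 0 disables social structure.
    preference_update_rate:
        Daily exponential-smoothing rate in [0, 1] by which co-foraging
        updates the latent preference matrix.
    denied_visit_rate:
        Probability that an individual follows flock-mates to a feeder of
        mismatched parity (producing an access-denied antenna read) rather
        than relocating to its permitted feeder.
    relocation_lag_days:
        Days at the start of the manipulation before individuals have
        learned which feeder of each pair admits them (while learning, the
        denied-visit probability is 0.5).
    home_site_switch_rate:
        Daily probability that an individual swaps one home site for a
        neighbouring one. This slow, parity-neutral range turnover is what
        makes network structure drift gradually over weeks, independently
        of the manipulation.
    rng_seed:
        Root seed; all period and context streams are derived from it by
        fixed offsets.
    """

    n_individuals: int = 339
    n_sites: int = 6
    period_lengths_days: tuple[int, int, int] = (40, 90, 6)
    event_rate_per_site_day: float = 50.0
    mean_flock_size: float = 3.8
    event_duration_s: float = 191.0
    reads_per_visit_mean: float = 3.0
    preference_strength: float = 6.0
    preference_update_rate: float = 0.7
    home_site_switch_rate: float = 0.05
    denied_visit_rate: float = 0.1
    relocation_lag_days: int = 0
    rng_seed: int = 0

    # unmanipulated contexts
    n_patches: int = 4
    patch_days: int = 4
    patch_event_rate_per_day: float = 25.0
    patch_starts_pre: tuple[int, ...] = (20,)
    patch_starts_during: tuple[int, ...] = (10, 24, 38, 52)
    n_nest_boxes: int = 44
    nestbox_preference_strength: float = 60.0
    nestbox_mean_visitors: float = 1.7
    nestbox_occupancy: float = 0.8
    nestbox_landings_mean: float = 3.0
    nestbox_days_before_post: int = 12
    nestbox_total_days: int = 24

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        self.period_lengths_days = tuple(self.period_lengths_days)  # type: ignore[assignment]
        if len(self.period_lengths_days) != 3 or any(
            d < 1 for d in self.period_lengths_days
        ):
            raise ValueError("period_lengths_days must be three values >= 1 day")
        for name in (
            "event_rate_per_site_day",
            "mean_flock_size",
            "event_duration_s",
            "reads_per_visit_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.preference_strength < 0:
            raise ValueError("preference_strength must be nonnegative")
        if not 0.0 <= self.preference_update_rate <= 1.0:
            raise ValueError("preference_update_rate must be in [0, 1]")
        if not 0.0 <= self.home_site_switch_rate <= 1.0:
            raise ValueError("home_site_switch_rate must be in [0, 1]")
        if not 0.0 <= self.denied_visit_rate <= 1.0:
            raise ValueError("denied_visit_rate must be in [0, 1]")
        self.patch_starts_pre = tuple(self.patch_starts_pre)  # type: ignore[assignment]
        self.patch_starts_during = tuple(self.patch_starts_during)  # type: ignore[assignment]

    # -- period bookkeeping ------------------------------------------------
    @property
    def period_starts_days(self) -> dict[str, int]:
        pre, during, _post = self.period_lengths_days
        return {PERIOD_PRE: 0, PERIOD_DURING: pre, PERIOD_POST: pre + during}

    @property
    def total_days(self) -> int:
        return sum(self.period_lengths_days)

    def period_of_day(self, day: int) -> str:
        pre, during, _ = self.period_lengths_days
        if day < pre:
            return PERIOD_PRE
        if day < pre + during:
            return PERIOD_DURING
        return PERIOD_POST

    # -- (de)serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def scaled_demo_config(seed: int = 0) -> ScenarioConfig:
    """A desk-scale scenario preserving the study's structure.

    100 individuals, 6 sites, 10/20/6-day periods, and proportionally
    reduced visitation, so a full simulate-detect-analyse cycle runs in
    minutes on one CPU while keeping every qualitative feature of the
    experiment (parity restriction, carry-over contexts, recovery).
    """
    return ScenarioConfig(
        n_individuals=100,
        n_sites=6,
        period_lengths_days=(10, 20, 6),
        event_rate_per_site_day=12.0,
        reads_per_visit_mean=2.0,
        rng_seed=seed,
        patch_starts_pre=(3,),
        patch_starts_during=(6, 13),
        patch_days=3,
        n_patches=4,
        patch_event_rate_per_day=12.0,
        n_nest_boxes=12,
        nestbox_days_before_post=6,
        nestbox_total_days=12,
    )


@dataclass
class SegmentationConfig:
    """Controls Gaussian-mixture segmentation of a location-day stream.

    ``model_selection`` is either ``"bic"`` (fit K = 1..max, keep the
    lowest BIC, stopping early once BIC has not improved for
    ``bic_patience`` consecutive K) or ``"variational"`` (one Bayesian
    mixture fit at the cap, empty components pruned).
    """

    max_components_per_day: int = 50
    min_event_detections: int = 1
    model_selection: str = "bic"
    merge_overlap_threshold: float = 0.8
    n_init: int = 3
    bic_patience: int = 3

    def __post_init__(self) -> None:
        if self.max_components_per_day < 1:
            raise ValueError("max_components_per_day must be >= 1")
        if self.min_event_detections < 1:
            raise ValueError("min_event_detections must be >= 1")
        if self.model_selection not in ("bic", "variational"):
            raise ValueError("model_selection must be 'bic' or 'variational'")
        if not 0.0 <= self.merge_overlap_threshold <= 1.0:
            raise ValueError("merge_overlap_threshold must be in [0, 1]")


@dataclass
class AnalysisPlan:
    """What the full-experiment analysis computes and with which settings."""

    window_days: int = 6
    n_perm: int = 10_000
    n_boot: int = 1_000
    seed: int = 0
    include_denied_visits: bool = True
    patch_lag_days: int = 4
    nestbox_split_days: int = 3
    alpha: float = 0.05
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
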