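"""Generator tests: population structure, access rules, preference dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocknet.config import SECONDS_PER_DAY, ScenarioConfig, scaled_demo_config
from flocknet.synthetic import (
    make_population,
    simulate_context,
    simulate_period,
    simulate_scenario,
    true_events,
    update_preferences,
)


def _cfg(**kw) -> ScenarioConfig:
    base = dict(
        n_individuals=40,
        n_sites=4,
        period_lengths_days=(3, 4, 2),
        event_rate_per_site_day=10.0,
        rng_seed=0,
        patch_starts_pre=(1,),
        patch_starts_during=(1,),
        patch_days=2,
        n_nest_boxes=6,
        nestbox_days_before_post=2,
        nestbox_total_days=4,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestPopulation:
    def test_parity_classes_balanced(self):
        pop = make_population(_cfg(n_individuals=10, rng_seed=1))
        odd = sum(ind.parity == "odd" for ind in pop)
        assert odd == 5

    @given(n=st.integers(2, 60), seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_balance_uniqueness_and_home_sites(self, n, seed):
        pop = make_population(_cfg(n_individuals=n, rng_seed=seed))
        odd = sum(ind.parity == "odd" for ind in pop)
        assert abs(odd - (n - odd)) <= 1
        assert len({ind.tag_id for ind in pop}) == n
        assert all(1 <= len(ind.home_sites) <= 3 for ind in pop)

    def test_population_size_matches_study_roster(self):
        pop = make_population(ScenarioConfig(n_individuals=339))
        assert len(pop) == 339

    def test_determinism(self):
        cfg = _cfg(rng_seed=5)
        assert make_population(cfg) == make_population(cfg)

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_individuals=1)


class TestFeederPeriods:
    def test_pre_period_grants_all_access(self, scaled_scenario):
        det = scaled_scenario.detections
        day = det["timestamp"] // SECONDS_PER_DAY
        pre = det[(det["context"] == "selective_feeder") & (day < 10)]
        assert pre["access_granted"].all()
        post = det[(det["context"] == "selective_feeder") & (day >= 30)]
        assert post["access_granted"].all()

    def test_denied_reads_only_during_at_mismatched_feeder(self, scaled_scenario):
        det = scaled_scenario.detections
        denied = det[~det["access_granted"]]
        day = denied["timestamp"] // SECONDS_PER_DAY
        assert ((day >= 10) & (day < 30)).all()
        assert (denied["context"] == "selective_feeder").all()
        # mismatched parity: odd birds denied only at even feeders and v.v.
        parity = denied["tag_id"].str[-1].astype(int) % 2
        feeder_is_odd = denied["location_id"].str.endswith("O")
        assert ((parity == 1) != feeder_is_odd).all()

    def test_granted_members_of_restricted_events_single_parity(
        self, scaled_scenario
    ):
        det = scaled_scenario.detections
        day = det["timestamp"] // SECONDS_PER_DAY
        dur = det[(det["context"] == "selective_feeder") & (day >= 10) & (day < 30)]
        granted = dur[dur["access_granted"]]
        parities = granted["tag_id"].str[-1].astype(int) % 2
        n_par = granted.assign(p=parities).groupby("true_event_id")["p"].nunique()
        assert (n_par == 1).all()

    def test_zero_denied_rate_makes_every_restricted_event_single_parity(self):
        cfg = _cfg(denied_visit_rate=0.0, rng_seed=2)
        pop = make_population(cfg)
        det, _ = simulate_period(pop, cfg, "during", np.zeros((40, 40)))
        assert det["access_granted"].all()
        par = det["tag_id"].str[-1].astype(int) % 2
        n_par = det.assign(p=par).groupby("true_event_id")["p"].nunique()
        assert (n_par == 1).all()

    def test_realized_flock_size_matches_config(self, scaled_scenario):
        ev = scaled_scenario.truth.events
        pre = ev[(ev["context"] == "selective_feeder") & (ev["period"] == "pre")]
        assert len(pre) >= 500
        sizes = pre["members"].map(lambda m: len(set(m)))
        assert abs(sizes.mean() - 3.8) / 3.8 < 0.10

    def test_event_durations_match_config_within_3se(self, scaled_scenario):
        ev = scaled_scenario.truth.events
        feeder = ev[ev["context"] == "selective_feeder"]
        assert len(feeder) >= 1000
        d = feeder["duration_s"]
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean() - 191.0) < 3 * se + 1e-9

    def test_unknown_period_rejected(self):
        cfg = _cfg()
        pop = make_population(cfg)
        P = np.zeros((len(pop), len(pop)))
        with pytest.raises(ValueError, match="period"):
            simulate_period(pop, cfg, "interim", P)

    def test_asymmetric_preference_rejected(self):
        cfg = _cfg()
        pop = make_population(cfg)
        P = np.zeros((len(pop), len(pop)))
        P[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            simulate_period(pop, cfg, "pre", P)


class TestDeterminism:
    def test_identical_configs_give_identical_streams(self):
        cfg = _cfg(rng_seed=11)
        a = simulate_scenario(cfg).detections
        b = simulate_scenario(cfg).detections
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_scenario(_cfg(rng_seed=1)).detections
        b = simulate_scenario(_cfg(rng_seed=2)).detections
        assert not a.equals(b)


class TestPreferences:
    def test_zero_rate_is_identity(self, rng):
        P = rng.random((6, 6))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0)
        np.testing.assert_array_equal(update_preferences(P, [[0, 1, 2]], 0.0), P)

    def test_full_rate_forgets_noncooccurring_pairs(self):
        P = np.zeros((4, 4))
        P[0, 3] = P[3, 0] = 0.9
        P2 = update_preferences(P, [np.array([0, 1]), np.array([1, 2])], 1.0)
        assert P2[0, 3] == 0.0

    def test_symmetry_and_zero_diagonal_preserved(self, rng):
        P = rng.random((8, 8))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0)
        events = [rng.choice(8, size=3, replace=False) for _ in range(5)]
        P2 = update_preferences(P, events, 0.4)
        np.testing.assert_allclose(P2, P2.T)
        assert (np.diag(P2) == 0).all()

    def test_asymmetric_input_rejected(self):
        P = np.zeros((3, 3))
        P[0, 1] = 1.0
        with pytest.raises(ValueError):
            update_preferences(P, [], 0.5)

    def test_manipulation_builds_within_parity_preference(self):
        cfg = _cfg(n_individuals=60, period_lengths_days=(2, 8, 2), rng_seed=3)
        pop = make_population(cfg)
        P0 = np.zeros((60, 60))
        _, truth = simulate_period(pop, cfg, "during", P0)
        P = truth.preference_final
        odd = np.array([ind.parity == "odd" for ind in pop])
        same = odd[:, None] == odd[None, :]
        np.fill_diagonal(same, False)
        cross = ~same
        np.fill_diagonal(cross, False)
        assert P[same].mean() > P[cross].mean()


class TestContexts:
    def test_unknown_context_rejected(self):
        cfg = _cfg()
        pop = make_population(cfg)
        with pytest.raises(ValueError, match="context"):
            simulate_context(pop, np.zeros((40, 40)), "roost", cfg)

    def test_nestbox_mean_visitors_configurable(self):
        cfg = _cfg(n_individuals=80, n_nest_boxes=40, nestbox_occupancy=1.0,
                   rng_seed=9)
        pop = make_population(cfg)
        det = simulate_context(pop, np.zeros((80, 80)), "nest_box", cfg,
                               start_day=0, n_days=8)
        per_box_day = det.groupby(
            ["location_id", det["timestamp"] // SECONDS_PER_DAY]
        )["tag_id"].nunique()
        se = per_box_day.std() / np.sqrt(len(per_box_day))
        assert abs(per_box_day.mean() - 1.7) < 3 * se + 0.05

    def test_patch_records_unrestricted(self, scaled_scenario):
        det = scaled_scenario.detections
        patch = det[det["context"] == "ephemeral_patch"]
        assert len(patch) > 0
        assert patch["access_granted"].all()

    def test_ground_truth_recoverable_from_true_event_id(self, scaled_scenario):
        det = scaled_scenario.detections
        ev = true_events(det[det["context"] == "ephemeral_patch"])
        assert (ev["members"].map(len) >= 1).all()
        assert ev["n_detections"].sum() == len(
            det[det["context"] == "ephemeral_patch"]
        )

    def test_carryover_polarises_patch_events_during_manipulation(
        self, scaled_scenario
    ):
        """During the manipulation, patch flocks should mix parities less
        than expected under random composition."""
        det = scaled_scenario.detections
        day = det["timestamp"] // SECONDS_PER_DAY
        patch = det[(det["context"] == "ephemeral_patch") & (day >= 10)]
        par = patch["tag_id"].str[-1].astype(int) % 2
        frac_pure = (
            patch.assign(p=par).groupby("true_event_id")["p"]
            .agg(lambda s: s.nunique() == 1)
        )
        sizes = patch.groupby("true_event_id")["tag_id"].nunique()
        multi = sizes[sizes >= 2].index
        observed = frac_pure.loc[multi].mean()
        # random parity mixing would leave ~2^(1-k) of k-bird flocks pure
        expected_random = np.mean(
            [2.0 ** (1 - k) for k in sizes.loc[multi]]
        )
        assert observed > expected_random
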