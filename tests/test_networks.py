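"""Half-weight-index networks, windowing, spatial overlap, alignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from flocknet.groups import GroupByIndividual
from flocknet.networks import (
    AssociationNetwork,
    align_common,
    common_roster,
    hwi,
    site_of_location,
    spatial_overlap,
    subset,
    window_networks,
)


def _gbi(mat, roster=None):
    mat = np.asarray(mat, dtype=np.uint8)
    roster = roster or [f"T{i}" for i in range(mat.shape[1])]
    return GroupByIndividual(matrix=mat, roster=roster,
                            event_ids=[str(k) for k in range(mat.shape[0])])


def _hwi_counting_oracle(mat):
    """Half-weight index by explicit event counting with Python sets."""
    K, N = mat.shape
    out = np.zeros((N, N))
    for a in range(N):
        for b in range(N):
            if a == b:
                continue
            x = sum(1 for k in range(K) if mat[k, a] and mat[k, b])
            ya = sum(1 for k in range(K) if mat[k, a] and not mat[k, b])
            yb = sum(1 for k in range(K) if mat[k, b] and not mat[k, a])
            if x + ya + yb:
                out[a, b] = x / (x + (ya + yb) / 2)
    return out


class TestHWI:
    def test_worked_example(self):
        # x = 3 joint events, yA = 1, yB = 2 -> 3 / (3 + 1.5) = 2/3
        mat = [[1, 1], [1, 1], [1, 1], [1, 0], [0, 1], [0, 1]]
        net = hwi(_gbi(mat, ["A1", "B2"]))
        assert net.W[0, 1] == pytest.approx(2 / 3, abs=1e-12)

    def test_identical_event_sets_score_one(self):
        net = hwi(_gbi([[1, 1], [1, 1], [1, 1]], ["A1", "B2"]))
        assert net.W[0, 1] == 1.0

    def test_never_cooccurring_score_zero(self):
        net = hwi(_gbi([[1, 0], [0, 1]], ["A1", "B2"]))
        assert net.W[0, 1] == 0.0

    def test_matches_counting_oracle_full_enumeration(self):
        """All binary GBIs with N=3 individuals and K<=4 events."""
        for K in (1, 2, 3, 4):
            for bits in itertools.product([0, 1], repeat=3 * K):
                mat = np.array(bits, dtype=np.uint8).reshape(K, 3)
                if not mat.any():
                    continue
                expected = _hwi_counting_oracle(mat)
                net = hwi(_gbi(mat))
                keep = mat.sum(axis=0) > 0
                np.testing.assert_allclose(
                    net.W, expected[np.ix_(keep, keep)], atol=1e-12
                )

    def test_matches_counting_oracle_random_larger(self, rng):
        for _ in range(300):
            mat = (rng.random((5, 4)) < 0.5).astype(np.uint8)
            if not mat.any():
                continue
            expected = _hwi_counting_oracle(mat)
            keep = mat.sum(axis=0) > 0
            np.testing.assert_allclose(
                hwi(_gbi(mat)).W, expected[np.ix_(keep, keep)], atol=1e-12
            )

    @given(mat=arrays(np.uint8, shape=(6, 5), elements=st.integers(0, 1)))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_bounded_zero_diagonal(self, mat):
        if not mat.any():
            return
        net = hwi(_gbi(mat))
        assert np.allclose(net.W, net.W.T)
        assert (net.W >= 0).all() and (net.W <= 1).all()
        assert (np.diag(net.W) == 0).all()

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            hwi(_gbi([[2, 1]]))

    def test_unobserved_individuals_dropped(self):
        net = hwi(_gbi([[1, 1, 0]], ["A", "B", "C"]))
        assert net.roster == ["A", "B"]


def _detections(days, per_day=3, location="S0"):
    rows = []
    for d in range(days):
        for k in range(per_day):
            rows.append(
                {
                    "tag_id": f"T{k}",
                    "timestamp": d * 86_400.0 + 30_000 + 60 * k,
                    "location_id": location,
                    "context": "selective_feeder",
                    "access_granted": True,
                    "true_event_id": d,
                }
            )
    return pd.DataFrame(rows)


class TestWindows:
    def test_twelve_days_two_windows(self):
        nets = window_networks(_detections(12), window_days=6)
        assert len(nets) == 2

    def test_ninety_day_period_gives_fifteen_windows(self):
        nets = window_networks(_detections(90, per_day=2), window_days=6)
        assert len(nets) == 15

    def test_window_partition_covers_every_day(self):
        det = _detections(12)
        nets = window_networks(det, window_days=5)
        assert len(nets) == 3  # days 0-4, 5-9, 10-11

    def test_pooling_windows_differs_from_averaging(self):
        """HWI of concatenated windows is not the mean of window HWIs."""
        m1 = _gbi([[1, 1], [1, 0]], ["A", "B"])
        m2 = _gbi([[1, 1]], ["A", "B"])
        w1, w2 = hwi(m1).W[0, 1], hwi(m2).W[0, 1]
        pooled = hwi(_gbi([[1, 1], [1, 0], [1, 1]], ["A", "B"])).W[0, 1]
        assert pooled != pytest.approx((w1 + w2) / 2)


class TestSpatialOverlap:
    def test_parity_feeders_collapse_to_parent_site(self):
        assert site_of_location("S3O") == "S3"
        assert site_of_location("S3E") == "S3"
        assert site_of_location("S11") == "S11"
        with pytest.raises(ValueError):
            site_of_location("B07")

    def test_disjoint_sites_score_zero_shared_site_scores_one(self):
        df = pd.DataFrame(
            {
                "tag_id": ["A", "B", "C", "C"],
                "timestamp": [1.0, 2.0, 3.0, 4.0],
                "location_id": ["S2", "S5", "S2", "S5"],
                "context": "selective_feeder",
                "access_granted": True,
                "true_event_id": -1,
            }
        )
        m = spatial_overlap(df)
        i = {t: k for k, t in enumerate(m.roster)}
        assert m.B[i["A"], i["B"]] == 0
        assert m.B[i["A"], i["C"]] == 1
        assert m.B[i["B"], i["C"]] == 1

    def test_matches_set_intersection_oracle(self, rng, scaled_scenario):
        det = scaled_scenario.detections
        day = det["timestamp"] // 86_400
        sub = det[(det["context"] == "selective_feeder") & (day >= 12) & (day < 15)]
        m = spatial_overlap(sub)
        sites = {
            tag: set(grp["location_id"].map(site_of_location))
            for tag, grp in sub.groupby("tag_id")
        }
        idx = rng.choice(len(m.roster), size=40)
        for a, b in zip(idx[::2], idx[1::2]):
            if a == b:
                continue
            expected = int(bool(sites[m.roster[a]] & sites[m.roster[b]]))
            assert m.B[a, b] == expected


class TestAlignment:
    def _net(self, roster, rng):
        n = len(roster)
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        return AssociationNetwork(roster=roster, W=W)

    def test_restricts_to_sorted_intersection(self, rng):
        a = self._net(["A", "B", "C", "D"], rng)
        b = self._net(["B", "C", "D", "E"], rng)
        a2, b2 = align_common(a, b)
        assert a2.roster == b2.roster == ["B", "C", "D"]

    def test_identical_rosters_unchanged(self, rng):
        a = self._net(["A", "B", "C"], rng)
        b = self._net(["A", "B", "C"], rng)
        a2, b2 = align_common(a, b)
        np.testing.assert_array_equal(a2.W, a.W)
        np.testing.assert_array_equal(b2.W, b.W)

    def test_surviving_dyad_values_unchanged(self, rng):
        a = self._net(["A", "B", "C", "D", "E"], rng)
        b = self._net(["B", "C", "D", "E", "F"], rng)
        a2, _ = align_common(a, b)
        for x, y in itertools.combinations(a2.roster, 2):
            assert a2.W[a2.roster.index(x), a2.roster.index(y)] == pytest.approx(
                a.W[a.roster.index(x), a.roster.index(y)]
            )

    def test_small_overlap_rejected(self, rng):
        a = self._net(["A", "B", "C"], rng)
        b = self._net(["C", "D", "E"], rng)
        with pytest.raises(ValueError, match="share"):
            align_common(a, b)

    def test_common_roster_and_subset_consistent(self, rng):
        nets = [self._net(list("ABCDE"), rng), self._net(list("BCDEF"), rng),
                self._net(list("CDEFG"), rng)]
        roster = common_roster(*nets)
        assert roster == ["C", "D", "E"]
        assert subset(nets[0], roster).roster == roster
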