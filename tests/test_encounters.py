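import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from flygroup.encounters import (
    EncounterRecord,
    XMeans,
    classify_outcome,
    detect_encounters,
    encounter_records,
    group_size_at,
    join_prob_by_size,
    percent_joining,
    walking_mask,
)
from flygroup.grouping import GroupingSeries, grouping_series, proximal_radius

from conftest import CALO, CALO_IR, make_traj, static_traj


def series_of(bits, fly_id=0):
    b = np.array(bits, dtype=bool)
    return GroupingSeries(
        fly_id=fly_id, t=np.arange(b.size, dtype=float), belongs=b,
        stay_events=[], total_grouping_duration_s=0.0, n_stay=0,
    )


class TestWalkingMask:
    def test_stationary_fly_never_walks(self):
        traj = static_traj([(0, 0), (20, 0), (0, 20)], duration_s=30)
        assert not walking_mask(traj, CALO).any()

    def test_steady_two_mm_per_s_walks(self):
        t = np.arange(30)
        pos = np.stack([
            np.column_stack([2.0 * t - 30, np.zeros(30)]),
            np.column_stack([np.full(30, 30.0), np.zeros(30)]),
        ])
        traj = make_traj(pos)
        w = walking_mask(traj, CALO)
        assert w[0, 1:].all() and not w[0, 0]
        assert not w[1].any()

    def test_infrared_threshold_reclassifies_slow_walkers(self):
        t = np.arange(30)
        pos = np.stack([
            np.column_stack([1.5 * t - 20, np.zeros(30)]),
            np.column_stack([np.full(30, 30.0), np.zeros(30)]),
        ])
        traj = make_traj(pos)
        assert walking_mask(traj, CALO)[0, 1:].all()  # white light: walking
        assert not walking_mask(traj, CALO_IR).any()  # infrared: stopping


class TestDetectEncounters:
    def test_transition_after_six_seconds_walking(self):
        s = series_of([False] * 6 + [True] * 10)
        walking = np.array([True] * 6 + [False] * 10)
        assert detect_encounters(s, walking) == [(0, 6)]

    def test_four_seconds_walking_is_insufficient(self):
        s = series_of([False] * 6 + [True] * 10)
        walking = np.array([False, False] + [True] * 4 + [False] * 10)
        assert detect_encounters(s, walking) == []

    def test_stopped_fly_has_no_encounter(self):
        s = series_of([False] * 6 + [True] * 10)
        walking = np.zeros(16, dtype=bool)
        assert detect_encounters(s, walking) == []

    def test_bridged_gap_cannot_spawn_encounter(self):
        bits = [True] * 8 + [False] * 3 + [True] * 8
        from flygroup.grouping import bridge_gaps
        s = series_of(bridge_gaps(np.array(bits)))
        walking = np.ones(len(bits), dtype=bool)
        # The gap was filled, so the only false->true transition is gone.
        assert detect_encounters(s, walking) == []


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "stay,expected", [(12, "join"), (8, "leave"), (10, "join")]
    )
    def test_ten_second_rule(self, stay, expected):
        bits = [False] * 6 + [True] * stay + [False] * 15
        rec = classify_outcome((0, 6), series_of(bits))
        assert rec.outcome == expected
        assert rec.stay_len_s == stay

    def test_censored_at_recording_end(self):
        bits = [False] * 6 + [True] * 7  # still grouped when record ends
        rec = classify_outcome((0, 6), series_of(bits))
        assert rec.outcome is None


class TestPercentJoining:
    def test_two_of_four(self):
        recs = [
            EncounterRecord(0, t, None, o, 0)
            for t, o in [(1, "join"), (2, "leave"), (3, "join"), (4, "leave")]
        ]
        assert percent_joining(recs) == 50.0

    def test_all_joins(self):
        recs = [EncounterRecord(0, 1, None, "join", 20)]
        assert percent_joining(recs) == 100.0

    def test_no_encounters_has_no_value(self):
        assert percent_joining([]) is None
        censored = [EncounterRecord(0, 1, None, None, 5)]
        assert percent_joining(censored) is None


def _blob(rng, center, n, sd=0.5):
    return rng.normal(center, sd, (n, 2))


class TestXMeans:
    def test_two_separated_blobs_match_connected_components(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([_blob(rng, (0, 0), 5), _blob(rng, (40, 0), 7)])
        xm = XMeans(random_state=0).fit(pts)
        sizes = sorted(np.bincount(xm.labels_))
        d = squareform(pdist(pts)) <= proximal_radius(CALO)
        n_cc, cc = connected_components(d, directed=False)
        assert sizes == sorted(np.bincount(cc))
        assert xm.n_clusters_ == n_cc == 2

    def test_single_tight_cluster_is_not_split(self):
        rng = np.random.default_rng(1)
        for k in (3, 6, 12):
            xm = XMeans(random_state=0).fit(_blob(rng, (5, 5), k, sd=0.4))
            assert xm.n_clusters_ == 1
            assert np.bincount(xm.labels_)[0] == k

    def test_partition_covers_all_points(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([
            _blob(rng, (0, 0), 6), _blob(rng, (30, 0), 4),
            _blob(rng, (0, 30), 5),
        ])
        xm = XMeans(random_state=0).fit(pts)
        assert np.bincount(xm.labels_).sum() == len(pts)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([_blob(rng, (0, 0), 8), _blob(rng, (25, 10), 9)])
        a = XMeans(random_state=0).fit(pts).labels_
        b = XMeans(random_state=0).fit(pts).labels_
        np.testing.assert_array_equal(a, b)


class TestGroupSize:
    def test_focal_reads_size_of_nearest_cluster(self):
        rng = np.random.default_rng(4)
        grouped = np.vstack([_blob(rng, (-20, 0), 5), _blob(rng, (20, 0), 7)])
        focal = np.array([[16.0, 2.0]])
        pts = np.vstack([grouped, focal])
        traj = static_traj(pts, duration_s=2)
        size = group_size_at(traj, np.arange(12), 0, encountered_fly=12)
        assert size == 7

    def test_single_cluster_size_counts_all_grouped(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([_blob(rng, (0, 0), 6), [[10.0, 0.0]]])
        traj = static_traj(pts, duration_s=2)
        assert group_size_at(traj, np.arange(6), 0, encountered_fly=6) == 6

    def test_too_few_grouped_flies_is_an_error(self):
        traj = static_traj([(0, 0), (1, 0), (30, 30)], duration_s=2)
        with pytest.raises(ValueError):
            group_size_at(traj, np.array([0]), 0, encountered_fly=2)

    def test_sizes_match_connected_components_when_well_separated(self, short_sims):
        """On simulated data, whenever clusters are separated by more than
        4x the proximal radius, the x-means group size agrees with the size
        of the focal fly's nearest connected component."""
        traj = short_sims[0]
        species = CALO
        series = grouping_series(traj, species)
        recs = encounter_records(traj, species, series=series)
        belongs = np.vstack([s.belongs for s in series])
        checked = 0
        for rec in recs:
            if rec.group_size is None:
                continue
            t = rec.t_s - 1
            grouped = [i for i in range(traj.n_flies)
                       if belongs[i, t] and i != rec.fly_id]
            if len(grouped) < 2:
                t = rec.t_s
                grouped = [i for i in range(traj.n_flies)
                           if belongs[i, t] and i != rec.fly_id]
            pos = traj.positions_at_time(t)[grouped]
            adj = squareform(pdist(pos)) <= proximal_radius(species)
            n_cc, cc = connected_components(adj, directed=False)
            # inter-component separation check
            min_sep = np.inf
            for a in range(n_cc):
                for b in range(a + 1, n_cc):
                    min_sep = min(
                        min_sep,
                        np.min(np.linalg.norm(
                            pos[cc == a][:, None] - pos[cc == b][None], axis=-1
                        )),
                    )
            if n_cc > 1 and min_sep <= 4 * proximal_radius(species):
                continue
            focal = traj.positions_at_time(t)[rec.fly_id]
            d_to = [np.min(np.linalg.norm(pos[cc == a] - focal, axis=1))
                    for a in range(n_cc)]
            expected = int(np.sum(cc == int(np.argmin(d_to))))
            assert rec.group_size == expected
            checked += 1
        assert checked > 0


class TestJoinBySize:
    def test_single_fly_curve(self):
        recs = [
            EncounterRecord(0, 1, 3, "join", 20),
            EncounterRecord(0, 2, 5, "leave", 2),
            EncounterRecord(0, 3, 5, "leave", 1),
        ]
        curve = join_prob_by_size(recs).set_index("group_size")
        assert curve.loc[3, "mean_join_pct"] == 100.0
        assert curve.loc[5, "mean_join_pct"] == 0.0
        assert curve.loc[5, "n_events"] == 2

    def test_fly_level_averaging_not_event_pooling(self):
        recs = (
            [EncounterRecord(0, t, 4, "join", 20) for t in range(3)]
            + [EncounterRecord(1, 9, 4, "leave", 1)]
        )
        curve = join_prob_by_size(recs).set_index("group_size")
        # Event pooling would give 75%; fly-level averaging gives 50%.
        assert curve.loc[4, "mean_join_pct"] == 50.0
        assert curve.loc[4, "n_events"] == 4

    def test_join_events_start_stay_events(self, short_sims):
        """The 10-s join rule and the 10-s stay rule agree: every join
        coincides with the start of a detected stay event."""
        traj = short_sims[0]
        series = grouping_series(traj, CALO)
        recs = encounter_records(traj, CALO, series=series)
        starts = {s.fly_id: {a for a, _ in s.stay_events} for s in series}
        joins = [r for r in recs if r.outcome == "join"]
        assert joins, "expected at least one join in the strong regime"
        for rec in joins:
            assert any(abs(rec.t_s - a) <= 1 for a in starts[rec.fly_id])

    def test_join_counts_bounded_by_encounters(self, short_sims):
        for traj in short_sims[:2]:
            recs = encounter_records(traj, CALO)
            for fid in np.unique([r.fly_id for r in recs]):
                mine = [r for r in recs if r.fly_id == fid]
                pct = percent_joining(mine)
                if pct is not None:
                    assert 0.0 <= pct <= 100.0
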