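"""Distances, approaches, huddling, activity — checked against naive scans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import colonytrack as ct
from conftest import START_08, START_14, build_session, random_walk_session
import oracles


def _stationary_session(d_ab: float, T: int = 7200, start=START_08, **kw):
    pos = {"A": np.tile([100.0, 100.0], (T, 1)),
           "B": np.tile([100.0 + d_ab, 100.0], (T, 1))}
    return build_session(pos, start=start, **kw)


class TestDistances:
    def test_three_four_five(self):
        rec = build_session({"A": np.tile([0.0, 0.0], (10, 1)),
                             "B": np.tile([30.0, 40.0], (10, 1))})
        d = ct.distance_series(rec)[("A", "B")]
        assert np.all(d.d_mm == 50.0)

    def test_coincident_mice(self):
        rec = build_session({"A": np.tile([5.0, 5.0], (10, 1)),
                             "B": np.tile([5.0, 5.0], (10, 1))})
        assert np.all(ct.distance_series(rec)[("A", "B")].d_mm == 0.0)

    def test_pair_count(self):
        rec = random_walk_session(4, 50, seed=1)
        assert len(ct.distance_series(rec)) == 6

    def test_binned_mean_matches_oracle(self):
        rec = random_walk_session(2, 5400, seed=2)
        ds = ct.distance_series(rec)[("M0", "M1")]
        got = ct.mean_distance_binned(ds, rec, 30)
        want = oracles.naive_binned_mean(ds.t, ds.d_mm, rec.start_clock_s, 1800)
        assert len(got) == len(want)
        for _, row in got.iterrows():
            assert row["mean_d_mm"] == pytest.approx(want[row["gbin"]], rel=1e-12)

    def test_binned_mean_halves(self):
        # one aligned 30-min bin: half the seconds at 40 mm, half at 80 mm
        T = 1800
        bx = np.concatenate([np.full(T // 2, 140.0), np.full(T // 2, 180.0)])
        rec = build_session({"A": np.tile([100.0, 100.0], (T, 1)),
                             "B": np.column_stack([bx, np.full(T, 100.0)])},
                            start=START_08)
        out = ct.mean_distance_binned(ct.distance_series(rec)[("A", "B")], rec, 30)
        assert out["mean_d_mm"].iloc[0] == pytest.approx(60.0)

    def test_constant_distance_every_bin(self):
        rec = _stationary_session(80.0, T=3 * 1800)
        out = ct.mean_distance_binned(ct.distance_series(rec)[("A", "B")], rec, 30)
        assert np.allclose(out["mean_d_mm"], 80.0)


class TestApproaches:
    def _walk_in_session(self):
        # B fixed at origin area; A walks in along x at 5 mm/s from 120 mm,
        # crossing 60 mm between t=11 and t=12, then leaves at 5 mm/s
        ax = np.concatenate([120.0 - 5.0 * np.arange(13),   # t=0..12: 120→60
                             60.0 + 5.0 * np.arange(1, 10)])  # t=13.. leaves
        ax[12] = 55.0  # d(12)=55 < 60; d(11)=65
        pos = {"A": np.column_stack([100.0 + ax, np.full(len(ax), 100.0)]),
               "B": np.tile([100.0, 100.0], (len(ax), 1))}
        return build_session(pos)

    def test_single_event_onset_end_approacher(self):
        rec = self._walk_in_session()
        ds = ct.distance_series(rec)[("A", "B")]
        events = ct.detect_approaches(ds, rec)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_onset == 12
        assert ds.d_mm[ev.t_onset] < 60 <= ds.d_mm[ev.t_onset - 1]
        assert ds.d_mm[ev.t_end] >= 60
        assert ev.approacher == "A" and ev.approached == "B"
        assert ev.approacher_defined
        assert ev.duration_s == ev.t_end - ev.t_onset

    def test_stationary_close_pair_yields_no_events(self):
        rec = _stationary_session(50.0)
        ds = ct.distance_series(rec)[("A", "B")]
        assert ct.detect_approaches(ds, rec) == []
        # but huddle logic still applies
        hs = ct.detect_huddles(ds, rec)
        assert hs.bins["is_huddle"].all()

    def test_exactly_at_radius_is_outside(self):
        rec = _stationary_session(60.0)
        ds = ct.distance_series(rec)[("A", "B")]
        assert ct.detect_approaches(ds, rec) == []

    def test_tied_lookback_marks_approacher_undefined(self):
        # both mice step inward symmetrically: identical path lengths
        T = 40
        ax = 10.0 + 3.0 * np.arange(T)
        bx = 230.0 - 3.0 * np.arange(T)
        pos = {"A": np.column_stack([ax, np.full(T, 50.0)]),
               "B": np.column_stack([bx, np.full(T, 50.0)])}
        rec = build_session(pos)
        ds = ct.distance_series(rec)[("A", "B")]
        events = ct.detect_approaches(ds, rec)
        assert len(events) >= 1
        assert not events[0].approacher_defined
        assert events[0].approacher == "A"  # deterministic smaller id

    @given(st.integers(0, 10 ** 6))
    def test_event_list_matches_per_second_scan(self, seed):
        rec = random_walk_session(2, 600, seed=seed)
        ds = ct.distance_series(rec)[("M0", "M1")]
        got = [(ev.t_onset, ev.t_end) for ev in ct.detect_approaches(ds, rec)]
        assert got == oracles.naive_events(ds.d_mm, 60.0)

    def test_event_partition_covers_below_radius_seconds(self):
        rec = random_walk_session(3, 1200, seed=7)
        for pair, ds in ct.distance_series(rec).items():
            events = ct.detect_approaches(ds, rec)
            covered = np.zeros(len(ds.t), bool)
            for ev in events:
                assert not covered[ev.t_onset:ev.t_end].any()  # disjoint
                covered[ev.t_onset:ev.t_end] = True
            below = ds.d_mm < 60.0
            # the partition may miss only an initial run with no crossing
            first_out = np.argmin(below) if below[0] else 0
            np.testing.assert_array_equal(covered[first_out:], below[first_out:])

    def test_imputed_samples_count_zero_displacement(self):
        # A is unobserved after t=0 (carried in place), B walks in: only B's
        # real locomotion counts toward the approacher decision
        T = 30
        t = np.arange(T)
        b = ct.Trajectory("B", t, 100.0 + 2.0 * t, np.full(T, 100.0),
                          np.ones(T, bool))
        a = ct.Trajectory("A", t, np.full(T, 200.0), np.full(T, 100.0),
                          np.r_[True, np.zeros(T - 1, bool)])
        chamber = ct.ChamberSpec.rectangle(240, 240)
        schedule = ct.LightSchedule.from_clock()
        rec = ct.SessionRecording(chamber, schedule, START_14, [a, b]).impute()
        ds = ct.distance_series(rec)[("A", "B")]
        events = ct.detect_approaches(ds, rec)
        assert len(events) == 1
        assert events[0].approacher == "B" and events[0].approacher_defined


class TestApproachCounts:
    def test_division_by_possible_ordered_pairs(self):
        # 4 GH mice -> 12 ordered GH->GH pairs; 24 events in one bin -> mean 2
        T = 1800
        rng = np.random.default_rng(0)
        pos = {f"M{k}": rng.uniform(60, 180, (T, 2)) for k in range(4)}
        rec = build_session(pos, start=START_08)
        events = []
        ids = rec.ids
        for k in range(24):
            a, b = ids[k % 4], ids[(k + 1) % 4]
            events.append(ct.ApproachEvent(ct.pair_key(a, b), 10 + k, 20 + k, a, b))
        out = ct.approach_counts(events, rec, bin_minutes=30)
        row = out[(out["gbin"] == 0) & (out["direction"] == "GHtoGH")].iloc[0]
        assert row["n_possible_pairs"] == 12
        assert row["mean_per_pair"] == pytest.approx(2.0)

    def test_mixed_chamber_pair_combinatorics(self):
        T = 60
        pos = {m: np.tile([100.0, 100.0], (T, 1)) for m in ("G1", "G2", "S1", "S2")}
        rec = build_session(pos, groups={"G1": "GH", "G2": "GH",
                                         "S1": "SI", "S2": "SI"})
        out = ct.approach_counts([], rec, bin_minutes=30)
        n = out.drop_duplicates("direction").set_index("direction")["n_possible_pairs"]
        assert n["GHtoSI"] == 4 and n["SItoGH"] == 4  # heterogeneous: 8 total
        assert n["GHtoGH"] == 2 and n["SItoSI"] == 2  # homogeneous: 4 total

    def test_zero_events_zero_means(self):
        rec = random_walk_session(2, 60, seed=3)
        out = ct.approach_counts([], rec, bin_minutes=30)
        assert (out["mean_per_pair"] == 0).all()


class TestDurationClasses:
    def test_examples(self):
        def ev(d):
            return ct.ApproachEvent(("A", "B"), 0, d, "A", "B")
        assert ct.duration_class_counts([ev(1), ev(1), ev(5)]) == (2, 0, 1)
        assert ct.duration_class_counts([]) == (0, 0, 0)

    @given(st.lists(st.integers(0, 10), max_size=50))
    def test_partition_against_histogram(self, durations):
        events = [ct.ApproachEvent(("A", "B"), 0, d, "A", "B") for d in durations]
        lo, mid, hi = ct.duration_class_counts(events)
        assert lo == sum(1 for d in durations if d < 2)
        assert mid == sum(1 for d in durations if 2 <= d <= 3)
        assert hi == sum(1 for d in durations if d > 3)
        assert lo + mid + hi == len(durations)


class TestHuddles:
    def test_constant_50_always_huddle(self):
        hsrec = _stationary_session(50.0)
        hs = ct.detect_huddles(ct.distance_series(hsrec)[("A", "B")], hsrec)
        assert hs.bins["is_huddle"].all()

    def test_exactly_60_never_huddle(self):
        rec = _stationary_session(60.0)
        hs = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        assert not hs.bins["is_huddle"].any()

    def test_split_bin_mean_65_not_huddle(self):
        T = 1800
        bx = np.concatenate([np.full(900, 130.0), np.full(900, 200.0)])
        rec = build_session({"A": np.tile([100.0, 100.0], (T, 1)),
                             "B": np.column_stack([bx, np.full(T, 100.0)])},
                            start=START_08)
        hs = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        assert hs.bins["mean_d_mm"].iloc[0] == pytest.approx(65.0)
        assert not hs.bins["is_huddle"].iloc[0]

    def test_huddle_flags_match_oracle(self):
        rec = random_walk_session(2, 4 * 1800 + 123, seed=11, start=START_14)
        ds = ct.distance_series(rec)[("M0", "M1")]
        hs = ct.detect_huddles(ds, rec)
        want = oracles.naive_huddle_bins(ds.t, ds.d_mm, rec.start_clock_s)
        for _, row in hs.bins.iterrows():
            m, flag = want[row["gbin"]]
            assert row["mean_d_mm"] == pytest.approx(m, rel=1e-12)
            assert bool(row["is_huddle"]) == flag

    def test_radius_monotonicity(self):
        rec = random_walk_session(2, 7200, seed=13)
        ds = ct.distance_series(rec)[("M0", "M1")]
        counts = [ct.detect_huddles(ds, rec, radius_mm=r).bins["is_huddle"].sum()
                  for r in (30, 60, 90, 120)]
        assert counts == sorted(counts)


class TestHuddleLatency:
    def _series_with_first_huddle_in_bin(self, k, n_bins=10):
        T = n_bins * 1800
        d = np.full(T, 100.0)
        d[k * 1800:(k + 1) * 1800] = 30.0
        bx = 100.0 + d
        rec = build_session({"A": np.tile([100.0, 100.0], (T, 1)),
                             "B": np.column_stack([bx, np.full(T, 100.0)])},
                            start=START_08)
        return ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)

    def test_first_bin_gives_half_hour(self):
        assert ct.huddle_latency(self._series_with_first_huddle_in_bin(0)).hours == 0.5

    def test_bin_8_gives_4_5_hours(self):
        lat = ct.huddle_latency(self._series_with_first_huddle_in_bin(8))
        assert lat.hours == 4.5 and not lat.censored

    def test_censored_returns_total_hours(self):
        rec = _stationary_session(100.0, T=72 * 1800)  # 36 h apart
        hs = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        lat = ct.huddle_latency(hs)
        assert lat.censored and lat.hours == pytest.approx(36.0)


class TestHuddlePercentage:
    def test_formula(self):
        # day 1 from 08:00: light phase bins 0..23; 12 huddled
        T = 86400
        d = np.full(T, 100.0)
        d[:12 * 1800] = 30.0
        rec = build_session({"A": np.tile([100.0, 100.0], (T, 1)),
                             "B": np.column_stack([100.0 + d, np.full(T, 100.0)])},
                            start=START_08)
        hs = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        pct, partial = ct.huddle_percentage(hs, day=1, phase=0)
        assert pct == 50.0 and not partial
        pct_dark, _ = ct.huddle_percentage(hs, day=1, phase=1)
        assert pct_dark == 0.0

    def test_partial_phase_flagged(self):
        rec = _stationary_session(30.0, T=3600, start=START_08)
        hs = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        pct, partial = ct.huddle_percentage(hs, day=1, phase=0)
        assert partial
        assert pct == pytest.approx(100.0 * 2 / 24)


class TestHuddleOrder:
    def _huddles(self, first_bins):
        out = {}
        for k, (pair, b) in enumerate(first_bins.items()):
            T = 12 * 1800
            d = np.full(T, 100.0)
            if b is not None:
                d[b * 1800:(b + 1) * 1800] = 30.0
            rec = build_session({"A": np.tile([100.0, 100.0], (T, 1)),
                                 "B": np.column_stack([100.0 + d, np.full(T, 100.0)])},
                                start=START_08)
            out[pair] = ct.detect_huddles(ct.distance_series(rec)[("A", "B")], rec)
        return out

    def test_distinct_bins_one_first_one_last(self):
        pairs = {(f"M{i}", f"N{i}"): i for i in range(6)}
        cats = ct.huddle_order(self._huddles(pairs))
        vals = list(cats.values())
        assert vals.count("first") == 1 and vals.count("last") == 1
        assert vals.count("intermediate") == 4
        assert cats[("M0", "N0")] == "first" and cats[("M5", "N5")] == "last"

    def test_tied_earliest_share_first(self):
        cats = ct.huddle_order(self._huddles({("A", "B"): 0, ("C", "D"): 0,
                                              ("E", "F"): 3}))
        assert cats[("A", "B")] == cats[("C", "D")] == "first"
        assert cats[("E", "F")] == "last"

    def test_never_huddled_ranks_last(self):
        cats = ct.huddle_order(self._huddles({("A", "B"): 1, ("C", "D"): None}))
        assert cats[("A", "B")] == "first" and cats[("C", "D")] == "last"

    def test_no_huddles_error(self):
        with pytest.raises(ValueError):
            ct.huddle_order(self._huddles({("A", "B"): None}))


class TestActivity:
    def test_constant_walk_unit_conversion(self):
        # zig-zag between x=100 and x=110: exactly 10 mm every second
        T = 1800
        xs = np.where(np.arange(T) % 2 == 0, 100.0, 110.0)
        rec = build_session({"A": np.column_stack([xs, np.full(T, 10.0)]),
                             "B": np.tile([5.0, 5.0], (T, 1))}, start=START_08)
        act = ct.activity_series(rec.trajectory("A"))
        assert np.all(act.v_mm_s == 10.0)
        binned = ct.activity_binned(act, rec, 30)
        assert binned["mean_mm_s"].iloc[0] == pytest.approx(10.0)
        assert binned["mean_cm_min"].iloc[0] == pytest.approx(60.0)

    def test_immobile_zero(self):
        rec = _stationary_session(100.0, T=100)
        act = ct.activity_series(rec.trajectory("A"))
        assert np.all(act.v_mm_s == 0.0)

    def test_total_distance_matches_path_length(self):
        rec = random_walk_session(1, 500, seed=5)
        tr = rec.trajectory("M0")
        act = ct.activity_series(tr)
        assert act.v_mm_s.sum() == pytest.approx(
            oracles.naive_path_length(tr.x, tr.y), rel=1e-12)


class TestActivityCorrelation:
    def _session_with_activity(self, vec_a, vec_b, per_bin=300):
        # build positions whose per-5-min mean activity equals the given vectors
        def walk(vec):
            xs = [10.0]
            for v in vec:
                for s in range(per_bin):
                    step = v if s % 2 == 0 else -v
                    xs.append(xs[-1] + step)
            return np.array(xs[1:])
        T = per_bin * len(vec_a)
        rec = build_session({"A": np.column_stack([walk(vec_a), np.full(T, 50.0)]),
                             "B": np.column_stack([walk(vec_b), np.full(T, 60.0)])},
                            start=START_08)
        return rec

    def test_identical_activity_r_one(self):
        rec = self._session_with_activity([1, 5, 3, 8], [1, 5, 3, 8])
        m = ct.activity_correlation(rec)
        assert m.loc["A", "B"] == pytest.approx(1.0)

    def test_immobile_mouse_undefined(self):
        rec = self._session_with_activity([1, 5, 3, 8], [0, 0, 0, 0])
        m = ct.activity_correlation(rec)
        assert np.isnan(m.loc["A", "B"])
        assert m.loc["A", "A"] == 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        va, vb = rng.uniform(1, 9, 6), rng.uniform(1, 9, 6)
        rec = self._session_with_activity(va, vb)
        m = ct.activity_correlation(rec)
        ba = ct.activity_binned(ct.activity_series(rec.trajectory("A")), rec, 5)
        bb = ct.activity_binned(ct.activity_series(rec.trajectory("B")), rec, 5)
        x, y = ba["mean_mm_s"].to_numpy(), bb["mean_mm_s"].to_numpy()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert m.loc["A", "B"] == pytest.approx(r, rel=1e-9)

    def test_too_few_bins_error(self):
        rec = _stationary_session(50.0, T=400)
        with pytest.raises(ValueError):
            ct.activity_correlation(rec)


class TestGeometricInvariance:
    def test_translation_and_rotation_leave_metrics_unchanged(self):
        rec = random_walk_session(3, 900, seed=21)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = []
        big = ct.ChamberSpec.rectangle(2000, 2000)
        for tr in rec.trajectories:
            p = (tr.positions() @ R.T) + np.array([400.0, 500.0])
            moved.append(ct.Trajectory(tr.mouse_id, tr.t, p[:, 0], p[:, 1],
                                       tr.observed, tr.group))
        rec_big = ct.SessionRecording(big, rec.schedule, rec.start,
                                      [ct.Trajectory(tr.mouse_id, tr.t,
                                                     tr.x + 800, tr.y + 800,
                                                     tr.observed, tr.group)
                                       for tr in rec.trajectories])
        rec2 = ct.SessionRecording(big, rec.schedule, rec.start, moved)
        for pair in ct.distance_series(rec):
            d0 = ct.distance_series(rec)[pair].d_mm
            np.testing.assert_allclose(ct.distance_series(rec2)[pair].d_mm, d0,
                                       rtol=1e-9)
            e0 = [(e.t_onset, e.t_end, e.approacher)
                  for e in ct.detect_approaches(ct.distance_series(rec)[pair], rec)]
            e2 = [(e.t_onset, e.t_end, e.approacher)
                  for e in ct.detect_approaches(ct.distance_series(rec2)[pair], rec2)]
            assert e0 == e2

    def test_relabelling_permutes_outputs(self):
        rec = random_walk_session(3, 600, seed=22)
        ren = {"M0": "Z9", "M1": "A1", "M2": "K5"}
        rec2 = ct.SessionRecording(
            rec.chamber, rec.schedule, rec.start,
            [ct.Trajectory(ren[tr.mouse_id], tr.t, tr.x, tr.y, tr.observed,
                           tr.group) for tr in rec.trajectories])
        d1 = ct.distance_series(rec)
        d2 = ct.distance_series(rec2)
        for pair, ds in d1.items():
            new_pair = ct.pair_key(ren[pair[0]], ren[pair[1]])
            np.testing.assert_array_equal(d2[new_pair].d_mm, ds.d_mm)
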