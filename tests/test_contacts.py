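import numpy as np
import pytest

from contactrsf import contacts as cmod
from contactrsf.contacts import (
    ContactEvent,
    PairRecord,
    classify_pair,
    detect_contacts,
    filter_pairs,
    temporal_intersection,
)
from contactrsf.errors import InsufficientDataError, InvalidArgumentError


def brute_force_contacts(a, b, buffer_m):
    """Exhaustive all-pairs-of-timestamps scan (oracle)."""
    out = []
    for i, ta in enumerate(a.times):
        for j, tb in enumerate(b.times):
            if ta == tb:
                d = float(np.hypot(a.x[i] - b.x[j], a.y[i] - b.y[j]))
                if d <= buffer_m:
                    out.append((ta, d))
    return out


def regular(make_track, minutes, x, y, animal_id):
    return make_track(minutes, x, y, animal_id=animal_id, regular=True, interval_min=5.0)


class TestTemporalIntersection:
    def test_overlapping(self, make_track):
        a = make_track([0, 100], [0, 0], [0, 0], animal_id="a")
        b = make_track([50, 150], [0, 0], [0, 0], animal_id="b")
        start, end = temporal_intersection(a, b)
        assert start == b.times[0] and end == a.times[-1]

    def test_disjoint_signals_empty(self, make_track):
        a = make_track([0, 10], [0, 0], [0, 0], animal_id="a")
        b = make_track([20, 30], [0, 0], [0, 0], animal_id="b")
        assert temporal_intersection(a, b) is None

    def test_identical_windows(self, make_track):
        a = make_track([0, 60], [0, 0], [0, 0], animal_id="a")
        b = make_track([0, 60], [1, 1], [1, 1], animal_id="b")
        assert temporal_intersection(a, b) == (a.times[0], a.times[-1])


class TestDetect:
    def test_buffer_boundary(self, make_track):
        t = [0.0, 5.0]
        a = regular(make_track, t, [0.0, 0.0], [0.0, 0.0], "a")
        b = regular(make_track, t, [9.0, 11.0], [0.0, 0.0], "b")
        events = detect_contacts(a, b)
        assert len(events) == 1 and events[0].timestamp == a.times[0]
        assert events[0].distance == pytest.approx(9.0)
        # exactly at the buffer counts (inclusive)
        c = regular(make_track, t, [10.0, 10.0], [0.0, 0.0], "c")
        assert len(detect_contacts(a, c)) == 2

    def test_identical_trajectories_all_contacts(self, make_track):
        t = np.arange(0, 50, 5.0)
        x = np.cumsum(np.ones(len(t)))
        a = regular(make_track, t, x, x, "a")
        b = regular(make_track, t, x, x, "b")
        events = detect_contacts(a, b)
        assert len(events) == len(t)
        assert all(e.distance == 0.0 for e in events)
        # contact location is the midpoint
        assert events[0].x == pytest.approx(x[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, make_track, seed):
        rng = np.random.default_rng(seed)
        ta = np.arange(0, 250, 5.0)
        tb = np.arange(25, 300, 5.0)
        a = regular(make_track, ta, rng.normal(0, 8, len(ta)), rng.normal(0, 8, len(ta)), "a")
        b = regular(make_track, tb, rng.normal(0, 8, len(tb)), rng.normal(0, 8, len(tb)), "b")
        events = detect_contacts(a, b)
        oracle = brute_force_contacts(a, b, 10.0)
        assert [(e.timestamp, e.distance) for e in events] == oracle

    def test_symmetry(self, make_track):
        rng = np.random.default_rng(3)
        t = np.arange(0, 100, 5.0)
        a = regular(make_track, t, rng.normal(0, 6, len(t)), rng.normal(0, 6, len(t)), "a")
        b = regular(make_track, t, rng.normal(0, 6, len(t)), rng.normal(0, 6, len(t)), "b")
        assert detect_contacts(a, b) == detect_contacts(b, a)

    def test_buffer_monotonicity(self, make_track):
        rng = np.random.default_rng(4)
        t = np.arange(0, 200, 5.0)
        a = regular(make_track, t, rng.normal(0, 10, len(t)), rng.normal(0, 10, len(t)), "a")
        b = regular(make_track, t, rng.normal(0, 10, len(t)), rng.normal(0, 10, len(t)), "b")
        counts = [len(detect_contacts(a, b, buffer_m=r)) for r in (2, 5, 10, 20, 50)]
        assert counts == sorted(counts)

    def test_mismatched_intervals_rejected(self, make_track):
        a = make_track([0, 5], [0, 0], [0, 0], animal_id="a", regular=True, interval_min=5.0)
        b = make_track([0, 10], [0, 0], [0, 0], animal_id="b", regular=True, interval_min=10.0)
        with pytest.raises(InvalidArgumentError):
            detect_contacts(a, b)


def cloud_track(make_track, animal_id, center, n_weeks, rng, n_per_week=60, spread=40.0):
    """Fixes clustered around a center, spanning n_weeks ISO weeks."""
    minutes, xs, ys = [], [], []
    for w in range(n_weeks):
        base = w * 7 * 1440
        minutes.extend(base + np.sort(rng.choice(7 * 1440, n_per_week, replace=False)))
        xs.extend(rng.normal(center[0], spread, n_per_week))
        ys.extend(rng.normal(center[1], spread, n_per_week))
    return make_track(np.array(minutes, float), xs, ys, animal_id=animal_id)


class TestClassify:
    def test_fm_dyad_bypasses_kde(self, make_track, tiny_grid):
        a = make_track([0, 10], [0, 0], [0, 0], animal_id="a")
        b = make_track([0, 10], [500, 500], [500, 500], animal_id="b")
        rec = classify_pair(a, b, {"a": "F", "b": "M"}, tiny_grid)
        assert rec.dyad_class == "FM" and rec.relationship == "between"
        assert rec.weekly_overlap == {}

    def test_ff_identical_tracks_within(self, make_track, tiny_grid):
        rng = np.random.default_rng(7)
        a = cloud_track(make_track, "a", (300, 300), 3, rng)
        b = make_track(a.times.astype("int64") / 6e10 - a.times.astype("int64")[0] / 6e10,
                       a.x, a.y, animal_id="b")
        b = cloud_track(make_track, "b", (300, 300), 3, np.random.default_rng(7))
        rec = classify_pair(a, b, {"a": "F", "b": "F"}, tiny_grid)
        assert rec.relationship == "within"

    def test_ff_disjoint_ranges_between(self, make_track, tiny_grid):
        rng = np.random.default_rng(8)
        a = cloud_track(make_track, "a", (120, 120), 3, rng)
        b = cloud_track(make_track, "b", (480, 480), 3, rng)
        rec = classify_pair(a, b, {"a": "F", "b": "F"}, tiny_grid)
        assert rec.relationship == "between"
        assert all(v == 0.0 for v in rec.weekly_overlap.values())

    def test_insufficient_weeks(self, make_track, tiny_grid):
        rng = np.random.default_rng(9)
        a = cloud_track(make_track, "a", (300, 300), 1, rng)
        b = cloud_track(make_track, "b", (300, 300), 1, rng)
        with pytest.raises(InsufficientDataError):
            classify_pair(a, b, {"a": "F", "b": "F"}, tiny_grid)

    def test_below_threshold_week_never_flips_between_to_within(self, make_track, tiny_grid):
        rng = np.random.default_rng(10)
        a = cloud_track(make_track, "a", (150, 150), 4, rng)
        b = cloud_track(make_track, "b", (450, 450), 4, rng)
        rec4 = classify_pair(a, b, {"a": "F", "b": "F"}, tiny_grid)
        a5 = cloud_track(make_track, "a", (150, 150), 5, np.random.default_rng(10))
        b5 = cloud_track(make_track, "b", (450, 450), 5, np.random.default_rng(10))
        rec5 = classify_pair(a5, b5, {"a": "F", "b": "F"}, tiny_grid)
        assert rec4.relationship == "between"
        assert rec5.relationship == "between"


class TestFilter:
    def _rec(self, n, relationship="between"):
        return PairRecord(
            pair=("a", "b"),
            dyad_class="FF",
            relationship=relationship,
            window=(np.datetime64("2020-01-01"), np.datetime64("2020-02-01")),
            n_contacts=n,
        )

    def test_strict_threshold(self):
        kept = filter_pairs([self._rec(9), self._rec(10), self._rec(11)])
        assert [r.n_contacts for r in kept] == [11]

    def test_empty_input(self):
        assert filter_pairs([]) == []

    def test_within_group_excluded_regardless_of_count(self):
        assert filter_pairs([self._rec(500, relationship="within")]) == []

    def test_included_flag_invariant(self):
        with pytest.raises(InvalidArgumentError):
            PairRecord(
                pair=("a", "b"), dyad_class="FF", relationship="between",
                window=(np.datetime64("2020-01-01"), np.datetime64("2020-02-01")),
                n_contacts=3, included=True,
            )


def test_contacts_csv_roundtrip(tmp_path, make_track):
    rng = np.random.default_rng(11)
    t = np.arange(0, 100, 5.0)
    a = regular(make_track, t, rng.normal(0, 5, len(t)), rng.normal(0, 5, len(t)), "a")
    b = regular(make_track, t, rng.normal(0, 5, len(t)), rng.normal(0, 5, len(t)), "b")
    events = cmod.detect_contacts(a, b)
    assert events
    path = cmod.write_contacts_csv(events, tmp_path / "c.csv")
    back = cmod.read_contacts_csv(path)
    assert len(back) == len(events)
    assert back[0].pair == events[0].pair
    assert back[0].timestamp == events[0].timestamp
    assert back[0].distance == pytest.approx(events[0].distance, abs=1e-6)


def test_pair_records_roundtrip(tmp_path):
    rec = PairRecord(
        pair=("a", "b"), dyad_class="FM", relationship="between",
        window=(np.datetime64("2020-01-01T00:00:00.000000000"),
                np.datetime64("2020-02-01T00:00:00.000000000")),
        weekly_overlap={"2020-01-06": 0.25}, n_contacts=12, included=True,
    )
    path = cmod.write_pair_records([rec], tmp_path / "p.jsonl")
    back = cmod.read_pair_records(path)
    assert back[0].pair == rec.pair
    assert back[0].n_contacts == 12
    assert back[0].weekly_overlap == rec.weekly_overlap
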