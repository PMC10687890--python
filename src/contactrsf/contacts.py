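"""Direct-contact detection and dyad classification.

A direct contact is the co-location of two animals at the same discretized
timestamp within a spatial buffer (default 10 m, inclusive) that absorbs
GPS location error.  Female-female dyads are classified as within-group,
between-group or temporarily-same-group from their weekly kernel-density
core-area overlap; male-involved dyads are treated as between-group.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from contactrsf.errors import InsufficientDataError, InvalidArgumentError
from contactrsf.homerange import kde_homerange, overlap_index
from contactrsf.landscape import Grid
from contactrsf.tracks import Trajectory

DEFAULT_BUFFER_M = 10.0
MIN_CONTACTS = 10

_MIN_WEEK_POINTS = 30  # enough fixes in an ISO week to estimate a weekly core


@dataclass(frozen=True)
class ContactEvent:
    """One simultaneous co-location of a dyad within the buffer."""

    pair: tuple[str, str]  # lexicographically ordered ids
    timestamp: np.datetime64
    distance: float
    x: float  # midpoint of the two simultaneous positions
    y: float

    def __post_init__(self):
        if self.pair[0] >= self.pair[1]:
            raise InvalidArgumentError("pair ids must be strictly ordered")


@dataclass
class PairRecord:
    """Classification and bookkeeping for one dyad."""

    pair: tuple[str, str]
    dyad_class: str  # FF / FM / MM
    relationship: str  # between / within / temporary
    window: tuple[np.datetime64, np.datetime64]
    weekly_overlap: dict[str, float] = field(default_factory=dict)
    n_contacts: int = 0
    included: bool = False

    def __post_init__(self):
        if self.dyad_class not in {"FF", "FM", "MM"}:
            raise InvalidArgumentError(f"bad dyad class {self.dyad_class!r}")
        if self.relationship not in {"between", "within", "temporary"}:
            raise InvalidArgumentError(f"bad relationship {self.relationship!r}")
        if self.n_contacts < 0:
            raise InvalidArgumentError("n_contacts must be >= 0")
        if self.included and not (
            self.n_contacts > MIN_CONTACTS and self.relationship in ("between", "temporary")
        ):
            raise InvalidArgumentError("included pairs need >10 contacts and a between window")

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "dyad_class": self.dyad_class,
            "relationship": self.relationship,
            "window": [str(self.window[0]), str(self.window[1])],
            "weekly_overlap": self.weekly_overlap,
            "n_contacts": self.n_contacts,
            "included": self.included,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairRecord":
        return cls(
            pair=tuple(d["pair"]),
            dyad_class=d["dyad_class"],
            relationship=d["relationship"],
            window=(np.datetime64(d["window"][0]), np.datetime64(d["window"][1])),
            weekly_overlap=dict(d["weekly_overlap"]),
            n_contacts=int(d["n_contacts"]),
            included=bool(d["included"]),
        )


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    if id_a == id_b:
        raise InvalidArgumentError("a pair needs two distinct animals")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


def temporal_intersection(track_a: Trajectory, track_b: Trajectory):
    """Closed intersection of the two tracking windows, or None when empty."""
    start = max(track_a.start, track_b.start)
    end = min(track_a.end, track_b.end)
    if start > end:
        return None
    return start, end


def detect_contacts(
    itrack_a: Trajectory, itrack_b: Trajectory, buffer_m: float = DEFAULT_BUFFER_M
) -> list[ContactEvent]:
    """Contacts at every shared grid timestamp with distance <= buffer.

    Both tracks must be regular on the same interval; output is ordered by
    time and symmetric in argument order.
    """
    if buffer_m < 0:
        raise InvalidArgumentError("buffer must be non-negative")
    if not (itrack_a.regular and itrack_b.regular):
        raise InvalidArgumentError("contact detection needs regular (interpolated) tracks")
    if itrack_a.interval_min != itrack_b.interval_min:
        raise InvalidArgumentError(
            f"mismatched grid intervals: {itrack_a.interval_min} vs {itrack_b.interval_min}"
        )
    pair = canonical_pair(itrack_a.animal_id, itrack_b.animal_id)
    if pair[0] != itrack_a.animal_id:
        itrack_a, itrack_b = itrack_b, itrack_a
    ta = itrack_a.times.astype("int64")
    tb = itrack_b.times.astype("int64")
    common, ia, ib = np.intersect1d(ta, tb, return_indices=True)
    if len(common) == 0:
        return []
    dx = itrack_a.x[ia] - itrack_b.x[ib]
    dy = itrack_a.y[ia] - itrack_b.y[ib]
    dist = np.hypot(dx, dy)
    hit = dist <= buffer_m
    mx = 0.5 * (itrack_a.x[ia] + itrack_b.x[ib])
    my = 0.5 * (itrack_a.y[ia] + itrack_b.y[ib])
    return [
        ContactEvent(
            pair=pair,
            timestamp=common[i].astype("datetime64[ns]"),
            distance=float(dist[i]),
            x=float(mx[i]),
            y=float(my[i]),
        )
        for i in np.flatnonzero(hit)
    ]


def _week_start(times: np.ndarray) -> np.ndarray:
    """Monday (ISO week start) of each timestamp, as datetime64[D]."""
    days = times.astype("datetime64[D]")
    dow = (days.astype("int64") + 3) % 7  # 1970-01-01 was a Thursday
    return days - dow.astype("timedelta64[D]")


def classify_pair(
    track_a: Trajectory,
    track_b: Trajectory,
    sexes: dict[str, str],
    grid: Grid,
    core_isopleth: float = 0.50,
    overlap_threshold: float = 0.5,
    min_consecutive_weeks: int = 12,
) -> PairRecord:
    """Classify a dyad from weekly core-area overlap.

    Male-involved dyads bypass the kernel-density computation and are
    between-group by definition.  Female-female dyads are within-group when
    the tracking-period mean weekly overlap exceeds the threshold;
    a run of more than ``min_consecutive_weeks`` consecutive above-threshold
    weeks inside an otherwise below-threshold record marks a temporary
    same-group phase, excluded from the analysis window.
    """
    pair = canonical_pair(track_a.animal_id, track_b.animal_id)
    if pair[0] != track_a.animal_id:
        track_a, track_b = track_b, track_a
    sex_a, sex_b = sexes[pair[0]].upper(), sexes[pair[1]].upper()
    dyad_class = "".join(sorted((sex_a, sex_b)))
    window = temporal_intersection(track_a, track_b)
    if window is None:
        raise InsufficientDataError("no joint tracking window")

    if dyad_class != "FF":
        return PairRecord(pair=pair, dyad_class=dyad_class, relationship="between", window=window)

    sub_a = track_a.window(*window)
    sub_b = track_b.window(*window)
    weeks_a = _week_start(sub_a.times)
    weeks_b = _week_start(sub_b.times)
    shared_weeks = np.intersect1d(np.unique(weeks_a), np.unique(weeks_b))
    weekly: dict[np.datetime64, float] = {}
    for wk in shared_weeks:
        sel_a = weeks_a == wk
        sel_b = weeks_b == wk
        if sel_a.sum() < _MIN_WEEK_POINTS or sel_b.sum() < _MIN_WEEK_POINTS:
            continue
        hr_a = kde_homerange(
            np.column_stack([sub_a.x[sel_a], sub_a.y[sel_a]]),
            grid,
            isopleth_levels=(core_isopleth,),
            animal_id=pair[0],
        )
        hr_b = kde_homerange(
            np.column_stack([sub_b.x[sel_b], sub_b.y[sel_b]]),
            grid,
            isopleth_levels=(core_isopleth,),
            animal_id=pair[1],
        )
        weekly[wk] = overlap_index(hr_a, hr_b, core_isopleth)
    if len(weekly) < 2:
        raise InsufficientDataError("fewer than 2 weeks of joint data for classification")

    wk_keys = sorted(weekly)
    series = {str(k): weekly[k] for k in wk_keys}
    mean_overlap = float(np.mean([weekly[k] for k in wk_keys]))
    if mean_overlap > overlap_threshold:
        return PairRecord(
            pair=pair, dyad_class="FF", relationship="within",
            window=window, weekly_overlap=series,
        )

    # longest run of consecutive above-threshold weeks
    run_best: list[np.datetime64] = []
    run: list[np.datetime64] = []
    for k in wk_keys:
        if weekly[k] > overlap_threshold and (
            not run or (k - run[-1]).astype("timedelta64[D]") == np.timedelta64(7, "D")
        ):
            run.append(k)
        elif weekly[k] > overlap_threshold:
            run = [k]
        else:
            run = []
        if len(run) > len(run_best):
            run_best = list(run)
    if len(run_best) > min_consecutive_weeks:
        # exclude the temporary-same-group phase from the analysis window
        run_start = run_best[0].astype("datetime64[ns]")
        run_end = (run_best[-1] + np.timedelta64(7, "D")).astype("datetime64[ns]")
        before = (window[0], min(window[1], run_start - np.timedelta64(1, "ns")))
        after = (max(window[0], run_end), window[1])
        spans = [s for s in (before, after) if s[0] <= s[1]]
        if not spans:
            raise InsufficientDataError("temporary phase covers the whole joint window")
        new_window = max(spans, key=lambda s: s[1] - s[0])
        return PairRecord(
            pair=pair, dyad_class="FF", relationship="temporary",
            window=new_window, weekly_overlap=series,
        )
    return PairRecord(
        pair=pair, dyad_class="FF", relationship="between",
        window=window, weekly_overlap=series,
    )


def filter_pairs(records: list[PairRecord], min_contacts: int = MIN_CONTACTS) -> list[PairRecord]:
    """Pairs with a between-group analysis window and strictly more than
    ``min_contacts`` direct contacts."""
    kept = []
    for rec in records:
        if rec.relationship in ("between", "temporary") and rec.n_contacts > min_contacts:
            rec.included = True
            kept.append(rec)
        else:
            rec.included = False
    return kept


# ---------------------------------------------------------------------------
# I/O


def contacts_to_frame(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_a": [e.pair[0] for e in events],
            "pair_b": [e.pair[1] for e in events],
            "timestamp": pd.DatetimeIndex([e.timestamp for e in events], tz="UTC"),
            "x": [e.x for e in events],
            "y": [e.y for e in events],
            "distance_m": [e.distance for e in events],
        }
    )


def write_contacts_csv(events: list[ContactEvent], path) -> Path:
    path = Path(path)
    df = contacts_to_frame(events)
    if len(df):
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3] + "Z"
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_contacts_csv(path) -> list[ContactEvent]:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601").dt.tz_localize(None)
    return [
        ContactEvent(
            pair=canonical_pair(str(r.pair_a), str(r.pair_b)),
            timestamp=np.datetime64(t.to_datetime64()),
            distance=float(r.distance_m),
            x=float(r.x),
            y=float(r.y),
        )
        for r, t in zip(df.itertuples(), ts)
    ]


def write_pair_records(records: list[PairRecord], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
    return path


def read_pair_records(path) -> list[PairRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(PairRecord.from_dict(json.loads(line)))
    return records
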