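"""Synthetic landscapes and socially structured movement.

Generates covariate stacks with known semantics and simulates groups of
animals moving as OU processes around group attractors, with scheduled
between-group meetings steered to resource locations.  Every downstream
stage of the pipeline is therefore testable against recorded ground truth
(group membership, meeting sites, and the attraction coefficients that
biased where meetings happen).

Movement is simulated in continuous time by exact OU transition sampling
at 1-minute internal steps and then thinned to the fix schedule, so
emitted fixes are genuine subsamples of the latent path.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from contactrsf.errors import InvalidArgumentError
from contactrsf.landscape import EnvStack, Grid
from contactrsf.tracks import Trajectory

GPS_ERROR_SD_M = 5.0  # default isotropic location error


# ---------------------------------------------------------------------------
# landscape generation


def _rasterize_line(mask: np.ndarray, r0, c0, r1, c1) -> None:
    """1-cell-wide Bresenham polyline onto a boolean mask."""
    n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
    rr = np.round(np.linspace(r0, r1, n)).astype(int)
    cc = np.round(np.linspace(c0, c1, n)).astype(int)
    ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    mask[rr[ok], cc[ok]] = True


def _disk(mask: np.ndarray, r, c, radius) -> None:
    rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
    mask[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = True


def gen_landscape(
    extent_m: float,
    cell_size_m: float,
    n_days: int,
    n_food_sites: int,
    seed: int,
    start_date: dt.date = dt.date(2020, 1, 1),
    food_persistence: float = 0.9,
    food_layout: str = "random",
    food_lattice_spacing: int = 3,
) -> EnvStack:
    """Synthetic covariate stack on a square grid.

    Static layers: wetland/water blobs, three 1-cell-wide linear features
    (road, fence_or_trail, ditch), continuous tree canopy.  Dynamic daily
    layers: ndvi (smooth field plus seasonal drift), binary food sites that
    switch on/off by day, and spatially constant weather scalars.
    """
    if extent_m <= 0 or cell_size_m <= 0:
        raise InvalidArgumentError("extent and cell size must be positive")
    if extent_m % cell_size_m != 0:
        raise InvalidArgumentError("extent must be divisible by cell size")
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")
    if n_food_sites < 0:
        raise InvalidArgumentError("n_food_sites must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(extent_m // cell_size_m)
    grid = Grid(n_rows=n, n_cols=n, cell_size=float(cell_size_m), x0=0.0, y_top=float(extent_m))

    wetland = np.zeros((n, n), dtype=bool)
    for _ in range(max(2, n // 30)):
        _disk(wetland, rng.integers(0, n), rng.integers(0, n), rng.integers(2, max(3, n // 12)))
    water = np.zeros((n, n), dtype=bool)
    for _ in range(2):
        _disk(water, rng.integers(0, n), rng.integers(0, n), rng.integers(1, max(2, n // 20)))

    road = np.zeros((n, n), dtype=bool)
    _rasterize_line(road, rng.integers(0, n), 0, rng.integers(0, n), n - 1)
    fence = np.zeros((n, n), dtype=bool)
    _rasterize_line(fence, 0, rng.integers(0, n), n - 1, rng.integers(0, n))
    ditch = np.zeros((n, n), dtype=bool)
    _rasterize_line(ditch, rng.integers(0, n), 0, rng.integers(0, n), n - 1)

    canopy = gaussian_filter(rng.random((n, n)), sigma=max(2, n // 20))
    canopy = (canopy - canopy.min()) / max(np.ptp(canopy), 1e-12)

    static = {
        "wetland": wetland.astype(float),
        "water": water.astype(float),
        "road": road.astype(float),
        "fence_or_trail": fence.astype(float),
        "ditch": ditch.astype(float),
        "tree_canopy": canopy,
    }

    days = [start_date + dt.timedelta(days=i) for i in range(n_days)]
    ndvi_base = gaussian_filter(rng.random((n, n)), sigma=max(2, n // 25))
    ndvi_base = 0.2 + 0.6 * (ndvi_base - ndvi_base.min()) / max(np.ptp(ndvi_base), 1e-12)
    if food_layout == "lattice" and n_food_sites:
        # regular baiting grid: decorrelates food exposure from usage density
        s = int(food_lattice_spacing)
        rr, cc = np.meshgrid(np.arange(0, n, s), np.arange(0, n, s), indexing="ij")
        food_rows, food_cols = rr.ravel(), cc.ravel()
    elif n_food_sites:
        food_rc = rng.choice(n * n, size=min(n_food_sites, n * n), replace=False)
        food_rows, food_cols = np.unravel_index(food_rc, (n, n))
    else:
        food_rows = food_cols = np.empty(0, dtype=int)

    dynamic: dict[str, dict[dt.date, np.ndarray]] = {
        k: {} for k in ("ndvi", "food", "tmax", "tmin", "prcp", "rhum", "vp")
    }
    for i, day in enumerate(days):
        season = 0.1 * math.sin(2 * math.pi * i / 365.0)
        dynamic["ndvi"][day] = np.clip(ndvi_base + season + rng.normal(0, 0.01, (n, n)), 0, 1)
        food = np.zeros((n, n))
        if n_food_sites:
            active = rng.random(len(food_rows)) < food_persistence
            food[food_rows[active], food_cols[active]] = 1.0
        dynamic["food"][day] = food
        tmax = 22.0 + 6.0 * math.sin(2 * math.pi * i / 365.0) + rng.normal(0, 1.5)
        dynamic["tmax"][day] = np.full((n, n), tmax)
        dynamic["tmin"][day] = np.full((n, n), tmax - 8.0 - abs(rng.normal(0, 1.0)))
        dynamic["prcp"][day] = np.full((n, n), float(rng.exponential(2.0)))
        dynamic["rhum"][day] = np.full((n, n), float(rng.uniform(40, 95)))
        dynamic["vp"][day] = np.full((n, n), float(rng.uniform(800, 1600)))
    return EnvStack(grid=grid, static=static, dynamic=dynamic)


# ---------------------------------------------------------------------------
# ground truth record


@dataclass
class SimTruth:
    """Everything the simulator knows that the pipeline must recover."""

    groups: dict[str, str]  # animal id -> group id
    group_centers: dict[str, tuple[float, float]]
    sexes: dict[str, str]
    attraction_coeffs: dict[str, float]
    meetings: list[dict] = field(default_factory=list)
    contacts: list[dict] = field(default_factory=list)  # ground-truth events
    seed: int | None = None

    def __post_init__(self):
        for aid, g in self.groups.items():
            if g not in self.group_centers:
                raise InvalidArgumentError(f"animal {aid} in unknown group {g}")

    def between_group_contacts(self) -> list[dict]:
        return [c for c in self.contacts if self.groups[c["pair"][0]] != self.groups[c["pair"][1]]]

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "group_centers": {k: list(v) for k, v in self.group_centers.items()},
            "sexes": self.sexes,
            "attraction_coeffs": self.attraction_coeffs,
            "meetings": self.meetings,
            "contacts": self.contacts,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["group_centers"] = {k: tuple(v) for k, v in d["group_centers"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# movement simulation


def _ou_segments(attr_x, attr_y, tau, sig2, x0, y0, rng):
    """Exact OU sampling over 1-min steps with piecewise-constant params.

    ``attr_*``, ``tau`` and ``sig2`` are per-minute arrays of length T; the
    return holds positions at minutes 0..T (length T+1) starting from
    (x0, y0).
    """
    T = len(attr_x)
    xs = np.empty(T + 1)
    ys = np.empty(T + 1)
    xs[0], ys[0] = x0, y0
    # segment boundaries where any parameter changes
    changed = np.zeros(T, dtype=bool)
    changed[1:] = (
        (np.diff(attr_x) != 0) | (np.diff(attr_y) != 0) | (np.diff(tau) != 0) | (np.diff(sig2) != 0)
    )
    bounds = np.concatenate([[0], np.flatnonzero(changed), [T]])
    bounds = np.unique(bounds)
    ex = rng.standard_normal(T)
    ey = rng.standard_normal(T)
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        phi = math.exp(-1.0 / tau[s0])
        sd = math.sqrt(sig2[s0] * (1.0 - phi * phi))
        ax, ay = attr_x[s0], attr_y[s0]
        n = s1 - s0
        # d[k] = phi*d[k-1] + e[k], run as an IIR filter seeded with d0
        d0x = xs[s0] - ax
        d0y = ys[s0] - ay
        dx = lfilter([1.0], [1.0, -phi], sd * ex[s0:s1], zi=[phi * d0x])[0]
        dy = lfilter([1.0], [1.0, -phi], sd * ey[s0:s1], zi=[phi * d0y])[0]
        xs[s0 + 1 : s1 + 1] = ax + dx
        ys[s0 + 1 : s1 + 1] = ay + dy
    return xs, ys


def _default_centers(n_groups: int, grid: Grid, rng) -> list[tuple[float, float]]:
    xmin, ymin, xmax, ymax = grid.extent
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    radius = 0.28 * min(xmax - xmin, ymax - ymin)
    out = []
    for i in range(n_groups):
        ang = 2 * math.pi * i / n_groups + rng.uniform(-0.1, 0.1)
        out.append((cx + radius * math.cos(ang), cy + radius * math.sin(ang)))
    return out


def _meeting_site_candidates(env, day, mid, reach, coeffs, rng):
    """Resource-anchored site choice: one random active cell per nonzero-
    coefficient layer (near the pair midpoint) plus one background cell,
    sampled with probability proportional to exp(beta . x(cell))."""
    grid = env.grid
    cand_xy = []
    for name, beta in coeffs.items():
        if beta == 0:
            continue
        layer = env.layer(name, day)
        rows, cols = np.nonzero(layer)
        if len(rows) == 0:
            continue
        x, y = grid.cell_center(rows, cols)
        d = np.hypot(x - mid[0], y - mid[1])
        near = np.flatnonzero(d <= reach)
        pick = rng.choice(near) if len(near) else int(np.argmin(d))
        cand_xy.append((float(x[pick]), float(y[pick])))
    # background candidate around the midpoint
    for _ in range(50):
        bx = rng.normal(mid[0], reach / 2.0)
        by = rng.normal(mid[1], reach / 2.0)
        if grid.contains(bx, by):
            break
    else:
        bx, by = mid
    r, c = grid.cell_of(bx, by)
    bx, by = grid.cell_center(r, c)
    cand_xy.append((float(bx), float(by)))
    w = np.array(
        [
            math.exp(
                sum(b * float(env.layer(n, day)[grid.cell_of(px, py)]) for n, b in coeffs.items())
            )
            for px, py in cand_xy
        ]
    )
    i = rng.choice(len(cand_xy), p=w / w.sum())
    return cand_xy[i]


def _meeting_site_density(env, day, centers_pair, sigma2, coeffs, rng):
    """Usage-weighted site choice: cell probability proportional to the
    pair's stationary OU density times exp(beta . x(cell)), so meeting
    locations carry exactly the configured odds multiplier relative to the
    dyad's availability."""
    grid = env.grid
    gx, gy = grid.centers()
    dens = np.zeros_like(gx)
    for cx, cy in centers_pair:
        dens += np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma2))
    eta = np.zeros_like(gx)
    for name, beta in coeffs.items():
        if beta:
            eta += beta * env.layer(name, day)
    w = (dens * np.exp(eta)).ravel()
    idx = rng.choice(w.size, p=w / w.sum())
    r, c = np.unravel_index(idx, gx.shape)
    x, y = grid.cell_center(r, c)
    return float(x), float(y)


def sim_population(
    env: EnvStack,
    n_groups: int,
    animals_per_group: int,
    tau_p_min: float = 60.0,
    sigma_m2: float = 1.2e5,
    fix_interval_min=10.0,
    n_days: int | None = None,
    attraction_coeffs: dict[str, float] | None = None,
    seed: int = 0,
    gps_error_sd: float = GPS_ERROR_SD_M,
    dropout: float = 0.0,
    meetings_per_day: float = 1.0,
    meeting_duration_min: float = 12.0,
    travel_lead_min: float = 20.0,
    steer_tau_min: float = 4.0,
    steer_sigma2: float = 9.0,
    group_centers=None,
    sexes: dict[str, str] | None = None,
    meeting_pairs: list[tuple[str, str]] | None = None,
    site_mode: str = "candidates",
    buffer_m: float = 10.0,
    flank_offset_m: float = 0.0,
    flank_prob: float = 1.0,
) -> tuple[list[Trajectory], SimTruth]:
    """Simulate a socially structured population with steered co-locations.

    Animals follow OU processes around their group centers.  When any
    attraction coefficient is nonzero, between-group meetings are scheduled
    at ``meetings_per_day``: the chosen dyad's attractors are temporarily
    relocated to a resource-biased site, producing ground-truth contacts
    whose locations track ``attraction_coeffs``.  With all-zero
    coefficients the co-location mechanism is off.

    ``fix_interval_min`` may be a scalar (regular schedule) or a (lo, hi)
    tuple of uniformly drawn gaps in minutes.
    """
    if n_groups < 2:
        raise InvalidArgumentError("need n_groups >= 2 so between-group pairs exist")
    if animals_per_group < 1:
        raise InvalidArgumentError("animals_per_group must be >= 1")
    coeffs = dict(attraction_coeffs or {})
    unknown = [k for k in coeffs if k not in env.layer_names]
    if unknown:
        raise InvalidArgumentError(f"attraction coefficients for unknown layers: {unknown}")
    env_days = env.days
    if not env_days:
        raise InvalidArgumentError("env must carry dynamic daily layers")
    if n_days is None:
        n_days = len(env_days)
    if n_days > len(env_days):
        raise InvalidArgumentError("n_days exceeds the env stack's daily coverage")
    if site_mode not in ("candidates", "density"):
        raise InvalidArgumentError(f"unknown site_mode {site_mode!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = int(n_days * 1440)
    t0 = np.datetime64(env_days[0]).astype("datetime64[ns]")

    centers = list(group_centers) if group_centers is not None else _default_centers(n_groups, env.grid, rng)
    if len(centers) != n_groups:
        raise InvalidArgumentError("group_centers length must equal n_groups")
    group_ids = [f"G{g:02d}" for g in range(n_groups)]
    animal_ids = []
    groups: dict[str, str] = {}
    for g in range(n_groups):
        for a in range(animals_per_group):
            aid = f"A{g * animals_per_group + a:02d}"
            animal_ids.append(aid)
            groups[aid] = group_ids[g]
    if sexes is None:
        sexes = {aid: ("F" if i % 2 == 0 else "M") for i, aid in enumerate(animal_ids)}

    # --- meeting schedule -------------------------------------------------
    meetings: list[dict] = []
    flank_acc = 0.0  # deterministic (Bresenham) thinning of flanked meetings
    active = any(v != 0 for v in coeffs.values())
    if active and meetings_per_day > 0:
        n_meet = int(round(meetings_per_day * n_days))
        lead = int(round(travel_lead_min))
        dur = int(round(meeting_duration_min))
        lo, hi = lead + 1, T - dur - 2
        times = np.sort(rng.integers(lo, hi, size=n_meet)) if n_meet else np.empty(0, int)
        for mi, tm in enumerate(times):
            if meeting_pairs:
                a, b = meeting_pairs[int(rng.integers(len(meeting_pairs)))]
            else:
                ga, gb = rng.choice(n_groups, size=2, replace=False)
                a = rng.choice([x for x in animal_ids if groups[x] == group_ids[ga]])
                b = rng.choice([x for x in animal_ids if groups[x] == group_ids[gb]])
            a, b = (a, b) if a < b else (b, a)
            ca = centers[group_ids.index(groups[a])]
            cb = centers[group_ids.index(groups[b])]
            day = env_days[min(int(tm) // 1440, n_days - 1)]
            if site_mode == "candidates":
                mid = (0.5 * (ca[0] + cb[0]), 0.5 * (ca[1] + cb[1]))
                dist = math.hypot(ca[0] - cb[0], ca[1] - cb[1])
                site = _meeting_site_candidates(env, day, mid, 0.5 * dist + 300.0, coeffs, rng)
            else:
                site = _meeting_site_density(env, day, (ca, cb), sigma_m2, coeffs, rng)
            r, c = env.grid.cell_of(*site)
            on_food = bool(env.layer("food", day)[int(r), int(c)] > 0)
            flanked = False
            if flank_offset_m > 0:
                flank_acc += flank_prob
                if flank_acc >= 1.0 - 1e-12:
                    flank_acc -= 1.0
                    flanked = True
            if flanked and on_food and r > 0 and c < env.grid.n_cols - 1:
                # animals flank the resource point near the cell's top-right
                # corner: the contact midpoint stays on the resource cell
                # while each animal's own fixes sit in neighbouring cells
                cs = env.grid.cell_size
                x1 = env.grid.x0 + (c + 1) * cs  # right edge
                y1 = env.grid.y_top - r * cs  # top edge
                inset = 0.45 * flank_offset_m
                sx, sy = x1 - inset, y1 - inset
                attr_a = (sx - flank_offset_m, sy + flank_offset_m)
                attr_b = (sx + flank_offset_m, sy - flank_offset_m)
            elif flanked:
                # same straddle geometry around the site point, keeping the
                # per-meeting contact yield comparable across site types
                attr_a = (site[0] - flank_offset_m, site[1] + flank_offset_m)
                attr_b = (site[0] + flank_offset_m, site[1] - flank_offset_m)
            else:
                attr_a = attr_b = site
            meetings.append(
                {
                    "index": mi,
                    "pair": [a, b],
                    "t_minute": int(tm),
                    "lead_min": lead,
                    "duration_min": dur,
                    "site_x": site[0],
                    "site_y": site[1],
                    "attr": {a: list(attr_a), b: list(attr_b)},
                    "on_food": on_food,
                    "date": day.isoformat(),
                }
            )

    # --- per-animal simulation -------------------------------------------
    tracks: list[Trajectory] = []
    positions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fix_minutes: dict[str, np.ndarray] = {}
    for aid in animal_ids:
        cg = centers[group_ids.index(groups[aid])]
        attr_x = np.full(T, cg[0])
        attr_y = np.full(T, cg[1])
        tau = np.full(T, float(tau_p_min))
        sig2 = np.full(T, float(sigma_m2))
        for m in meetings:
            if aid in m["pair"]:
                s = max(m["t_minute"] - m["lead_min"], 0)
                e = min(m["t_minute"] + m["duration_min"], T)
                ax, ay = m["attr"][aid]
                attr_x[s:e] = ax
                attr_y[s:e] = ay
                tau[s:e] = steer_tau_min
                sig2[s:e] = steer_sigma2
        x0 = cg[0] + rng.normal(0, math.sqrt(sigma_m2))
        y0 = cg[1] + rng.normal(0, math.sqrt(sigma_m2))
        xs, ys = _ou_segments(attr_x, attr_y, tau, sig2, x0, y0, rng)
        # keep the latent path on the landscape (rare tail excursions)
        xmin, ymin, xmax, ymax = env.grid.extent
        pad = 0.5 * env.grid.cell_size
        np.clip(xs, xmin + pad, xmax - pad, out=xs)
        np.clip(ys, ymin + pad, ymax - pad, out=ys)

        if np.isscalar(fix_interval_min):
            sched = np.arange(0, T, int(round(fix_interval_min)))
            regular = True
        else:
            lo, hi = fix_interval_min
            gaps = rng.uniform(lo, hi, size=int(T / lo) + 2)
            sched = np.round(np.cumsum(gaps)).astype(int)
            sched = np.unique(np.concatenate([[0], sched[sched < T]]))
            regular = False
        if dropout > 0:
            keep = rng.random(len(sched)) >= dropout
            keep[0] = True
            sched = sched[keep]
            regular = False
        fx = xs[sched]
        fy = ys[sched]
        if gps_error_sd > 0:
            fx = fx + rng.normal(0, gps_error_sd, len(sched))
            fy = fy + rng.normal(0, gps_error_sd, len(sched))
        times = t0 + (sched.astype("int64") * np.int64(60_000_000_000)).astype("timedelta64[ns]")
        tracks.append(
            Trajectory(
                animal_id=aid,
                times=times,
                x=fx,
                y=fy,
                regular=regular,
                interval_min=float(fix_interval_min) if regular else None,
            )
        )
        positions[aid] = (xs, ys)
        fix_minutes[aid] = sched

    # --- ground-truth contact log ----------------------------------------
    contacts: list[dict] = []
    for m in meetings:
        a, b = m["pair"]
        s = max(m["t_minute"] - m["lead_min"], 0)
        e = min(m["t_minute"] + m["duration_min"], T)
        shared = np.intersect1d(fix_minutes[a], fix_minutes[b])
        shared = shared[(shared >= s) & (shared < e)]
        xa, ya = positions[a]
        xb, yb = positions[b]
        for tm in shared:
            d = math.hypot(xa[tm] - xb[tm], ya[tm] - yb[tm])
            if d <= buffer_m:
                mx, my = 0.5 * (xa[tm] + xb[tm]), 0.5 * (ya[tm] + yb[tm])
                r, c = env.grid.cell_of(mx, my)
                day = env_days[min(int(tm) // 1440, n_days - 1)]
                contacts.append(
                    {
                        "pair": [a, b],
                        "t_minute": int(tm),
                        "timestamp": str(
                            (t0 + np.timedelta64(int(tm) * 60_000_000_000, "ns"))
                        ),
                        "x": float(mx),
                        "y": float(my),
                        "distance": float(d),
                        "on_food": bool(env.layer("food", day)[int(r), int(c)] > 0),
                        "meeting": m["index"],
                    }
                )

    truth = SimTruth(
        groups=groups,
        group_centers={gid: tuple(c) for gid, c in zip(group_ids, centers)},
        sexes=dict(sexes),
        attraction_coeffs=coeffs,
        meetings=meetings,
        contacts=contacts,
        seed=seed,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# exact single-track simulation for the movement-model families


def simulate_family_track(
    family: str,
    n: int,
    dt_min: float,
    seed: int,
    sigma2: float,
    tau_p: float | None = None,
    tau_v: float | None = None,
    mu: tuple[float, float] = (0.0, 0.0),
    error_sd: float = 0.0,
    animal_id: str = "sim",
    start=np.datetime64("2020-01-01T00:00:00", "ns"),
) -> Trajectory:
    """Exact state-space draw from one movement-model family.

    For IOU, ``sigma2`` is the stationary velocity variance and the path
    starts at ``mu`` with a stationary velocity.
    """
    from contactrsf.ctmm import _step_matrices  # shared closed forms

    rng = np.random.default_rng(seed)
    dts = np.full(n - 1, float(dt_min))
    F, Q = _step_matrices(family, dts, sigma2, tau_p, tau_v)
    d = F.shape[1]
    if family == "OUF":
        P0 = np.diag([sigma2, sigma2 / (tau_p * tau_v)])
    elif family == "IOU":
        P0 = np.diag([0.0, sigma2])
    else:
        P0 = np.array([[sigma2]])
    L0 = np.linalg.cholesky(P0 + 1e-15 * np.eye(d))
    Lq = np.linalg.cholesky(Q[0] + 1e-15 * np.eye(d))
    out = np.empty((n, 2))
    state = L0 @ rng.standard_normal((d, 2))
    out[0] = state[0]
    for i in range(1, n):
        state = F[0] @ state + Lq @ rng.standard_normal((d, 2))
        out[i] = state[0]
    x = out[:, 0] + mu[0]
    y = out[:, 1] + mu[1]
    if error_sd > 0:
        x = x + rng.normal(0, error_sd, n)
        y = y + rng.normal(0, error_sd, n)
    times = start + (np.arange(n) * dt_min * 60 * 1e9).astype("timedelta64[ns]")
    return Trajectory(animal_id=animal_id, times=times, x=x, y=y)
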