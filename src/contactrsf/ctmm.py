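"""Continuous-time movement models: fitting, AIC selection, interpolation.

Four Gaussian families are supported — IID, OU (mean-reverting position),
IOU (integrated OU, nonstationary) and OUF (position + velocity
timescales).  Coordinates are treated as independent with shared
timescales and an isotropic spatial variance.  Likelihoods are exact
linear-Gaussian state-space (Kalman) likelihoods handling irregular gaps;
the mean location is profiled out by GLS on the filter innovations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from contactrsf._kalman import filter_iou, filter_ou, filter_ouf, smooth_series
from contactrsf.errors import FitFailureError, InsufficientDataError, InvalidArgumentError
from contactrsf.tracks import Trajectory

FAMILIES = ("IID", "OU", "IOU", "OUF")

_MIN_FIXES = 10
_LL_TOL = 1e-8


@dataclass
class MovementModel:
    """A fitted movement model for one animal.

    ``sigma2`` is the stationary positional variance (m^2) for IID/OU/OUF
    and the stationary *velocity* variance (m^2/min^2) for the
    nonstationary IOU family.  Timescales are in minutes.
    """

    family: str
    mu: tuple[float, float] | None
    sigma2: float
    tau_p: float | None
    tau_v: float | None
    error_var: float
    loglik: float
    k: int
    aic: float
    n: int
    animal_id: str = ""
    converged: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.family in ("OU", "OUF") and not (self.tau_p and self.tau_p > 0):
            raise InvalidArgumentError("tau_p must be positive")
        if self.family == "OUF" and not (self.tau_v and 0 < self.tau_v < self.tau_p):
            raise InvalidArgumentError("OUF requires tau_p > tau_v > 0")
        if self.family == "IOU" and not (self.tau_v and self.tau_v > 0):
            raise InvalidArgumentError("IOU requires tau_v > 0")
        if not math.isclose(self.aic, 2 * self.k - 2 * self.loglik, rel_tol=0, abs_tol=1e-6):
            raise InvalidArgumentError("AIC must equal 2k - 2*loglik")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mu": None if self.mu is None else list(self.mu),
            "sigma2": self.sigma2,
            "tau_p": self.tau_p,
            "tau_v": self.tau_v,
            "error_var": self.error_var,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "n": self.n,
            "animal_id": self.animal_id,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovementModel":
        d = dict(d)
        if d.get("mu") is not None:
            d["mu"] = tuple(d["mu"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "MovementModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# likelihood


def _prep(track: Trajectory, error_var) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t = track.t_seconds / 60.0  # minutes
    dts = np.diff(t)
    if error_var is None:
        if track.error_sd is not None:
            R = track.error_sd.astype(float) ** 2
        else:
            R = np.zeros(len(t))
    else:
        R = np.broadcast_to(np.asarray(error_var, dtype=float), (len(t),)).copy()
    return dts, track.x, track.y, R


def _innovations(family, dts, yx, yy, R, sigma2, tau_p, tau_v):
    if family == "IID":
        return filter_ou(dts, yx, yy, sigma2, 0.0, R)
    if family == "OU":
        return filter_ou(dts, yx, yy, sigma2, tau_p, R)
    if family == "OUF":
        return filter_ouf(dts, yx, yy, sigma2, tau_p, tau_v, R)
    if family == "IOU":
        return filter_iou(dts, yx, yy, sigma2, tau_v, R)
    raise InvalidArgumentError(f"unknown family {family!r}")


def _loglik_mu(family, dts, yx, yy, R, sigma2, tau_p, tau_v, mu=None):
    """Profiled (or fixed-mu) log-likelihood; returns (loglik, mu)."""
    nu_x, nu_y, nu_1, S = _innovations(family, dts, yx, yy, R, sigma2, tau_p, tau_v)
    if not np.all(np.isfinite(S)) or np.any(S <= 0):
        return -np.inf, (np.nan, np.nan)
    w1 = nu_1 / S
    denom = float(nu_1 @ w1)
    if family == "IOU" or denom <= 0:
        mux = muy = 0.0
    elif mu is not None:
        mux, muy = mu
    else:
        mux = float(nu_x @ w1) / denom
        muy = float(nu_y @ w1) / denom
    rx = nu_x - mux * nu_1
    ry = nu_y - muy * nu_1
    const = len(S) * math.log(2 * math.pi)
    ll = -0.5 * (2 * const + 2 * float(np.sum(np.log(S))) + float(rx @ (rx / S)) + float(ry @ (ry / S)))
    if not math.isfinite(ll):
        return -np.inf, (mux, muy)
    return ll, (mux, muy)


def log_likelihood(track: Trajectory, family: str, sigma2: float,
                   tau_p: float | None = None, tau_v: float | None = None,
                   error_var=None, mu=None) -> float:
    """Exact state-space log-likelihood at the given parameters.

    With ``mu=None`` the mean location is profiled out (GLS); for IOU the
    likelihood is conditional on the first fix and has no mean parameter.
    """
    dts, yx, yy, R = _prep(track, error_var)
    ll, _ = _loglik_mu(family, dts, yx, yy, R, sigma2, tau_p, tau_v, mu=mu)
    return ll


# ---------------------------------------------------------------------------
# fitting


def _k_for(family: str) -> int:
    return {"IID": 3, "OU": 4, "IOU": 2, "OUF": 5}[family]


def _fit_iid(track, dts, yx, yy, R):
    n = len(yx)
    mux = float(np.mean(yx))
    muy = float(np.mean(yy))
    raw = float(np.sum((yx - mux) ** 2) + np.sum((yy - muy) ** 2)) / (2 * n)
    sigma2 = max(raw - float(np.mean(R)), 1e-12)
    ll, mu = _loglik_mu("IID", dts, yx, yy, R, sigma2, None, None)
    # with homogeneous R the GLS mean is the sample mean; keep the profiled one
    return sigma2, None, None, ll, mu


def _optimize(objective, inits, bounds=None):
    best = None
    for x0 in inits:
        res = minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 4000, "maxfev": 6000},
        )
        if best is None or res.fun < best.fun - 0:
            best = res
    return best


def fit_movement_model(track: Trajectory, family: str, error_var=None) -> MovementModel:
    """Maximum-likelihood fit of one family to one track.

    ``error_var`` fixes the measurement-error variance (m^2); by default it
    is taken from the track's per-fix error SDs, or zero when absent.
    """
    if family not in FAMILIES:
        raise InvalidArgumentError(f"unknown family {family!r}")
    if len(track) < _MIN_FIXES:
        raise InsufficientDataError(
            f"need >= {_MIN_FIXES} fixes, got {len(track)}"
        )
    dts, yx, yy, R = _prep(track, error_var)
    n = len(yx)
    var0 = 0.5 * (float(np.var(yx)) + float(np.var(yy)))
    var0 = max(var0, 1e-9)
    mdt = float(np.median(dts))

    if family == "IID":
        sigma2, tau_p, tau_v, ll, mu = _fit_iid(track, dts, yx, yy, R)
        converged = True
    elif family == "OU":
        def obj(theta):
            s2, tp = np.exp(theta)
            ll, _ = _loglik_mu("OU", dts, yx, yy, R, s2, tp, None)
            return -ll if math.isfinite(ll) else 1e300

        inits = [
            (math.log(var0), math.log(mdt * m)) for m in (2.0, 20.0, 200.0)
        ] + [(math.log(var0), math.log(mdt * 1e-3))]  # near-IID start
        res = _optimize(obj, inits)
        sigma2, tau_p = np.exp(res.x)
        tau_v = None
        ll, mu = _loglik_mu("OU", dts, yx, yy, R, sigma2, tau_p, None)
        converged = bool(res.success) or math.isfinite(ll)
    elif family == "OUF":
        # parameterize tau_p = tau_v + dtau to enforce tau_p > tau_v > 0
        def obj(theta):
            s2, tv, dtau = np.exp(theta)
            dtau = max(dtau, 1e-8 * tv)
            ll, _ = _loglik_mu("OUF", dts, yx, yy, R, s2, tv + dtau, tv)
            return -ll if math.isfinite(ll) else 1e300

        try:
            warm = fit_movement_model(track, "OU", error_var=error_var)
            tp0, s20 = warm.tau_p, warm.sigma2
        except Exception:
            tp0, s20 = mdt * 20.0, var0
        inits = [
            (math.log(s20), math.log(max(tp0 / 10.0, 1e-3)), math.log(tp0)),
            (math.log(s20), math.log(max(mdt, 1e-3)), math.log(max(tp0, mdt * 10))),
            (math.log(var0), math.log(mdt * 1e-2), math.log(max(tp0, mdt * 10))),
        ]
        res = _optimize(obj, inits)
        s2, tv, dtau = np.exp(res.x)
        dtau = max(dtau, 1e-8 * tv)
        sigma2, tau_v, tau_p = s2, tv, tv + dtau
        ll, mu = _loglik_mu("OUF", dts, yx, yy, R, sigma2, tau_p, tau_v)
        converged = bool(res.success) or math.isfinite(ll)
    else:  # IOU
        vx = np.diff(yx) / dts
        vy = np.diff(yy) / dts
        sv0 = max(0.5 * (float(np.var(vx)) + float(np.var(vy))), 1e-12)

        def obj(theta):
            s2, tv = np.exp(theta)
            ll, _ = _loglik_mu("IOU", dts, yx, yy, R, s2, None, tv)
            return -ll if math.isfinite(ll) else 1e300

        inits = [
            (math.log(sv0), math.log(mdt * 2.0)),
            (math.log(sv0), math.log(mdt * 20.0)),
            (math.log(sv0 * 10.0), math.log(mdt * 200.0)),
        ]
        res = _optimize(obj, inits)
        sigma2, tau_v = np.exp(res.x)
        tau_p = None
        ll, mu = _loglik_mu("IOU", dts, yx, yy, R, sigma2, None, tau_v)
        converged = bool(res.success) or math.isfinite(ll)

    if not math.isfinite(ll):
        raise FitFailureError(
            f"{family} fit did not produce a finite likelihood",
            diagnostics={"family": family, "n": n},
        )
    k = _k_for(family)
    return MovementModel(
        family=family,
        mu=None if family == "IOU" else (mu[0], mu[1]),
        sigma2=float(sigma2),
        tau_p=None if tau_p is None else float(tau_p),
        tau_v=None if tau_v is None else float(tau_v),
        error_var=float(np.mean(R)),
        loglik=float(ll),
        k=k,
        aic=float(2 * k - 2 * ll),
        n=n,
        animal_id=track.animal_id,
        converged=converged,
    )


def select_movement_model(track: Trajectory, families=FAMILIES, error_var=None) -> MovementModel:
    """Fit every candidate family and return the AIC-minimal model.

    Ties (|dAIC| < 1e-9) break toward fewer parameters.  Raises
    ``FitFailureError`` when every family fails.
    """
    fits: list[MovementModel] = []
    failures: dict[str, str] = {}
    for family in families:
        try:
            fits.append(fit_movement_model(track, family, error_var=error_var))
        except (FitFailureError, InsufficientDataError) as exc:
            failures[family] = str(exc)
    if not fits:
        raise FitFailureError(f"all families failed: {failures}", diagnostics=failures)
    best = fits[0]
    for m in fits[1:]:
        if m.aic < best.aic - 1e-9 or (abs(m.aic - best.aic) <= 1e-9 and m.k < best.k):
            best = m
    return best


# ---------------------------------------------------------------------------
# interpolation


def _step_matrices(family, dts, sigma2, tau_p, tau_v):
    """Per-step transition and process-noise matrices, shapes (m-1, d, d)."""
    m = len(dts)
    if family in ("IID", "OU"):
        F = np.zeros((m, 1, 1))
        Q = np.zeros((m, 1, 1))
        if family == "OU":
            phi = np.exp(-dts / tau_p)
        else:
            phi = np.zeros(m)
        F[:, 0, 0] = phi
        Q[:, 0, 0] = sigma2 * (1.0 - phi**2)
        return F, Q
    F = np.zeros((m, 2, 2))
    Q = np.zeros((m, 2, 2))
    if family == "OUF":
        l1, l2 = 1.0 / tau_p, 1.0 / tau_v
        sv2 = sigma2 * l1 * l2
        e1 = np.exp(-l1 * dts)
        e2 = np.exp(-l2 * dts)
        den = l2 - l1
        F[:, 0, 0] = (l2 * e1 - l1 * e2) / den
        F[:, 0, 1] = (e1 - e2) / den
        F[:, 1, 0] = -l1 * l2 * F[:, 0, 1]
        F[:, 1, 1] = (l2 * e2 - l1 * e1) / den
        Pinf = np.diag([sigma2, sv2])
        Q[:] = Pinf[None] - F @ Pinf[None] @ np.swapaxes(F, 1, 2)
        return F, Q
    # IOU: sigma2 is the velocity variance
    e = np.exp(-dts / tau_v)
    one_e = 1.0 - e
    F[:, 0, 0] = 1.0
    F[:, 0, 1] = tau_v * one_e
    F[:, 1, 1] = e
    Q[:, 0, 0] = 2.0 * sigma2 * tau_v * (dts - tau_v * one_e - 0.5 * tau_v * one_e**2)
    Q[:, 0, 1] = sigma2 * tau_v * one_e**2
    Q[:, 1, 0] = Q[:, 0, 1]
    Q[:, 1, 1] = sigma2 * (1.0 - e**2)
    return F, Q


def interpolation_grid(track: Trajectory, interval_min: float = 5.0) -> np.ndarray:
    """Regular grid over [first fix, last fix], anchored at the first fix's
    timestamp floored to the interval; both endpoints are kept when they
    land on the grid."""
    if interval_min <= 0:
        raise InvalidArgumentError("interval must be positive")
    step = np.int64(round(interval_min * 60 * 1e9))
    t0 = track.times[0].astype("int64")
    t1 = track.times[-1].astype("int64")
    anchor = (t0 // step) * step
    k0 = -(-(t0 - anchor) // step)  # ceil division
    first = anchor + k0 * step
    if first > t1:
        raise InsufficientDataError("interpolation grid is empty")
    times = np.arange(first, t1 + 1, step, dtype="int64")
    return times.astype("datetime64[ns]")


def interpolate(track: Trajectory, model: MovementModel, interval_min: float = 5.0) -> Trajectory:
    """Conditional-mean positions (Kalman smoother) on a regular grid."""
    grid_ns = interpolation_grid(track, interval_min).astype("int64")
    obs_ns = track.times.astype("int64")
    union_ns = np.union1d(grid_ns, obs_ns)
    t_min = union_ns / (60 * 1e9)
    dts = np.diff(t_min)
    is_obs = np.isin(union_ns, obs_ns)
    m = len(union_ns)

    yx = np.zeros(m)
    yy = np.zeros(m)
    Rfull = np.zeros(m)
    obs_idx = np.searchsorted(union_ns, obs_ns)
    if track.error_sd is not None:
        Rfull[obs_idx] = track.error_sd**2
    else:
        Rfull[obs_idx] = model.error_var
    mux, muy = model.mu if model.mu is not None else (0.0, 0.0)
    yx[obs_idx] = track.x - mux
    yy[obs_idx] = track.y - muy

    F, Q = _step_matrices(model.family, dts, model.sigma2, model.tau_p, model.tau_v)
    if model.family == "IOU":
        m0x = np.array([yx[0], 0.0])
        m0y = np.array([yy[0], 0.0])
        P0 = np.array([[Rfull[0], 0.0], [0.0, model.sigma2]])
        is_obs = is_obs.copy()
        is_obs[0] = False  # first fix absorbed into the initial condition
    elif model.family == "OUF":
        sv2 = model.sigma2 / (model.tau_p * model.tau_v)
        m0x = np.zeros(2)
        m0y = np.zeros(2)
        P0 = np.diag([model.sigma2, sv2])
    else:
        m0x = np.zeros(1)
        m0y = np.zeros(1)
        P0 = np.array([[model.sigma2]])

    sx = smooth_series(F, Q, yx, is_obs, Rfull, m0x, P0)
    sy = smooth_series(F, Q, yy, is_obs, Rfull, m0y, P0)
    grid_idx = np.searchsorted(union_ns, grid_ns)
    return Trajectory(
        animal_id=track.animal_id,
        times=union_ns[grid_idx].astype("datetime64[ns]"),
        x=sx[grid_idx, 0] + mux,
        y=sy[grid_idx, 0] + muy,
        regular=True,
        interval_min=float(interval_min),
    )
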