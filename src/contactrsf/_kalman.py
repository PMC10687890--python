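"""Kalman-filter kernels for Gaussian movement processes.

Each family is a linear-Gaussian state space per coordinate; x and y share
timescales, so one pass filters both coordinate series (and a constant
"ones" series used to profile the mean by GLS on the innovations).

State-space forms (per coordinate, zero-mean):

* IID  — state = position, no carry-over between fixes.
* OU   — scalar position state, transition ``exp(-dt/tau_p)``.
* OUF  — (position, velocity) state with rates ``l1 = 1/tau_p``,
  ``l2 = 1/tau_v``; stationary covariance ``diag(s2, s2*l1*l2)``.
* IOU  — (position, velocity); velocity is OU with stationary variance
  ``s2``; position is its integral (nonstationary, conditioned on the
  first fix).

All kernels return innovation sequences ``(nu_x, nu_y, nu_ones, S)`` so the
caller can profile the mean and assemble the log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def filter_ou(dts, yx, yy, sigma2, tau_p, R):
    """OU filter (IID when ``tau_p <= 0``).  ``R`` is per-fix error variance."""
    n = yx.shape[0]
    nu_x = np.empty(n)
    nu_y = np.empty(n)
    nu_1 = np.empty(n)
    S = np.empty(n)
    mx = 0.0
    my = 0.0
    m1 = 0.0
    P = sigma2
    for i in range(n):
        Si = P + R[i]
        nu_x[i] = yx[i] - mx
        nu_y[i] = yy[i] - my
        nu_1[i] = 1.0 - m1
        S[i] = Si
        K = P / Si
        mx += K * nu_x[i]
        my += K * nu_y[i]
        m1 += K * nu_1[i]
        P -= K * P
        if i < n - 1:
            if tau_p > 0.0:
                phi = np.exp(-dts[i] / tau_p)
            else:
                phi = 0.0
            mx *= phi
            my *= phi
            m1 *= phi
            P = phi * phi * P + sigma2 * (1.0 - phi * phi)
    return nu_x, nu_y, nu_1, S


@njit(cache=True)
def filter_ouf(dts, yx, yy, sigma2, tau_p, tau_v, R):
    """OUF filter; requires ``tau_p > tau_v > 0``."""
    n = yx.shape[0]
    nu_x = np.empty(n)
    nu_y = np.empty(n)
    nu_1 = np.empty(n)
    S = np.empty(n)
    l1 = 1.0 / tau_p
    l2 = 1.0 / tau_v
    sv2 = sigma2 * l1 * l2
    # per-stream state means (position, velocity)
    mx0 = 0.0
    mx1 = 0.0
    my0 = 0.0
    my1 = 0.0
    m10 = 0.0
    m11 = 0.0
    p00 = sigma2
    p01 = 0.0
    p11 = sv2
    for i in range(n):
        Si = p00 + R[i]
        nu_x[i] = yx[i] - mx0
        nu_y[i] = yy[i] - my0
        nu_1[i] = 1.0 - m10
        S[i] = Si
        k0 = p00 / Si
        k1 = p01 / Si
        mx0 += k0 * nu_x[i]
        mx1 += k1 * nu_x[i]
        my0 += k0 * nu_y[i]
        my1 += k1 * nu_y[i]
        m10 += k0 * nu_1[i]
        m11 += k1 * nu_1[i]
        p11 -= k1 * p01
        p01 -= k0 * p01
        p00 -= k0 * p00
        if i < n - 1:
            d = dts[i]
            e1 = np.exp(-l1 * d)
            e2 = np.exp(-l2 * d)
            den = l2 - l1
            f00 = (l2 * e1 - l1 * e2) / den
            f01 = (e1 - e2) / den
            f10 = -l1 * l2 * f01
            f11 = (l2 * e2 - l1 * e1) / den
            tx0 = f00 * mx0 + f01 * mx1
            tx1 = f10 * mx0 + f11 * mx1
            ty0 = f00 * my0 + f01 * my1
            ty1 = f10 * my0 + f11 * my1
            t10 = f00 * m10 + f01 * m11
            t11 = f10 * m10 + f11 * m11
            mx0, mx1, my0, my1, m10, m11 = tx0, tx1, ty0, ty1, t10, t11
            # P <- F P F' + Q with Q = Pinf - F Pinf F'
            a00 = f00 * p00 + f01 * p01
            a01 = f00 * p01 + f01 * p11
            a10 = f10 * p00 + f11 * p01
            a11 = f10 * p01 + f11 * p11
            fpf00 = a00 * f00 + a01 * f01
            fpf01 = a00 * f10 + a01 * f11
            fpf11 = a10 * f10 + a11 * f11
            q00 = sigma2 - (f00 * f00 * sigma2 + f01 * f01 * sv2)
            q01 = -(f00 * f10 * sigma2 + f01 * f11 * sv2)
            q11 = sv2 - (f10 * f10 * sigma2 + f11 * f11 * sv2)
            p00 = fpf00 + q00
            p01 = fpf01 + q01
            p11 = fpf11 + q11
    return nu_x, nu_y, nu_1, S


@njit(cache=True)
def filter_iou(dts, yx, yy, sv2, tau_v, R):
    """IOU filter conditioned on the first fix.

    Returns innovations for observations ``1..n-1`` (length ``n-1``); the
    ones stream is zero because the process has no stationary mean.
    """
    n = yx.shape[0]
    m = n - 1
    nu_x = np.empty(m)
    nu_y = np.empty(m)
    nu_1 = np.zeros(m)
    S = np.empty(m)
    # posterior at the first fix: position = y0 with its error variance
    mx0 = yx[0]
    mx1 = 0.0
    my0 = yy[0]
    my1 = 0.0
    p00 = R[0]
    p01 = 0.0
    p11 = sv2
    for i in range(m):
        d = dts[i]
        e = np.exp(-d / tau_v)
        f01 = tau_v * (1.0 - e)
        # predict
        tx0 = mx0 + f01 * mx1
        tx1 = e * mx1
        ty0 = my0 + f01 * my1
        ty1 = e * my1
        mx0, mx1, my0, my1 = tx0, tx1, ty0, ty1
        one_e = 1.0 - e
        qxx = 2.0 * sv2 * tau_v * (d - tau_v * one_e - 0.5 * tau_v * one_e * one_e)
        qxv = sv2 * tau_v * one_e * one_e
        qvv = sv2 * (1.0 - e * e)
        a00 = p00 + f01 * p01
        a01 = p01 + f01 * p11
        a10 = e * p01
        a11 = e * p11
        n00 = a00 + a01 * f01 + qxx
        n01 = a01 * e + qxv
        n11 = a11 * e + qvv
        p00, p01, p11 = n00, n01, n11
        # update with observation i+1
        Si = p00 + R[i + 1]
        nu_x[i] = yx[i + 1] - mx0
        nu_y[i] = yy[i + 1] - my0
        S[i] = Si
        k0 = p00 / Si
        k1 = p01 / Si
        mx0 += k0 * nu_x[i]
        mx1 += k1 * nu_x[i]
        my0 += k0 * nu_y[i]
        my1 += k1 * nu_y[i]
        p11 -= k1 * p01
        p01 -= k0 * p01
        p00 -= k0 * p00
    return nu_x, nu_y, nu_1, S


@njit(cache=True)
def smooth_series(F, Q, y, obs, R, m0, P0):
    """Fixed-interval RTS smoother for one observation series.

    F, Q: (m-1, d, d) per-step transition/process noise; y: (m,) data with
    ``obs`` flagging which entries are real observations; R: (m,) error
    variances.  Returns the smoothed state means, shape (m, d).
    """
    m = y.shape[0]
    d = m0.shape[0]
    mf = np.empty((m, d))
    Pf = np.empty((m, d, d))
    mp = np.empty((m, d))
    Pp = np.empty((m, d, d))
    mean = m0.copy()
    cov = P0.copy()
    for i in range(m):
        mp[i] = mean
        Pp[i] = cov
        if obs[i]:
            S = cov[0, 0] + R[i]
            nu = y[i] - mean[0]
            for a in range(d):
                K = cov[a, 0] / S
                mean[a] = mean[a] + K * nu
            # cov <- cov - K H cov, K = cov[:,0]/S
            c0 = cov[:, 0].copy()
            for a in range(d):
                for b in range(d):
                    cov[a, b] = cov[a, b] - c0[a] * c0[b] / S
        mf[i] = mean
        Pf[i] = cov
        if i < m - 1:
            mean = F[i] @ mean
            cov = F[i] @ cov @ F[i].T + Q[i]
            mean = mean.copy()
            cov = cov.copy()
    ms = np.empty((m, d))
    ms[m - 1] = mf[m - 1]
    prev = mf[m - 1].copy()
    for i in range(m - 2, -1, -1):
        # J = Pf[i] F' inv(Pp[i+1])
        A = Pf[i] @ F[i].T
        J = np.linalg.solve(Pp[i + 1].T, A.T).T
        cur = mf[i] + J @ (prev - mp[i + 1])
        ms[i] = cur
        prev = cur.copy()
    return ms
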