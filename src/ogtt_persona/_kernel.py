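"""Low-level numba kernel: packed right-hand side and adaptive RK45 integrator.

The public, typed surface lives in :mod:`ogtt_persona.model`; this module only
knows about flat float arrays so that the whole integration loop can be jitted.
Parameter packing layout (see :func:`ogtt_persona.model.pack_kernel_params`):

  0..8   k1..k9
  9      sigma        gastric-emptying shape factor (dimensionless, >= 1)
  10     km           Michaelis-Menten constant, mmol/L
  11     Gb           basal plasma glucose, mmol/L
  12     Ib           basal plasma insulin, mU/L
  13     VgBW         glucose distribution volume, L (vG * body weight)
  14     fD           bioavailable glucose dose, mmol (f * dose)
  15     Gth          renal glucose threshold, mmol/L
  16     c1           renal clearance, L/min
  17     tau_i        PID integral time constant, min
  18     tau_d        PID derivative time constant, min
  19     beta         insulin/glucose distribution factor, dimensionless
  20     c_liv        hepatic insulin clearance rate, 1/min
  21     uii_b        basal insulin-independent uptake, mmol/L/min
  22     egp_b        basal endogenous glucose production, mmol/L/min
  23     t_meal       glucose ingestion time, min

State vector: [gut glucose mass (mmol), plasma glucose (mmol/L),
plasma insulin (mU/L), PID integral (mmol*min/L)].
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_PACKED = 24


@njit(cache=True)
def rhs_packed(t, y, pk):
    """Time derivative of the packed 4-state system."""
    M = y[0]
    G = y[1]
    I = y[2]
    J = y[3]

    k1 = pk[0]
    k2 = pk[1]
    k3 = pk[2]
    k4 = pk[3]
    k5 = pk[4]
    k6 = pk[5]
    k7 = pk[6]
    k8 = pk[7]
    k9 = pk[8]
    sigma = pk[9]
    km = pk[10]
    Gb = pk[11]
    Ib = pk[12]
    VgBW = pk[13]
    fD = pk[14]
    Gth = pk[15]
    c1 = pk[16]
    tau_i = pk[17]
    tau_d = pk[18]
    beta = pk[19]
    c_liv = pk[20]
    uii_b = pk[21]
    egp_b = pk[22]
    t_meal = pk[23]

    # gastric emptying of the ingested load (Weibull-shaped rate, sigma=1 is
    # a pure exponential); integral over [0, inf) equals fD
    tm = t - t_meal
    if tm > 0.0 and fD > 0.0:
        z = k1 * tm
        ra = fD * sigma * k1 * z ** (sigma - 1.0) * np.exp(-(z ** sigma))
    else:
        ra = 0.0

    gut_to_plasma = k2 * M                      # mmol/min
    g_gut = gut_to_plasma / VgBW                # mmol/L/min

    # net hepatic glucose balance: basal production suppressed by glucose
    # and insulin elevation; may go negative (net hepatic uptake) during
    # postprandial hyperinsulinemia
    egp = egp_b - k3 * (G - Gb) - k4 * beta * (I - Ib)

    sat = G / (km + G)
    uii = uii_b * sat / (Gb / (km + Gb))        # obligate oxidizers
    uid = k5 * beta * I * sat                   # insulin-dependent uptake
    ren = 0.0
    if G > Gth:
        ren = c1 * (G - Gth) / VgBW

    dG = g_gut + egp - uii - uid - ren
    dM = ra - gut_to_plasma
    dJ = G - Gb

    sec = (k6 * (G - Gb) + (k7 / tau_i) * J + k8 * tau_d * dG) / beta
    if sec < 0.0:
        sec = 0.0                               # no negative secretion
    dI = sec - c_liv * (I - Ib) - k9 * (I - Ib)

    out = np.empty(4)
    out[0] = dM
    out[1] = dG
    out[2] = dI
    out[3] = dJ
    return out


@njit(cache=True)
def integrate(pk, y0, t_out, rtol, atol, h_max):
    """Adaptive Dormand-Prince RK5(4) from t_out[0] over the requested grid.

    Returns (ys, status): ys has shape (len(t_out), 4); status 0 on success,
    1 on step-size underflow or non-finite state.  Output points are filled by
    cubic Hermite interpolation inside each accepted step.
    """
    n_out = t_out.shape[0]
    ys = np.empty((n_out, 4))
    t = t_out[0]
    y = y0.copy()
    ys[0, 0] = y[0]
    ys[0, 1] = y[1]
    ys[0, 2] = y[2]
    ys[0, 3] = y[3]
    i_out = 1
    t_end = t_out[n_out - 1]
    if i_out >= n_out:
        return ys, 0

    f = rhs_packed(t, y, pk)
    h = 0.1
    if h > h_max:
        h = h_max
    h_min = 1e-10
    safety = 0.9

    while t < t_end:
        if t + h > t_end:
            h = t_end - t

        k1v = f
        k2v = rhs_packed(t + h * 0.2, y + h * 0.2 * k1v, pk)
        k3v = rhs_packed(t + h * 0.3, y + h * (3.0 / 40.0 * k1v + 9.0 / 40.0 * k2v), pk)
        k4v = rhs_packed(
            t + h * 0.8,
            y + h * (44.0 / 45.0 * k1v - 56.0 / 15.0 * k2v + 32.0 / 9.0 * k3v),
            pk,
        )
        k5v = rhs_packed(
            t + h * 8.0 / 9.0,
            y
            + h
            * (
                19372.0 / 6561.0 * k1v
                - 25360.0 / 2187.0 * k2v
                + 64448.0 / 6561.0 * k3v
                - 212.0 / 729.0 * k4v
            ),
            pk,
        )
        k6v = rhs_packed(
            t + h,
            y
            + h
            * (
                9017.0 / 3168.0 * k1v
                - 355.0 / 33.0 * k2v
                + 46732.0 / 5247.0 * k3v
                + 49.0 / 176.0 * k4v
                - 5103.0 / 18656.0 * k5v
            ),
            pk,
        )
        y_new = y + h * (
            35.0 / 384.0 * k1v
            + 500.0 / 1113.0 * k3v
            + 125.0 / 192.0 * k4v
            - 2187.0 / 6784.0 * k5v
            + 11.0 / 84.0 * k6v
        )
        f_new = rhs_packed(t + h, y_new, pk)
        y4 = y + h * (
            5179.0 / 57600.0 * k1v
            + 7571.0 / 16695.0 * k3v
            + 393.0 / 640.0 * k4v
            - 92097.0 / 339200.0 * k5v
            + 187.0 / 2100.0 * k6v
            + 1.0 / 40.0 * f_new
        )

        # scaled error norm
        err = 0.0
        ok = True
        for j in range(4):
            if not np.isfinite(y_new[j]):
                ok = False
                break
            sc = atol + rtol * max(abs(y[j]), abs(y_new[j]))
            e = (y_new[j] - y4[j]) / sc
            err += e * e
        if ok:
            err = np.sqrt(err / 4.0)
        else:
            err = 1e12

        if err <= 1.0:
            # accepted: emit requested outputs inside (t, t+h]
            while i_out < n_out and t_out[i_out] <= t + h + 1e-12:
                s = (t_out[i_out] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for j in range(4):
                    ys[i_out, j] = (
                        h00 * y[j]
                        + h10 * h * f[j]
                        + h01 * y_new[j]
                        + h11 * h * f_new[j]
                    )
                i_out += 1
            t = t + h
            y = y_new
            f = f_new
            fac = safety * err ** -0.2 if err > 0.0 else 5.0
            if fac > 5.0:
                fac = 5.0
            h = h * fac
            if h > h_max:
                h = h_max
        else:
            fac = safety * err ** -0.2
            if fac < 0.1:
                fac = 0.1
            h = h * fac

        if h < h_min:
            return ys, 1

    return ys, 0
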