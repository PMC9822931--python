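"""Independent brute-force oracles used to freeze expected values.

These deliberately re-derive parcel thermodynamics and bookkeeping with
naive fine-step loops, sharing only physical constants with the package,
so they can serve as cross-checks on the implementation's numerics.
"""

import numpy as np

RD = 287.04
CPD = 1005.7
LV = 2.501e6
EPS = 0.622


def es_bolton(t_k):
    tc = t_k - 273.15
    return 611.2 * np.exp(17.67 * tc / (tc + 243.5))


def rs_of(p, t_k):
    es = es_bolton(t_k)
    return EPS * es / (p - es)


def tv_of(t_k, r):
    return t_k * (1.0 + r / EPS) / (1.0 + r)


def lcl_bolton(ps, ts, qs):
    if qs <= 0:
        return 0.0, 0.0
    r = qs / (1.0 - qs)
    e = ps * r / (EPS + r)
    t_lcl = 2840.0 / (3.5 * np.log(ts) - np.log(e / 100.0) - 4.805) + 55.0
    if t_lcl >= ts:
        return ps, ts
    return ps * (t_lcl / ts) ** (CPD / RD), t_lcl


def parcel_temperature_euler(ps, ts, qs, p_target, step=10.0):
    """Parcel temperature at p_target via fine-step Euler ascent."""
    p_lcl, t_lcl = lcl_bolton(ps, ts, qs)
    if p_target >= p_lcl:
        return ts * (p_target / ps) ** (RD / CPD)
    p, t = p_lcl, t_lcl
    while p > p_target:
        h = -min(step, p - p_target)
        rs = rs_of(p, t)
        dtdp = (RD * t + LV * rs) / (p * (CPD + LV**2 * rs * EPS / (RD * t**2)))
        t += h * dtdp
        p += h
    return t


def cape_brute_force(plev_env, t_env, ps, ts, qs, dp=100.0, step=10.0):
    """Fine-dp buoyancy sum with Euler parcel ascent and log-p interpolation."""
    levels = np.arange(1.0e5, 1.0e4 - 0.5 * dp, -dp)
    x = -np.log(plev_env)
    cape = 0.0
    p_lcl, t_lcl = lcl_bolton(ps, ts, qs)
    r0 = qs / (1.0 - qs)
    # single upward pass so the Euler path is continuous across levels
    p, t = p_lcl, t_lcl
    for lev in levels:
        if lev > ps:
            continue
        xt = -np.log(lev)
        if xt < x[0] or xt > x[-1]:
            continue
        te = np.interp(xt, x, t_env)
        rho_e = lev / (RD * te)
        if lev >= p_lcl:
            tp = ts * (lev / ps) ** (RD / CPD)
            rp = r0
        else:
            while p > lev:
                h = -min(step, p - lev)
                rs = rs_of(p, t)
                dtdp = (RD * t + LV * rs) / (p * (CPD + LV**2 * rs * EPS / (RD * t**2)))
                t += h * dtdp
                p += h
            tp = t
            rp = rs_of(lev, tp)
        rho_p = lev / (RD * tv_of(tp, rp))
        b = 1.0 / rho_p - 1.0 / rho_e
        if b > 0:
            cape += dp * b
    return cape


def lapse_rate_environment(t_surface=298.0, lapse_per_m=6.5e-3, p0=1.0e5, dp=5000.0):
    """Constant-lapse-rate sounding T(p) = T0·(p/p0)^(R·γ/g)."""
    g = 9.80665
    plev = np.arange(p0, 1.0e4 - 0.5 * dp, -dp)
    t_env = t_surface * (plev / p0) ** (RD * lapse_per_m / g)
    return plev, t_env
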