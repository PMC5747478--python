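"""Independent brute-force integrator of the human atrial ionic model.

A deliberately plain, scalar transcription of the published equations
(no lookup tables, no Rush-Larsen: explicit forward Euler on every
state) used as the oracle for the package's optimised implementation.
Kept separate from the package so the two codings share nothing but
the published model itself.
"""

import math

R = 8.3143
T = 310.0
F = 96.4867
CM = 100.0
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48
NA_O, K_O, CA_O = 140.0, 5.4, 1.8

STATE0 = {
    "V": -81.18, "m": 2.908e-3, "h": 9.649e-1, "j": 9.775e-1,
    "oa": 3.043e-2, "oi": 9.992e-1, "ua": 4.966e-3, "ui": 9.986e-1,
    "xr": 3.296e-5, "xs": 1.869e-2, "d": 1.367e-4, "f": 9.996e-1,
    "fca": 7.755e-1, "u": 0.0, "v": 1.0, "w": 9.992e-1,
    "nai": 11.17, "ki": 139.0, "cai": 1.013e-4, "caup": 1.488, "carel": 1.488,
}


def _exp(x):
    return math.exp(max(min(x, 300.0), -300.0))


def derivatives(s, istim=0.0, remodel=False):
    """Time derivatives of all 21 states; currents in pA/pF."""
    V = s["V"]
    g_to = 0.1652 * (0.2 if remodel else 1.0)
    kur_scale = 0.5 if remodel else 1.0
    g_cal = 0.12375 * (0.6 if remodel else 1.0)
    g_k1 = 0.09 * (1.5 if remodel else 1.0)

    ena = R * T / F * math.log(NA_O / s["nai"])
    ek = R * T / F * math.log(K_O / s["ki"])
    eca = R * T / (2 * F) * math.log(CA_O / s["cai"])

    ina = 7.8 * s["m"] ** 3 * s["h"] * s["j"] * (V - ena)
    ik1 = g_k1 * (V - ek) / (1 + _exp(0.07 * (V + 80)))
    ito = g_to * s["oa"] ** 3 * s["oi"] * (V - ek)
    gkur = 0.005 + 0.05 / (1 + _exp(-(V - 15) / 13))
    ikur = kur_scale * gkur * s["ua"] ** 3 * s["ui"] * (V - ek)
    ikr = 0.029411765 * s["xr"] * (V - ek) / (1 + _exp((V + 15) / 22.4))
    iks = 0.12941176 * s["xs"] ** 2 * (V - ek)
    ical = g_cal * s["d"] * s["f"] * s["fca"] * (V - 65.0)
    sigma = (_exp(NA_O / 67.3) - 1) / 7
    fnak = 1.0 / (1 + 0.1245 * _exp(-0.1 * F * V / (R * T))
                  + 0.0365 * sigma * _exp(-F * V / (R * T)))
    inak = 0.59933874 * fnak / (1 + (10.0 / s["nai"]) ** 1.5) * K_O / (K_O + 1.5)
    g = F * V / (R * T)
    inaca = 1600.0 * (_exp(0.35 * g) * s["nai"] ** 3 * CA_O
                      - _exp(-0.65 * g) * NA_O ** 3 * s["cai"]) / (
        (87.5 ** 3 + NA_O ** 3) * (1.38 + CA_O) * (1 + 0.1 * _exp(-0.65 * g)))
    ibna = 0.0006744375 * (V - ena)
    ibca = 0.001131 * (V - eca)
    ipca = 0.275 * s["cai"] / (0.0005 + s["cai"])

    irel = 30.0 * s["u"] ** 2 * s["v"] * s["w"] * (s["carel"] - s["cai"])
    itr = (s["caup"] - s["carel"]) / 180.0
    iup = 0.005 / (1 + 0.00092 / s["cai"])
    iupleak = 0.005 * s["caup"] / 15.0
    fn = 1e3 * (1e-15 * V_REL * irel - 1e-15 / (2 * F) * (0.5 * ical - 0.2 * inaca) * CM)

    d = {}
    iion = ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca + ibna + ibca + ipca
    d["V"] = -(iion + istim)

    # gates: alpha/beta or inf/tau forms, forward differences
    if abs(V + 47.13) < 1e-7:
        am = 3.2
    else:
        am = 0.32 * (V + 47.13) / (1 - _exp(-0.1 * (V + 47.13)))
    bm = 0.08 * _exp(-V / 11.0)
    d["m"] = am * (1 - s["m"]) - bm * s["m"]
    if V < -40:
        ah = 0.135 * _exp((V + 80) / -6.8)
        bh = 3.56 * _exp(0.079 * V) + 3.1e5 * _exp(0.35 * V)
        aj = ((-1.2714e5 * _exp(0.2444 * V) - 3.474e-5 * _exp(-0.04391 * V))
              * (V + 37.78) / (1 + _exp(0.311 * (V + 79.23))))
        bj = 0.1212 * _exp(-0.01052 * V) / (1 + _exp(-0.1378 * (V + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1 + _exp((V + 10.66) / -11.1)))
        aj = 0.0
        bj = 0.3 * _exp(-2.535e-7 * V) / (1 + _exp(-0.1 * (V + 32)))
    d["h"] = ah * (1 - s["h"]) - bh * s["h"]
    d["j"] = aj * (1 - s["j"]) - bj * s["j"]

    aoa = 0.65 / (_exp(-(V + 10) / 8.5) + _exp(-(V - 30) / 59.0))
    boa = 0.65 / (2.5 + _exp((V + 82) / 17.0))
    oainf = 1 / (1 + _exp(-(V + 20.47) / 17.54))
    d["oa"] = (oainf - s["oa"]) * (aoa + boa) * 3.0
    aoi = 1 / (18.53 + _exp((V + 113.7) / 10.95))
    boi = 1 / (35.56 + _exp(-(V + 1.26) / 7.44))
    oiinf = 1 / (1 + _exp((V + 43.1) / 5.3))
    d["oi"] = (oiinf - s["oi"]) * (aoi + boi) * 3.0
    uainf = 1 / (1 + _exp(-(V + 30.3) / 9.6))
    d["ua"] = (uainf - s["ua"]) * (aoa + boa) * 3.0
    aui = 1 / (21 + _exp(-(V - 185) / 28))
    bui = _exp((V - 158) / 16.0)
    uiinf = 1 / (1 + _exp((V - 99.45) / 27.48))
    d["ui"] = (uiinf - s["ui"]) * (aui + bui) * 3.0

    if abs(V + 14.1) < 1e-7:
        axr = 0.0015
    else:
        axr = 0.0003 * (V + 14.1) / (1 - _exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-7:
        bxr = 7.3898e-5 * 5.1237
    else:
        bxr = 7.3898e-5 * (V - 3.3328) / (_exp((V - 3.3328) / 5.1237) - 1)
    xrinf = 1 / (1 + _exp(-(V + 14.1) / 6.5))
    d["xr"] = (xrinf - s["xr"]) * (axr + bxr)
    if abs(V - 19.9) < 1e-7:
        axs = 4e-5 * 17.0
        bxs = 3.5e-5 * 9.0
    else:
        axs = 4e-5 * (V - 19.9) / (1 - _exp(-(V - 19.9) / 17.0))
        bxs = 3.5e-5 * (V - 19.9) / (_exp((V - 19.9) / 9.0) - 1)
    xsinf = (1 + _exp(-(V - 19.9) / 12.7)) ** -0.5
    d["xs"] = (xsinf - s["xs"]) * 2.0 * (axs + bxs)

    if abs(V + 10) < 1e-7:
        taud = 1 / (0.035 * 6.24 * 2)
    else:
        taud = (1 - _exp(-(V + 10) / 6.24)) / (
            0.035 * (V + 10) * (1 + _exp(-(V + 10) / 6.24)))
    dinf = 1 / (1 + _exp(-(V + 10) / 8.0))
    d["d"] = (dinf - s["d"]) / taud
    tauf = 9.0 / (0.0197 * _exp(-(0.0337 ** 2) * (V + 10) ** 2) + 0.02)
    finf = 1 / (1 + _exp((V + 28) / 6.9))
    d["f"] = (finf - s["f"]) / tauf
    fcainf = 1 / (1 + s["cai"] / 0.00035)
    d["fca"] = (fcainf - s["fca"]) / 2.0

    uinf = 1 / (1 + _exp(-(fn - 3.4175e-13) / 13.67e-16))
    d["u"] = (uinf - s["u"]) / 8.0
    vinf = 1 - 1 / (1 + _exp(-(fn - 6.835e-14) / 13.67e-16))
    tauv = 1.91 + 2.09 / (1 + _exp(-(fn - 3.4175e-13) / 13.67e-16))
    d["v"] = (vinf - s["v"]) / tauv
    if abs(V - 7.9) < 1e-7:
        tauw = 6.0 * 0.2 / 1.3
    else:
        tauw = (6.0 * (1 - _exp(-(V - 7.9) / 5.0))
                / ((1 + 0.3 * _exp(-(V - 7.9) / 5.0)) * (V - 7.9)))
    winf = 1 - 1 / (1 + _exp(-(V - 40) / 17.0))
    d["w"] = (winf - s["w"]) / tauw

    d["nai"] = (-3 * inak - 3 * inaca - ibna - ina) * CM / (F * V_I)
    d["ki"] = (2 * inak - ik1 - ito - ikur - ikr - iks) * CM / (F * V_I)
    b1 = ((2 * inaca - ipca - ical - ibca) * CM / (2 * F * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1 + 0.07 * 0.0005 / (s["cai"] + 0.0005) ** 2
          + 0.05 * 0.00238 / (s["cai"] + 0.00238) ** 2)
    d["cai"] = b1 / b2
    d["caup"] = iup - iupleak - itr * V_REL / V_UP
    d["carel"] = (itr - irel) / (1 + 10.0 * 0.8 / (s["carel"] + 0.8) ** 2)
    return d


def integrate(duration_ms, dt=0.005, stim_times=(), stim_dur=2.0,
              stim_amp=-20.0, remodel=False, record_every=0.1):
    """Forward-Euler integration; returns (times, V) lists."""
    s = dict(STATE0)
    times, volts = [0.0], [s["V"]]
    n = int(round(duration_ms / dt))
    rec = max(1, int(round(record_every / dt)))
    for k in range(1, n + 1):
        t = (k - 1) * dt
        istim = 0.0
        for ts in stim_times:
            if ts <= t < ts + stim_dur:
                istim = stim_amp
                break
        d = derivatives(s, istim, remodel)
        for key in s:
            s[key] += dt * d[key]
        if k % rec == 0:
            times.append(k * dt)
            volts.append(s["V"])
    return times, volts, s
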