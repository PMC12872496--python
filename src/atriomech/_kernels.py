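"""Compiled right-hand side of the electromechanical cell model.

Electrophysiology and Ca2+ handling follow the Courtemanche/Koivumaki family
of human atrial formulations with two cytosolic Ca2+ compartments (a thin
sub-sarcolemmal "subspace" ss facing the junctional SR, and the bulk cytosol
bc facing the network SR), RyR release units with Ca-dependent activation,
inactivation and slow adaptation in both compartments, a reversible SERCA
pump, a CaMKII activity state, and a mean-field regulatory-unit /
cross-bridge contraction model whose Ca-TnC buffer feeds back on the bulk
Ca2+ balance (mechano-calcium feedback).

Everything here works on flat float64 vectors laid out per `_layout`;
`model.py` provides the user-facing containers.
"""

import math

import numpy as np
from numba import njit

from ._layout import *  # noqa: F401,F403 -- index constants
from ._layout import (
    NSTATE, NCURRENT,
    S_V, S_M, S_H, S_J, S_D, S_F, S_FCA, S_ATO, S_ITO, S_AUR, S_IUR, S_PA,
    S_XS, S_OSS, S_CSS, S_ASS, S_OBC, S_CBC, S_ABC, S_CASS, S_CABC,
    S_CASRSS, S_CASRBC, S_NAI, S_KI, S_CAMK, S_CATNC, S_PRU, S_NXB, S_XD,
    S_SL,
    P_CM, P_VSS, P_VBC, P_VSRSS, P_VSRBC, P_NAO, P_KO, P_CAO, P_GNA, P_GCAL,
    P_GTO, P_GKUR, P_GKR, P_GKS, P_GK1, P_KNACA, P_INAK, P_GCAB, P_GNAB,
    P_IPCA, P_GKACH, P_KCA, P_ECAL, P_KRVH, P_KRSL, P_INARS, P_INASH,
    P_RYR_TAUA_SS, P_RYR_TAUI_SS, P_RYR_TAUAD, P_RYR_TAUA_BC, P_RYR_TAUI_BC,
    P_RYR_A1, P_RYR_A2, P_RYR_OK, P_RYR_CK, P_RYR_SRVH, P_RYR_SRK,
    P_NURELSS, P_NURELBC, P_KSRLEAK, P_SERCA_K4, P_SERCA_KMF, P_SERCA_KMR,
    P_TAUDIFF, P_TAUSRDIFF, P_BSS, P_KDBSS, P_BBC, P_KDBBC, P_CSQN,
    P_KMCSQN, P_CAMK0, P_ACAMK, P_BCAMK, P_KMCAM, P_CAMK_RYR, P_CAMK_SERCA,
    P_ACH, P_GAMMA, P_KD0, P_KOFF, P_KBASIC, P_MUFP0, P_MUFP1, P_R0P,
    P_R0N, P_ALPHA, P_AXB, P_FXB, P_TNCMAX, P_KDSCALE, P_SL, P_SLREF,
    P_LDA, P_X0, P_KOFFREF, P_CLAMP_CASR, P_CLAMP_CASS, P_TAUFCA,
    P_RYR_OFF_SS, P_RYR_OFF_BC, P_TAUF_SCALE, P_CAMK_LEAK,
    C_INA, C_ICAL, C_ITO, C_IKUR, C_IKR, C_IKS, C_IK1, C_INAK, C_INACA,
    C_ICAB, C_INAB, C_IPCA, C_IKACH, C_ITOT, C_JRELSS, C_JRELBC, C_JUP,
    C_JDIFF, C_JLEAK, C_TA,
)

FARADAY = 96.4867   # C/mmol
RTF = 26.712338     # mV at 310 K

# channel clamp modes
CLAMP_NONE = 0
CLAMP_ICAL = 1
CLAMP_IKR = 2

_EMPTY = np.zeros(1, dtype=np.float64)


@njit(cache=True, fastmath=False)
def _safe_exp(x):
    if x > 80.0:
        x = 80.0
    elif x < -80.0:
        x = -80.0
    return math.exp(x)


@njit(cache=True)
def contraction_rates(ca, y_catnc, y_pru, y_nxb, y_xd, P, dsl_dt):
    """Derivatives of the four contraction states for free Ca `ca` (uM).

    Returns (dCaTnC, dPRU, dNXB, dXD, Ta).  Rates in the parameter vector
    are per second; the model clock is ms.
    """
    sl = P[P_SL]
    # Ta-pCa half-activation: kd0 at SL_ref, shifted by length-dependent
    # activation; the kd_scale intervention multiplies the EC50.
    pca50 = P[P_KD0] + P[P_LDA] * (sl - P[P_SLREF])
    kd_ref = P[P_KDSCALE] * 10.0 ** (6.0 - pca50)      # uM
    # kon is tied to the reference off-rate so kd0 stays the half-activation
    # EC50; the factor compensates the off-rate feedback at half activation
    kon = (P[P_KOFFREF] * 1e-3) * (1.0 - 0.5 * (1.0 - P[P_MUFP1])) / kd_ref
    # permissive RUs hold their Ca (mechano-calcium feedback): off-rate
    # relaxes toward mufp1 * koff as activation saturates
    koff_eff = (P[P_KOFF] * 1e-3) * (1.0 - (1.0 - P[P_MUFP1]) * y_pru)
    tnc_free = P[P_TNCMAX] - y_catnc
    if tnc_free < 0.0:
        tnc_free = 0.0
    d_catnc = kon * ca * tnc_free - koff_eff * y_catnc

    # regulatory unit: cooperative permissivity driven by TnC occupancy
    occ = y_catnc / P[P_TNCMAX]
    if occ < 1e-12:
        occ = 1e-12
    # mean-field conversion of nearest-neighbour cooperativity to an
    # effective occupancy exponent
    g = 0.25 * P[P_GAMMA]
    w = occ ** g
    p_inf = w / (w + 0.5 ** g)
    d_pru = (P[P_KBASIC] * 1e-3) * (p_inf - y_pru)

    # cross-bridges: attachment from the permissive pool, strain-dependent
    # detachment; distortion relaxes to the power-stroke value x0 under
    # isometric conditions and is driven by filament sliding otherwise.
    x0 = P[P_X0]
    s = 1.0 / (1.0 + _safe_exp(-y_xd / (0.1 * x0)))
    r_det = (P[P_R0P] * s + P[P_R0N] * (1.0 - s)) \
        * (1.0 + P[P_ALPHA] * (y_xd - x0) ** 2) * 1e-3
    f_att = P[P_MUFP0] * 1e-3
    d_nxb = f_att * y_pru * (1.0 - y_nxb) - r_det * y_nxb
    d_xd = f_att * (x0 - y_xd) + 0.5 * dsl_dt

    # tension scales with the functional thin-filament density
    ta = P[P_AXB] * P[P_FXB] * (P[P_TNCMAX] / 70.0) * y_nxb * (y_xd / x0)
    return d_catnc, d_pru, d_nxb, d_xd, ta


@njit(cache=True)
def rhs(t, y, P, i_stim, clamp_mode, clamp_t, clamp_i, clamp_period,
        out_currents):
    """dy/dt of the full cell model; also fills `out_currents` (len NCURRENT)."""
    dy = np.zeros(NSTATE)

    v = y[S_V]
    nai = y[S_NAI]
    ki = y[S_KI]
    cass = y[S_CASS]        # uM
    cabc = y[S_CABC]        # uM
    casrss = y[S_CASRSS]    # mM
    casrbc = y[S_CASRBC]    # mM
    if nai < 1e-3:
        nai = 1e-3
    if ki < 1e-3:
        ki = 1e-3
    if cass < 1e-6:
        cass = 1e-6
    if cabc < 1e-6:
        cabc = 1e-6

    ena = RTF * math.log(P[P_NAO] / nai)
    ek = RTF * math.log(P[P_KO] / ki)
    eca = 0.5 * RTF * math.log(P[P_CAO] / (cass * 1e-3))

    # ----- INa (Luo-Rudy/Courtemanche kinetics, Kv-shifted availability) ---
    vm = v
    if vm == -47.13:
        am = 3.2
    else:
        am = 0.32 * (vm + 47.13) / (1.0 - _safe_exp(-0.1 * (vm + 47.13)))
    bm = 0.08 * _safe_exp(-vm / 11.0)
    dy[S_M] = am * (1.0 - y[S_M]) - bm * y[S_M]

    # availability shift moves the h/j voltage dependence rightward
    vh = v - P[P_INASH]
    if vh < -40.0:
        ah = 0.135 * _safe_exp(-(vh + 80.0) / 6.8)
        bh = 3.56 * _safe_exp(0.079 * vh) + 3.1e5 * _safe_exp(0.35 * vh)
        aj = (-1.2714e5 * _safe_exp(0.2444 * vh)
              - 3.474e-5 * _safe_exp(-0.04391 * vh)) * (vh + 37.78) \
            / (1.0 + _safe_exp(0.311 * (vh + 79.23)))
        bj = 0.1212 * _safe_exp(-0.01052 * vh) \
            / (1.0 + _safe_exp(-0.1378 * (vh + 40.14)))
    else:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + _safe_exp(-(vh + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * _safe_exp(-2.535e-7 * vh) \
            / (1.0 + _safe_exp(-0.1 * (vh + 32.0)))
    hinf = ah / (ah + bh) if (ah + bh) > 0.0 else 0.0
    tauh = 1.0 / (ah + bh)
    jinf = aj / (aj + bj) if (aj + bj) > 0.0 else 0.0
    tauj = 1.0 / (aj + bj)
    # recovery from inactivation (gate reopening) can be accelerated
    if hinf > y[S_H]:
        tauh *= P[P_INARS]
    if jinf > y[S_J]:
        tauj *= P[P_INARS]
    dy[S_H] = (hinf - y[S_H]) / tauh
    dy[S_J] = (jinf - y[S_J]) / tauj
    ina = P[P_GNA] * y[S_M] ** 3 * y[S_H] * y[S_J] * (v - ena)

    # ----- ICaL --------------------------------------------------------
    dv10 = v + 10.0
    dinf = 1.0 / (1.0 + _safe_exp(-dv10 / 8.0))
    if abs(dv10) < 1e-6:
        taud = 1.0 / (0.07 * 6.24)
    else:
        e = _safe_exp(-dv10 / 6.24)
        taud = (1.0 - e) / (0.035 * dv10 * (1.0 + e))
    finf = 1.0 / (1.0 + _safe_exp((v + 28.0) / 6.9))
    # voltage-dependent inactivation: ~170 ms clock at plateau potentials,
    # slow recovery in the -40..0 mV window (reopening there is the
    # phase-2 EAD substrate), fast recovery at diastolic potentials
    tauf = P[P_TAUF_SCALE] * (
        50.0 + 400.0 * _safe_exp(-((v + 50.0) / 40.0) ** 2)
        + 100.0 * _safe_exp(-((v - 10.0) / 30.0) ** 2))
    fcainf = 1.0 / (1.0 + (cass / P[P_KCA]) ** 2)
    dy[S_D] = (dinf - y[S_D]) / taud
    dy[S_F] = (finf - y[S_F]) / tauf
    dy[S_FCA] = (fcainf - y[S_FCA]) / P[P_TAUFCA]
    ical = P[P_GCAL] * y[S_D] * y[S_F] * y[S_FCA] * (v - P[P_ECAL])
    if clamp_mode == CLAMP_ICAL:
        tt = t % clamp_period
        ical = np.interp(tt, clamp_t, clamp_i)

    # ----- Ito (Kv4.3 kinetics: fast recovery) -------------------------
    atoinf = 1.0 / (1.0 + _safe_exp(-(v - 1.0) / 11.0))
    tauato = 3.5 * _safe_exp(-(v / 30.0) ** 2) + 1.5
    itoinf = 1.0 / (1.0 + _safe_exp((v + 40.5) / 11.5))
    tauito = 25.635 * _safe_exp(-((v + 52.45) / 15.8827) ** 2) + 24.14
    dy[S_ATO] = (atoinf - y[S_ATO]) / tauato
    dy[S_ITO] = (itoinf - y[S_ITO]) / tauito
    ito = P[P_GTO] * y[S_ATO] * y[S_ITO] * (v - ek)

    # ----- IKur (sustained outward; partial slow inactivation) ----------
    aurinf = 1.0 / (1.0 + _safe_exp(-(v + 6.0) / 8.6))
    tauaur = 9.0 / (1.0 + _safe_exp((v + 5.0) / 12.0)) + 0.5
    iurinf = 0.6 + 0.4 / (1.0 + _safe_exp((v + 7.5) / 10.0))
    tauiur = 590.0 / (1.0 + _safe_exp((v + 60.0) / 10.0)) + 3050.0
    dy[S_AUR] = (aurinf - y[S_AUR]) / tauaur
    dy[S_IUR] = (iurinf - y[S_IUR]) / tauiur
    ikur = P[P_GKUR] * y[S_AUR] * y[S_IUR] * (v - ek)

    # ----- IKr: activation gate + fast inactivation (slope updated) -----
    # activation speeds up steeply with depolarization, so an elevated
    # plateau recruits extra IKr (the voltage-mediated secondary response)
    painf = 1.0 / (1.0 + _safe_exp(-(v - 5.0) / 9.0))
    # fast voltage-sensitive activation at plateau potentials, slow
    # deactivation on repolarization (resurgent IKr tail)
    taupa = 31.18 + 217.18 * _safe_exp(-((v + 20.1376) / 22.1996) ** 2) \
        + 120.0 * _safe_exp(-((v + 70.0) / 20.0) ** 2)
    dy[S_PA] = (painf - y[S_PA]) / taupa
    r_kr = 1.0 / (1.0 + _safe_exp((v + P[P_KRVH]) / P[P_KRSL]))
    ikr = P[P_GKR] * y[S_PA] * r_kr * (v - ek)
    if clamp_mode == CLAMP_IKR:
        tt = t % clamp_period
        ikr = np.interp(tt, clamp_t, clamp_i)

    # ----- IKs ----------------------------------------------------------
    dv199 = v - 19.9
    if abs(dv199) < 1e-6:
        axs = 4e-5 * 17.0
        bxs = 3.5e-5 * 9.0
    else:
        axs = 4e-5 * dv199 / (1.0 - _safe_exp(-dv199 / 17.0))
        bxs = 3.5e-5 * dv199 / (_safe_exp(dv199 / 9.0) - 1.0)
    xsinf = 1.0 / (1.0 + _safe_exp(-dv199 / 12.7))
    tauxs = 0.5 / (axs + bxs)
    dy[S_XS] = (xsinf - y[S_XS]) / tauxs
    iks = P[P_GKS] * y[S_XS] ** 2 * (v - ek)

    # ----- IK1, pumps, exchangers, backgrounds --------------------------
    ik1 = P[P_GK1] * (v - ek) / (1.0 + _safe_exp(0.07 * (v + 80.0)))

    sigma = (_safe_exp(P[P_NAO] / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * _safe_exp(-0.1 * v / RTF)
                  + 0.0365 * sigma * _safe_exp(-v / RTF))
    inak = P[P_INAK] * fnak / (1.0 + (10.0 / nai) ** 1.5) \
        * P[P_KO] / (P[P_KO] + 1.5)

    cass_mm = cass * 1e-3
    e1 = _safe_exp(0.35 * v / RTF)
    e2 = _safe_exp(-0.65 * v / RTF)
    inaca = P[P_KNACA] * (e1 * nai ** 3 * P[P_CAO]
                          - e2 * P[P_NAO] ** 3 * cass_mm) \
        / ((87.5 ** 3 + P[P_NAO] ** 3) * (1.38 + P[P_CAO])
           * (1.0 + 0.1 * e2))

    icab = P[P_GCAB] * (v - eca)
    inab = P[P_GNAB] * (v - ena)
    ipca = P[P_IPCA] * cass / (cass + 0.5)

    # ----- IKACh (ACh dose-dependent inward rectifier) ------------------
    ach = P[P_ACH]
    if ach > 0.0 and P[P_GKACH] > 0.0:
        dose = 1.0 / (1.0 + (0.03 / ach) ** 2.1)
        ikach = P[P_GKACH] * dose \
            * (0.08 + 0.4 / (1.0 + _safe_exp((v + 91.0) / 12.0))) * (v - ek)
    else:
        ikach = 0.0

    itot = (ina + ical + ito + ikur + ikr + iks + ik1 + inak + inaca
            + icab + inab + ipca + ikach)
    dy[S_V] = -(itot + i_stim)

    # ----- CaMKII -------------------------------------------------------
    camk_b = P[P_CAMK0] * (1.0 - y[S_CAMK]) / (1.0 + P[P_KMCAM] / cass)
    camk_a = camk_b + y[S_CAMK]
    dy[S_CAMK] = P[P_ACAMK] * camk_b * camk_a - P[P_BCAMK] * y[S_CAMK]
    camk_frac = camk_a / (camk_a + 0.15)   # saturating effect curve

    # ----- RyR gating (both compartments) -------------------------------
    camk_shift = P[P_CAMK_RYR] * camk_frac
    a1 = P[P_RYR_A1]
    a2 = P[P_RYR_A2]

    ainf_ss = a1 - a2 / (1.0 + _safe_exp((cass - 0.29) / 0.082))
    oinf_ss = 1.0 - 1.0 / (1.0 + _safe_exp(
        (cass - (y[S_ASS] + P[P_RYR_OFF_SS] - camk_shift)) / P[P_RYR_OK]))
    cinf_ss = 1.0 / (1.0 + _safe_exp(
        (cass - (y[S_ASS] + 0.02)) / P[P_RYR_CK]))
    dy[S_OSS] = (oinf_ss - y[S_OSS]) / P[P_RYR_TAUA_SS]
    dy[S_CSS] = (cinf_ss - y[S_CSS]) / P[P_RYR_TAUI_SS]
    dy[S_ASS] = (ainf_ss - y[S_ASS]) / P[P_RYR_TAUAD]

    ainf_bc = a1 - a2 / (1.0 + _safe_exp((cabc - 0.29) / 0.082))
    oinf_bc = 1.0 - 1.0 / (1.0 + _safe_exp(
        (cabc - (y[S_ABC] + P[P_RYR_OFF_BC] - camk_shift)) / P[P_RYR_OK]))
    cinf_bc = 1.0 / (1.0 + _safe_exp(
        (cabc - (y[S_ABC] + 0.02)) / P[P_RYR_CK]))
    dy[S_OBC] = (oinf_bc - y[S_OBC]) / P[P_RYR_TAUA_BC]
    dy[S_CBC] = (cinf_bc - y[S_CBC]) / P[P_RYR_TAUI_BC]
    dy[S_ABC] = (ainf_bc - y[S_ABC]) / P[P_RYR_TAUAD]

    # SR-load dependence of release
    srgate_ss = 1.0 - 1.0 / (1.0 + _safe_exp(
        (casrss - P[P_RYR_SRVH]) / P[P_RYR_SRK]))
    srgate_bc = 1.0 - 1.0 / (1.0 + _safe_exp(
        (casrbc - P[P_RYR_SRVH]) / P[P_RYR_SRK]))

    jrel_ss = P[P_NURELSS] * y[S_OSS] * y[S_CSS] * srgate_ss \
        * (casrss * 1e3 - cass)
    jrel_bc = P[P_NURELBC] * y[S_OBC] * y[S_CBC] * srgate_bc \
        * (casrbc * 1e3 - cabc)

    # CaMKII hyperphosphorylation increases diastolic RyR leak
    kleak = P[P_KSRLEAK] * (1.0 + P[P_CAMK_LEAK] * camk_frac)
    jleak_ss = kleak * (casrss * 1e3 - cass)
    jleak_bc = kleak * (casrbc * 1e3 - cabc)

    # ----- SERCA (bulk -> network SR), CaMKII lowers Kmf ----------------
    kmf = P[P_SERCA_KMF] * (1.0 - P[P_CAMK_SERCA] * camk_frac)
    fwd = (cabc / kmf) ** 2
    rev = (casrbc / P[P_SERCA_KMR]) ** 2
    jup = P[P_SERCA_K4] * (fwd - rev) / (1.0 + fwd + rev)

    jdiff = (cass - cabc) / P[P_TAUDIFF]
    jsrdiff = (casrbc - casrss) / P[P_TAUSRDIFF]   # mM/ms in SRss volume

    # ----- contraction & mechano-calcium feedback -----------------------
    d_catnc, d_pru, d_nxb, d_xd, ta = contraction_rates(
        cabc, y[S_CATNC], y[S_PRU], y[S_NXB], y[S_XD], P, 0.0)
    dy[S_CATNC] = d_catnc
    dy[S_PRU] = d_pru
    dy[S_NXB] = d_nxb
    dy[S_XD] = d_xd
    dy[S_SL] = 0.0

    # ----- ion balances -------------------------------------------------
    cm = P[P_CM]
    vss = P[P_VSS]
    vbc = P[P_VBC]
    vsrss = P[P_VSRSS]
    vsrbc = P[P_VSRBC]
    # A/F -> uM/ms for a univalent ion in volume v_pl
    conv1_bc = cm * 1e-3 / (FARADAY * (vbc + vss))      # mM/ms per A/F
    conv2_ss = cm * 1e-3 / (2.0 * FARADAY * vss) * 1e3  # uM/ms per A/F

    dy[S_NAI] = -(ina + inab + 3.0 * inak + 3.0 * inaca) * conv1_bc
    dy[S_KI] = -(ito + ikur + ikr + iks + ik1 + ikach - 2.0 * inak
                 + i_stim) * conv1_bc

    bss = 1.0 / (1.0 + P[P_BSS] * P[P_KDBSS] / (P[P_KDBSS] + cass) ** 2)
    bbc = 1.0 / (1.0 + P[P_BBC] * P[P_KDBBC] / (P[P_KDBBC] + cabc) ** 2)
    bsrss = 1.0 / (1.0 + P[P_CSQN] * P[P_KMCSQN]
                   / (P[P_KMCSQN] + casrss) ** 2)
    bsrbc = 1.0 / (1.0 + P[P_CSQN] * P[P_KMCSQN]
                   / (P[P_KMCSQN] + casrbc) ** 2)

    dy[S_CASS] = bss * ((2.0 * inaca - ical - icab - ipca) * conv2_ss
                        + jrel_ss + jleak_ss - jdiff)
    dy[S_CABC] = bbc * (jdiff * vss / vbc + jrel_bc + jleak_bc - jup
                        - d_catnc)
    dy[S_CASRSS] = bsrss * (-(jrel_ss + jleak_ss) * vss / vsrss * 1e-3
                            + jsrdiff)
    dy[S_CASRBC] = bsrbc * ((jup - jrel_bc - jleak_bc) * vbc / vsrbc * 1e-3
                            - jsrdiff * vsrss / vsrbc)

    if P[P_CLAMP_CASS] != 0.0:
        dy[S_CASS] = 0.0
    if P[P_CLAMP_CASR] != 0.0:
        dy[S_CASRSS] = 0.0
        dy[S_CASRBC] = 0.0

    out_currents[C_INA] = ina
    out_currents[C_ICAL] = ical
    out_currents[C_ITO] = ito
    out_currents[C_IKUR] = ikur
    out_currents[C_IKR] = ikr
    out_currents[C_IKS] = iks
    out_currents[C_IK1] = ik1
    out_currents[C_INAK] = inak
    out_currents[C_INACA] = inaca
    out_currents[C_ICAB] = icab
    out_currents[C_INAB] = inab
    out_currents[C_IPCA] = ipca
    out_currents[C_IKACH] = ikach
    out_currents[C_ITOT] = itot
    out_currents[C_JRELSS] = jrel_ss
    out_currents[C_JRELBC] = jrel_bc
    out_currents[C_JUP] = jup
    out_currents[C_JDIFF] = jdiff
    out_currents[C_JLEAK] = jleak_ss * vss / vbc + jleak_bc  # bulk-volume units
    out_currents[C_TA] = ta
    return dy


@njit(cache=True)
def rhs_only(t, y, P, i_stim, clamp_mode, clamp_t, clamp_i, clamp_period):
    buf = np.empty(NCURRENT)
    return rhs(t, y, P, i_stim, clamp_mode, clamp_t, clamp_i, clamp_period,
               buf)


@njit(cache=True)
def currents_matrix(ts, ys, P, clamp_mode, clamp_t, clamp_i, clamp_period):
    """Per-sample currents/fluxes for an (n, NSTATE) state matrix."""
    n = ts.shape[0]
    out = np.empty((n, NCURRENT))
    buf = np.empty(NCURRENT)
    for i in range(n):
        rhs(ts[i], ys[i], P, 0.0, clamp_mode, clamp_t, clamp_i,
            clamp_period, buf)
        out[i] = buf
    return out
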