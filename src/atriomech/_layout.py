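"""Flat-array layouts shared by the ODE kernels and the Python API.

The compiled right-hand side works on plain float64 vectors; this module is
the single authority for which slot means what, both for the state vector
and the parameter vector.  Keep the integer constants and the name lists in
sync -- tests assert the correspondence.
"""

# ---------------------------------------------------------------------------
# state vector
# ---------------------------------------------------------------------------
S_V = 0        # membrane potential (mV)
S_M = 1        # INa activation
S_H = 2        # INa fast inactivation
S_J = 3        # INa slow inactivation
S_D = 4        # ICaL activation
S_F = 5        # ICaL voltage-dependent inactivation
S_FCA = 6      # ICaL Ca-dependent inactivation
S_ATO = 7      # Ito activation
S_ITO = 8      # Ito inactivation
S_AUR = 9      # IKur activation
S_IUR = 10     # IKur (partial) inactivation
S_PA = 11      # IKr activation
S_XS = 12      # IKs activation
S_OSS = 13     # RyR open gate, subspace
S_CSS = 14     # RyR inactivation gate, subspace
S_ASS = 15     # RyR adaptation, subspace
S_OBC = 16     # RyR open gate, bulk
S_CBC = 17     # RyR inactivation gate, bulk
S_ABC = 18     # RyR adaptation, bulk
S_CASS = 19    # subspace free Ca2+ (uM)
S_CABC = 20    # bulk-cytosol free Ca2+ (uM)
S_CASRSS = 21  # junctional SR free Ca2+ (mM)
S_CASRBC = 22  # network SR free Ca2+ (mM)
S_NAI = 23     # intracellular Na+ (mM)
S_KI = 24      # intracellular K+ (mM)
S_CAMK = 25    # trapped (autonomous) CaMKII fraction
S_CATNC = 26   # Ca bound to troponin C (uM)
S_PRU = 27     # permissive regulatory-unit fraction
S_NXB = 28     # attached cross-bridge fraction
S_XD = 29      # mean cross-bridge distortion (um)
S_SL = 30      # sarcomere length (um); isometric, dSL/dt = 0

NSTATE = 31

STATE_NAMES = [
    "Vm", "m", "h", "j", "d", "f", "fCa", "a_to", "i_to", "a_ur", "i_ur",
    "pa", "xs", "RyR_o_ss", "RyR_c_ss", "RyR_a_ss", "RyR_o_bc", "RyR_c_bc",
    "RyR_a_bc", "Ca_ss", "Ca_bc", "Ca_SRss", "Ca_SRbc", "Na_i", "K_i",
    "CaMK_trap", "Ca_TnC", "RU_perm", "XB_attached", "XB_distortion", "SL",
]

STATE_UNITS = [
    "mV", "1", "1", "1", "1", "1", "1", "1", "1", "1", "1",
    "1", "1", "1", "1", "1", "1", "1",
    "1", "uM", "uM", "mM", "mM", "mM", "mM",
    "1", "uM", "1", "1", "um", "um",
]

GATE_INDICES = (S_M, S_H, S_J, S_D, S_F, S_FCA, S_ATO, S_ITO, S_AUR, S_IUR,
                S_PA, S_XS, S_OSS, S_CSS, S_ASS, S_OBC, S_CBC, S_ABC)
CONC_INDICES = (S_CASS, S_CABC, S_CASRSS, S_CASRBC, S_NAI, S_KI)

# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------
P_CM = 0          # membrane capacitance (pF)
P_VSS = 1         # subspace volume (pL)
P_VBC = 2         # bulk cytosol volume (pL)
P_VSRSS = 3       # junctional SR volume (pL)
P_VSRBC = 4       # network SR volume (pL)
P_NAO = 5         # extracellular Na+ (mM)
P_KO = 6          # extracellular K+ (mM)
P_CAO = 7         # extracellular Ca2+ (mM)
P_GNA = 8         # nS/pF
P_GCAL = 9        # nS/pF
P_GTO = 10        # nS/pF
P_GKUR = 11       # nS/pF
P_GKR = 12        # nS/pF
P_GKS = 13        # nS/pF
P_GK1 = 14        # nS/pF
P_KNACA = 15      # NCX scale (A/F)
P_INAK = 16       # Na/K pump max (A/F)
P_GCAB = 17       # background Ca conductance (nS/pF)
P_GNAB = 18       # background Na conductance (nS/pF)
P_IPCA = 19       # sarcolemmal Ca pump max (A/F)
P_GKACH = 20      # IKACh scale (nS/pF at saturating ACh)
P_KCA = 21        # ICaL CDI half-inactivation Ca (uM)
P_ECAL = 22       # ICaL effective reversal (mV)
P_KRVH = 23       # IKr inactivation V-half (mV)
P_KRSL = 24       # IKr inactivation slope (mV)
P_INARS = 25      # INa recovery-from-inactivation time-constant scale
P_INASH = 26      # INa availability shift (mV, + = rightward)
P_RYR_TAUA_SS = 27   # ms
P_RYR_TAUI_SS = 28   # ms
P_RYR_TAUAD = 29     # ms
P_RYR_TAUA_BC = 30   # ms
P_RYR_TAUI_BC = 31   # ms
P_RYR_A1 = 32
P_RYR_A2 = 33
P_RYR_OK = 34     # activation-gate slope (uM)
P_RYR_CK = 35     # inactivation-gate slope (uM)
P_RYR_SRVH = 36   # SR-load gate V-half (mM)
P_RYR_SRK = 37    # SR-load gate slope (mM)
P_NURELSS = 38    # junctional release rate (1/ms)
P_NURELBC = 39    # network release rate (1/ms)
P_KSRLEAK = 40    # SR leak rate (1/ms per uM gradient)
P_SERCA_K4 = 41   # SERCA max rate (uM/ms)
P_SERCA_KMF = 42  # forward Km (uM)
P_SERCA_KMR = 43  # reverse Km (mM)
P_TAUDIFF = 44    # ss->bc Ca diffusion time constant (ms)
P_TAUSRDIFF = 45  # network->junctional SR transfer time constant (ms)
P_BSS = 46        # subspace fast buffer (uM)
P_KDBSS = 47      # its Kd (uM)
P_BBC = 48        # bulk fast buffer (uM)
P_KDBBC = 49      # its Kd (uM)
P_CSQN = 50       # calsequestrin (mM)
P_KMCSQN = 51     # its Kd (mM)
P_CAMK0 = 52      # CaMKII expression scale
P_ACAMK = 53      # trapping rate (1/ms)
P_BCAMK = 54      # untrapping rate (1/ms)
P_KMCAM = 55      # CaM half-activation Ca (uM)
P_CAMK_RYR = 56   # RyR sensitizing shift at full CaMKII activity (uM)
P_CAMK_SERCA = 57 # fractional Kmf reduction at full CaMKII activity
P_ACH = 58        # acetylcholine (uM)
P_STIMAMP = 59    # stimulus amplitude (A/F, negative = depolarizing)
P_STIMDUR = 60    # stimulus duration (ms)
P_GAMMA = 61      # RU cooperativity (-)
P_KD0 = 62        # Ta-pCa half-activation (pCa units at SL_ref)
P_KOFF = 63       # Ca-TnC / RU off-rate (1/s)
P_KBASIC = 64     # RU relaxation rate (1/s)
P_MUFP0 = 65      # XB attachment rate (1/s)
P_MUFP1 = 66      # permissive off-rate asymptote (-)
P_R0P = 67        # XB detachment rate, positive strain (1/s)
P_R0N = 68        # XB detachment rate, negative strain (1/s)
P_ALPHA = 69      # strain sensitivity of detachment (-)
P_AXB = 70        # tension upscaling (kPa-scale)
P_FXB = 71        # tension normalization (-)
P_TNCMAX = 72     # troponin C concentration (uM)
P_KDSCALE = 73    # Ta-pCa EC50 multiplier (kd intervention)
P_SL = 74         # sarcomere length (um)
P_SLREF = 75      # reference SL for kd0 (um)
P_LDA = 76        # length-dependent activation slope (pCa/um)
P_X0 = 77         # power-stroke distortion (um)
P_KOFFREF = 78    # reference off-rate tying kd0 to kon (1/s)
P_CLAMP_CASR = 79 # 1 = hold SR Ca fixed
P_CLAMP_CASS = 80 # 1 = hold subspace Ca fixed
P_TAUFCA = 81     # CDI gate time constant (ms)
P_RYR_OFF_SS = 82 # junctional RyR activation offset above adaptation (uM)
P_RYR_OFF_BC = 83 # non-junctional RyR activation offset (uM)
P_TAUF_SCALE = 84 # ICaL voltage-inactivation time-constant scale
P_CAMK_LEAK = 85  # fractional SR-leak increase at full CaMKII activity

NPARAM = 86

PARAM_NAMES = [
    "Cm", "Vss", "Vbc", "VSRss", "VSRbc", "Nao", "Ko", "Cao",
    "gNa", "gCaL", "gto", "gKur", "gKr", "gKs", "gK1", "kNaCa", "INaK_max",
    "gCab", "gNab", "IpCa_max", "gKACh", "KCa", "ECaL_rev",
    "kr_inact_vhalf", "kr_inact_slope", "ina_recovery_scale", "ina_avail_shift",
    "RyRtauactss", "RyRtauinactss", "RyRtauadapt", "RyRtauact", "RyRtauinact",
    "RyRa1ss", "RyRa2ss", "RyRo_k", "RyRc_k", "RyRsrca_vhalf", "RyRsrca_k",
    "nu_rel_ss", "nu_rel_bc", "kSRleak", "k4", "SERCAKmf", "SERCAKmr",
    "tau_diff", "tau_srdiff", "Bss", "KdBss", "Bbc", "KdBbc", "CSQN", "KmCSQN",
    "CaMK0", "alphaCaMK", "betaCaMK", "KmCaM", "camk_ryr_shift", "camk_serca",
    "ACh", "stim_amp", "stim_dur",
    "gamma", "kd0", "koff", "kbasic", "mufp0", "mufp1", "r0P", "r0N",
    "alpha", "alphaXB", "fXB", "TnCmax", "kd_scale", "SL", "SL_ref",
    "lda_slope", "x0_dist", "koff_ref", "clamp_casr", "clamp_cass", "tau_fca",
    "RyRo_off_ss", "RyRo_off_bc", "tau_f_scale", "camk_leak",
]

# currents / fluxes emitted by the kernel, in order
CURRENT_NAMES = [
    "INa", "ICaL", "Ito", "IKur", "IKr", "IKs", "IK1", "INaK", "INaCa",
    "ICab", "INab", "IpCa", "IKACh", "Itot",
    "Jrel_ss", "Jrel_bc", "Jup", "Jdiff", "JSRleak", "Ta",
]
CURRENT_UNITS = [
    "A/F", "A/F", "A/F", "A/F", "A/F", "A/F", "A/F", "A/F", "A/F",
    "A/F", "A/F", "A/F", "A/F", "A/F",
    "uM/ms", "uM/ms", "uM/ms", "uM/ms", "uM/ms", "kPa",
]
C_INA, C_ICAL, C_ITO, C_IKUR, C_IKR, C_IKS, C_IK1, C_INAK, C_INACA, \
    C_ICAB, C_INAB, C_IPCA, C_IKACH, C_ITOT, C_JRELSS, C_JRELBC, C_JUP, \
    C_JDIFF, C_JLEAK, C_TA = range(20)
NCURRENT = 20

assert len(STATE_NAMES) == len(STATE_UNITS) == NSTATE
assert len(PARAM_NAMES) == NPARAM
assert len(CURRENT_NAMES) == len(CURRENT_UNITS) == NCURRENT
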