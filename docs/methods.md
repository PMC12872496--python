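# Methods

## Scope and model structure

`atriomech` simulates a single human atrial cardiomyocyte with
bidirectional electromechanical coupling.  The state vector (31 entries)
comprises the membrane potential, the gating variables of nine sarcolemmal
currents, RyR release-unit gates in two compartments, free Ca²⁺ in a
sub-sarcolemmal subspace (*ss*) and the bulk cytosol (*bc*), free Ca²⁺ in
the junctional and network SR, intracellular Na⁺ and K⁺, a CaMKII
autonomous-activity state, the Ca²⁺–troponin-C (TnC) buffer, and the
regulatory-unit / cross-bridge states of the contraction model with the
sarcomere length SL (isometric: dSL/dt = 0 within a run; SL is varied only
as a static parameter).

The electrophysiology and Ca²⁺-handling equations follow the
Courtemanche/Nygren/Koivumäki family of human atrial formulations.  A
published update of that family specifies the deviations this package
implements: Kv4.3-like I_to kinetics (fast recovery), an I_Kr inactivation
slope of 13 mV ensuring complete inactivation at positive potentials,
junctional RyR inactivation recovery accelerated to 12 ms with adaptation
limits 0.505/0.427, the CDI half-saturation K_Ca = 0.68 µM, K⁺-conductance
rescalings (I_to ×1.5, I_Kr ×4 relative to the parent values), and the
recalibrated cross-bridge parameters (Table below).  The parent equations
themselves are not printed in that source, so the remainder of the model
is a reconstruction: current kinetics were taken from the standard
human-atrial formulations where available and calibrated so the baseline
cell reproduces the documented resting physiology (RMP ≈ −78 mV, resting
subspace Ca²⁺ ≈ 0.13 µM, Na_i ≈ 7 mM and SR Ca²⁺ ≈ 0.6 mM at slow
pacing) and the qualitative drug responses.  Quantities that depend on the
exact parent equations (absolute APD, EAD thresholds) should be read as
properties of this reconstruction, not of the original.

## Key parameters

All parameters live in a single `ParameterSet` (see
`atriomech/parameters.py` for every default with units).  The ones that
matter most:

| group | parameter (unit) | default | role |
|---|---|---|---|
| membrane | gNa, gCaL, gto, gKur, gKr, gKs, gK1 (nS/pF) | 7.8, 0.30, 0.05, 0.04, 0.096, 0.129, 0.07 | AP morphology: spike, sustained positive dome (~+5 mV), APD₉₀ ≈ 210 ms at BCL 2 s |
| exchangers | kNaCa (A/F scale), INaK_max (A/F) | 2000, 1.8 | Na⁺/Ca²⁺ homeostasis; INaK calibrated for Na_i ≈ 7 mM at BCL 2 s |
| ICaL | KCa (µM), tau_fca (ms) | 0.68, 10 | Ca²⁺-dependent inactivation (second order in Ca_ss) |
| IKr | inactivation V½/slope (mV) | +25 / 13 | complete inactivation at positive potentials; the voltage-sensitive activation speed makes plateau elevation recruit extra IKr |
| RyR | RyRo_k, RyRc_k (µM); RyRtauinactss (ms) | 0.03, 0.01; 12 | steep Ca-induced Ca release; fast junctional recovery |
| SERCA | k4 (µM/ms), Kmf (µM), Kmr (mM) | 0.45, 0.25, 1.3 | reversible uptake; equilibrium sets SR content ≈ 0.6 mM |
| CaMKII | CaMK0, α, β; effect gains | 0.05, 0.05/ms, 6.8e-4/ms | rate-dependent RyR sensitization, SERCA affinity gain, leak gain |
| contraction | γ, kd₀ (pCa), k_off, k_basic (s⁻¹), µ_fp0 (s⁻¹), µ_fp1, r₀P/r₀N (s⁻¹), α, αXB | 20, 6.29, 150, 150, 16.65, 0.65, 35/14, 25.184, 4e3 | calibrated solution-switching values |
| stimulus | amplitude (A/F), duration (ms) | −40, 1 | rectangular, suprathreshold in every condition |

The acetylcholine-gated current uses the dose dependence of the cited AF
model; its conductance scale (0.65) is a calibration of this package,
chosen so that the phase-3 protocol at [ACh] = 1 µM repolarizes fully and
elicits an I_Na-driven phase-3 EAD on the first post-pause beat.

## Contraction model

The contraction model is a mean-field regulatory-unit (RU) / distortion
cross-bridge model built for this package around the calibrated parameter
set.  Ca²⁺ binds TnC with off-rate k_off; permissive RUs retain Ca²⁺
(off-rate relaxing toward µ_fp1·k_off — the mechano-calcium feedback).
The permissive fraction relaxes at rate k_basic toward a cooperative
steady state in TnC occupancy; the nearest-neighbour cooperativity γ maps
to an effective occupancy exponent γ/4 (γ = 20 gives an apparent Ta–pCa
Hill coefficient near 2.5, matching atrial myofibrils).  Cross-bridges
attach from the permissive pool at µ_fp0 and detach at r₀P (positive
strain) or r₀N (negative strain) with strain sensitivity α; isometric
tension is proportional to the attached fraction, the mean distortion,
and the functional thin-filament density (TnC expression).  The Ta–pCa
EC50 equals kd₀ at the reference SL = 2.2 µm and shifts with
length-dependent activation (0.6 pCa/µm, so SL = 1.7 µm desensitizes by
0.3 pCa units) and with the `kd_scale` intervention.  The
solution-switching characterization (Ca²⁺ step 0.1 → 316 µM, then a
slack-restretch at saturating Ca²⁺) gives K_act = 42 s⁻¹, K_tr = 51 s⁻¹
and pCa₅₀ = 6.34 for the calibrated set.

## Interventions

All interventions are pure `ParameterSet → ParameterSet` transforms:

- **Pore block** (4-AP: IKur, IC50 8 µM, nH 1.3; AVE0118: IKur 3.126 µM /
  0.431 and I_to 5.45 **mM** / 0.385 — units carried explicitly).
- **cAF remodeling**, ordered groups: electrical (gNa ×0.9, gCaL ×0.5,
  gto ×0.2, gKs ×2, gK1 ×2, kNaCa ×1.4, and gKur ×0.5 — the IKur
  reduction is configurable because it varies across patients, and the
  "reversal" variant (case 2) restores it; case 1 skips the
  TnC/contraction factors), CaMKII (expression ×1.4, activation ×2,
  inactivation ×0.5), myofilament (k_off ×0.5, γ ×0.7, TnC ×0.75, both
  cross-bridge rates ×0.5), SR Ca²⁺ handling (RyR slopes ×0.5, leak
  ×1.25, k4 ×0.8, Kmf ×1.15).  Percentage conventions: "↓X%" = ×(1−X/100),
  "↑X%" (X<100) = ×(1+X/100), "↑200%" = ×2.
- **Phase-3 substrate**: I_Na recovery-from-inactivation time constants
  ×10⁻³ and availability shifted +15 mV; I_KACh activation; GCaL ×0.8 and
  GKur ×3.
- **Backward-coupling EAD substrate**: the SR-load-gate slope of RyR
  release reduced ×0.1.
- **Current clamp**: ICaL or IKr replaced by a recorded steady-state-beat
  waveform tiled at the pacing period, entering both the voltage equation
  and (for ICaL) the Ca²⁺ influx bookkeeping.  Clamp templates are
  recorded at BCL = 2 s (the basal rate used for the clamp dissection);
  at BCL = 1 s this reconstruction shows dome alternans, which breaks the
  single-beat-template assumption.

## Numerical choices

LSODA (stiff-capable, adaptive) with rtol 10⁻⁶, per-state absolute
tolerances 10⁻⁸ × characteristic magnitude, max step 1 ms, integrated in
segments split at stimulus edges so pulses are never skipped.  Output is
sampled on a fixed grid (0.1 ms default; protocols record at 0.25 ms and
conditioning phases record endpoints only).  Integration is deterministic
for fixed options; APD changes by <0.5% under 10× tolerance tightening.
Stored initial states per condition (SR, AF, case 1, case 2) were produced
by pacing 500 beats at BCL 1 s from a common resting guess and ship with
the package (regenerable via `scripts/make_initial_states.py`); slow ionic
drift (Na_i) continues over hundreds of beats, so protocols re-condition
at their own BCL before analysis.

Beat classification: APD at 90% repolarization (configurable); EAD = a
positive dV/dt excursion ≥0.05 V/s sustained ≥2 ms starting later than
80 ms after the upstroke (excluding the normal notch–dome sequence) and
before full repolarization; A-EAD = EADs on strictly alternating beats;
RF = Vm never reaches −60 mV before the next stimulus; DAD = a diastolic
depolarizing bump with ≥1 mV prominence (monotone diastolic drift is not
counted); precedence RF > EAD/A-EAD > DAD.  Ta relaxation duration is
measured from the Ta peak to 90% decay.

## What passing tests do and do not show

The unit/property suite (gating bounds, charge bookkeeping, Ca²⁺ mass
audit, Hill identities, clamp self-identity, classifier exactness on
constructed waveforms, solver convergence) validates the machinery.  The
sign-pattern suite validates emergent physiology, and several items are
faithfully implemented but currently not reproduced by this
reconstruction; they are left failing rather than loosened:

- δTa_max under K⁺-channel block is positive at BCL ≤ 1 s in SR but
  slightly negative at BCL 2 s, and mostly negative in AF: with the dome
  near +5 mV, plateau elevation loses ICaL driving force, whereas the
  original gains ICaL (positive inotropy at all rates).
- AVE0118 and the AF condition show drug-induced APD shortening at slow
  rates instead of prolongation: in this reconstruction IKr recruitment
  outweighs the blocked current in most regimes.  The 4-AP SR pattern
  (shortening at BCL 2 s/1 s, prolongation at 0.5 s) is reproduced.
- AF diastolic CaT is below SR instead of elevated; the CaMKII-leak
  pathway can raise it only at the cost of the (preserved) SR content.
- The phase-2 EAD substrates (GCaL ×3; GCaL ×4 + GKur ×0.8) are
  multistable: long EAD-carrying beats alternate with normal beats in an
  irregular (period-4/chaotic) pattern, so the strict alternate-beat
  A-EAD label and the printed Ca²⁺/tension values of those cells
  (relaxation duration 1.1 s, diastolic Ca 0.48 µM, resting Ca 0.5 µM)
  are only approximated.
- Myofilament desensitization (kd +50%, SL 1.7 µm) does not abolish the
  AF case-4 EADs here; the TnC buffer in this model equilibrates too fast
  to provide the slow Ca²⁺-release pathway that effect relies on.

The DAD protocol (first-post-pause-interval DADs, eliminated by clamping
SR Ca²⁺, decimated by 4-AP), the clamp dissection (IKr clamp converts
4-AP shortening into prolongation; ICaL clamp abolishes the AF response),
the phase-3 EAD (take-off −48 mV, eliminated by 4-AP, requiring the I_Na
reactivation mods), and the AF electrical/contractile phenotype (short
APD, hyperpolarized RMP, depressed Ta, case-1/case-2 contrasts) are
reproduced.

## Known limitations

Single cell only; no tissue coupling, no state/use-dependent drug
binding, no β-adrenergic signalling, no stochastic RyR gating or spatial
Ca²⁺ sparks (DAD amplitudes are therefore small and common-pool-limited).
The parent-model reconstruction is calibrated, not verbatim; absolute
APDs, EAD thresholds and loading levels carry that uncertainty.  At
BCL = 1 s the SR baseline shows dome alternans, and steady-state APD is
not strictly monotone in BCL around that rate.
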