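# atriomech

An electromechanically coupled human atrial cardiomyocyte simulator for
studying atrial-selective K⁺-channel blockade (4-aminopyridine, AVE0118),
chronic atrial-fibrillation (cAF) remodeling, and afterdepolarization
arrhythmia mechanisms — phase-2 and phase-3 early afterdepolarizations
(EADs) and delayed afterdepolarizations (DADs) — in a single cell.

It is aimed at cardiac electrophysiology modellers who want a scriptable,
deterministic cell model with the full experimental harness around it:
pore-block pharmacology, incremental AF remodeling, conductance-scan
vulnerability maps, rapid-pace/pause protocols, current-clamp dissection,
and myofilament-sensitivity sweeps.

## The model

The cell couples four subsystems in one stiff ODE system (31 states):

- **Electrophysiology** — a Courtemanche/Koivumäki-family human atrial
  membrane model: I_Na, I_CaL (with voltage- and Ca²⁺-dependent
  inactivation, CDI half-saturation K_Ca = 0.68 µM), Kv4.3-kinetics I_to,
  sustained I_Kur, I_Kr (inactivation slope 13 mV, complete at positive
  potentials), I_Ks, I_K1, Na⁺/K⁺ pump, Na⁺/Ca²⁺ exchange, background and
  pump Ca²⁺ currents, and the acetylcholine-gated I_KACh.
- **Ca²⁺ handling** — two cytosolic compartments (subspace *ss*, bulk
  *bc*), each facing its own SR pool, with RyR release units carrying
  Ca²⁺-dependent activation/inactivation gates, slow adaptation
  (a₁ = 0.505, a₂ = 0.427; junctional inactivation recovery 12 ms), an
  SR-load gate, a reversible SERCA pump, an SR leak, and a CaMKII activity
  state that modulates RyR sensitivity, SERCA affinity and leak.
- **Contraction** — a mean-field regulatory-unit / cross-bridge model with
  cooperativity γ = 20, Ta–pCa half-activation kd₀ = 6.29 (pCa),
  RU kinetics k_off = k_basic = 150 s⁻¹, cross-bridge attachment
  µ_fp0 = 16.65 s⁻¹ and strain-dependent detachment r₀P/r₀N = 35/14 s⁻¹,
  with length-dependent activation in the sarcomere length SL.
- **Mechano-calcium feedback** — the Ca²⁺–troponin-C buffer is an explicit
  state in the bulk Ca²⁺ balance, so myofilament (de)sensitization feeds
  back on the Ca²⁺ transient and hence the action potential.

Drugs act by Hill pore block: a conductance is scaled by
1 − cⁿᴴ/(cⁿᴴ + IC50ⁿᴴ). cAF remodeling is applied as ordered
multiplicative groups (electrical → CaMKII → myofilament → SR Ca²⁺
handling), with the no-TnC-remodeling (case 1) and IKur-reversal (case 2)
variants.

## Worked example

```python
import atriomech as am
from atriomech.model import CellModel, SolverOptions
from atriomech import biomarkers as bm

model = CellModel(am.condition_parameters("SR"),
                  solver=SolverOptions(dt_out=0.25))
_, y = model.pace(am.initial_state("SR"), bcl=2000.0, n_beats=30,
                  record_last=1, with_currents=False)
trace, _ = model.pace(y, bcl=2000.0, n_beats=2)
beat = bm.analyze_beats(trace, bcl=2000.0)[-1]
print(f"APD90 {beat.apd:.1f} ms, RMP {beat.rmp:.1f} mV, "
      f"CaT {beat.ca_bc_dia:.3f}-{beat.ca_bc_sys:.3f} uM, "
      f"Ta {beat.ta_max:.1f} kPa")

blocked = am.apply_drug(model.params, am.drug_4ap(5.0))
print(f"4-AP blocks {am.hill_block_fraction(5.0, 8.0, 1.3):.1%} of IKur")
```

prints (sinus rhythm, basal rate BCL = 2 s):

```
APD90 209.6 ms, RMP -78.5 mV, CaT 0.132-0.505 uM, Ta 14.1 kPa
4-AP blocks 35.2% of IKur
```

Re-pacing with the blocked parameter set shortens APD90 by ~5 ms at this
rate (the paradoxical IKur-block shortening: the elevated plateau recruits
extra I_Kr), while at BCL = 0.5 s the same drug prolongs the AP.  The
solution-switching characterization of the contraction model
(`atriomech.contraction.calibrate_contraction`) reports
K_act = 42 s⁻¹, K_tr = 51 s⁻¹ and a Ta–pCa half-activation at pCa 6.34.

A command-line interface mirrors the protocol library:

```
atriomech simulate run.yaml out/          # YAML-configured pacing run
atriomech rate-scan ... / conductance-scan ... / pace-pause ...
atriomech phase3 ... / calibrate-contraction ... / record-clamp ...
```

Each run writes `beats.csv`, `summary.json`, the trace, and a replay
manifest.  Shipped intervention files live in `src/atriomech/data/`
(`4AP_5uM.yaml`, `AVE0118_6uM.yaml`, `af_full.yaml`, …).

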