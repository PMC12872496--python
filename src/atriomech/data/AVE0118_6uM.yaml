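# AVE0118: nonselective IKur + Ito pore block (note Ito IC50 in mM)
name: AVE0118
concentration: 6.0
units: uM
targets:
  - channel: IKur
    ic50: 3.126
    n_h: 0.431
    units: uM
  - channel: Ito
    ic50: 5.45
    n_h: 0.385
    units: mM
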