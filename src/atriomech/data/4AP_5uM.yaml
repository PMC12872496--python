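# 4-aminopyridine, low dose: IKur-selective pore block
name: 4-AP
concentration: 5.0
units: uM
targets:
  - channel: IKur
    ic50: 8.0
    n_h: 1.3
    units: uM
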