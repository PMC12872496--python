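# AF remodeling with the IKur reduction reversed
kind: af_remodeling
case2_ikur_reversed: true
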