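# AF remodeling without contractile/TnC remodeling
kind: af_remodeling
case1_no_tnc_remodeling: true
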