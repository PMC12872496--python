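# chronic-AF remodeling, full (electrical + CaMKII + MCF + SR Ca handling)
kind: af_remodeling
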