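CCL2
CCL3
CCL4
CCL5
CCL8
CCL18
CCL19
CCL21
CXCL9
CXCL10
CXCL11
CXCL13
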