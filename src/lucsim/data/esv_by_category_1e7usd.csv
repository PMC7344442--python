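category,year,esv_1e7usd
regulating,1995,2296.56
regulating,2030,3224.16
provisioning,2030,-29.83
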