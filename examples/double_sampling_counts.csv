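n00,n01,n10,n11,t0,t1
840,40,3,97,1375,225
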