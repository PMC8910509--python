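class,pi
CL,0.67
WO,0.13
GL,0.1
WA,0.12
CO,0.96
UL,0.05
WL,0.15
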