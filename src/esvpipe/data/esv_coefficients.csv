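class,function,yuan_per_hm2
CL,FP,1793.88
CL,RM,179.39
CL,GR,896.94
CL,CR,1596.55
CL,WS,1076.33
CL,WD,2941.96
CL,SFR,2619.06
CL,BD,1273.65
CL,EC,17.94
WO,FP,179.39
WO,RM,4664.08
WO,GR,6278.58
WO,CR,4843.47
WO,WS,5740.41
WO,WD,2349.98
WO,SFR,6996.13
WO,BD,5848.04
WO,EC,2296.16
GL,FP,538.16
GL,RM,89.69
GL,GR,1435.10
GL,CR,1614.49
GL,WS,1435.10
GL,WD,2349.98
GL,SFR,3498.06
GL,BD,1955.33
GL,EC,71.76
WA,FP,179.39
WA,RM,17.94
WA,GR,0.00
WA,CR,825.18
WA,WS,36559.25
WA,WD,32612.71
WA,SFR,17.94
WA,BD,4466.76
WA,EC,7785.43
CO,FP,0.00
CO,RM,0.00
CO,GR,0.00
CO,CR,0.00
CO,WS,0.00
CO,WD,0.00
CO,SFR,0.00
CO,BD,0.00
CO,EC,0.00
UL,FP,17.94
UL,RM,0.00
UL,GR,0.00
UL,CR,0.00
UL,WS,53.82
UL,WD,17.94
UL,SFR,35.88
UL,BD,609.92
UL,EC,17.94
WL,FP,538.16
WL,RM,125.57
WL,GR,3228.98
WL,CR,30675.33
WL,WS,27805.12
WL,WD,32612.71
WL,SFR,3067.53
WL,BD,4484.70
WL,EC,9956.03
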