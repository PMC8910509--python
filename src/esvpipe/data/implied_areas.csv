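year,class,reference_function,area_hm2
2000,CL,WD,2750547.3
2000,GL,SFR,91479.3
2000,WA,WS,731497.5
2000,WL,WD,89106.4
2000,WO,SFR,2218655.2
2005,CL,WD,2710098.0
2005,GL,SFR,90621.7
2005,WA,WS,768095.6
2005,WL,WD,86285.4
2005,WO,SFR,2216368.2
2010,CL,WD,2695821.8
2010,GL,SFR,86905.3
2010,WA,WS,769189.7
2010,WL,WD,92509.9
2010,WO,SFR,2214938.8
2018,CL,WD,2588410.4
2018,GL,SFR,84904.2
2018,WA,WS,765606.5
2018,WL,WD,114311.3
2018,WO,SFR,2220370.4
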