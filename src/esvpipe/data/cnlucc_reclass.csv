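raw_code,class_code
11,1
12,1
21,2
22,2
23,2
24,2
31,3
32,3
33,3
41,4
42,4
43,4
44,4
45,7
46,7
51,5
52,5
53,5
61,6
62,6
63,6
64,7
65,6
66,6
67,6
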