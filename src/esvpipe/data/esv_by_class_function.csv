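year,class,function,billion_yuan
2000,CL,BD,3.503
2000,CL,CR,4.392
2000,CL,EC,0.049
2000,CL,FP,4.934
2000,CL,GR,2.467
2000,CL,RM,0.493
2000,CL,SFR,7.204
2000,CL,WD,8.092
2000,CL,WS,2.961
2000,GL,BD,0.179
2000,GL,CR,0.148
2000,GL,EC,0.007
2000,GL,FP,0.049
2000,GL,GR,0.131
2000,GL,RM,0.008
2000,GL,SFR,0.320
2000,GL,WD,0.215
2000,GL,WS,0.131
2000,WA,BD,3.267
2000,WA,CR,0.604
2000,WA,EC,5.695
2000,WA,FP,0.131
2000,WA,GR,0.000
2000,WA,RM,0.013
2000,WA,SFR,0.013
2000,WA,WD,23.856
2000,WA,WS,26.743
2000,WL,BD,0.400
2000,WL,CR,2.733
2000,WL,EC,0.887
2000,WL,FP,0.048
2000,WL,GR,0.288
2000,WL,RM,0.011
2000,WL,SFR,0.273
2000,WL,WD,2.906
2000,WL,WS,2.477
2000,WO,BD,12.975
2000,WO,CR,10.746
2000,WO,EC,5.095
2000,WO,FP,0.398
2000,WO,GR,13.930
2000,WO,RM,10.348
2000,WO,SFR,15.522
2000,WO,WD,5.214
2000,WO,WS,12.736
2005,CL,BD,3.452
2005,CL,CR,4.327
2005,CL,EC,0.049
2005,CL,FP,4.861
2005,CL,GR,2.431
2005,CL,RM,0.486
2005,CL,SFR,7.098
2005,CL,WD,7.973
2005,CL,WS,2.917
2005,GL,BD,0.177
2005,GL,CR,0.146
2005,GL,EC,0.006
2005,GL,FP,0.049
2005,GL,GR,0.130
2005,GL,RM,0.008
2005,GL,SFR,0.317
2005,GL,WD,0.213
2005,GL,WS,0.130
2005,WA,BD,3.431
2005,WA,CR,0.634
2005,WA,EC,5.980
2005,WA,FP,0.138
2005,WA,GR,0.000
2005,WA,RM,0.014
2005,WA,SFR,0.014
2005,WA,WD,25.050
2005,WA,WS,28.081
2005,WL,BD,0.387
2005,WL,CR,2.647
2005,WL,EC,0.859
2005,WL,FP,0.046
2005,WL,GR,0.279
2005,WL,RM,0.011
2005,WL,SFR,0.265
2005,WL,WD,2.814
2005,WL,WS,2.400
2005,WO,BD,12.962
2005,WO,CR,10.735
2005,WO,EC,5.089
2005,WO,FP,0.398
2005,WO,GR,13.916
2005,WO,RM,10.337
2005,WO,SFR,15.506
2005,WO,WD,5.208
2005,WO,WS,12.723
2010,CL,BD,3.434
2010,CL,CR,4.304
2010,CL,EC,0.048
2010,CL,FP,4.836
2010,CL,GR,2.418
2010,CL,RM,0.484
2010,CL,SFR,7.060
2010,CL,WD,7.931
2010,CL,WS,2.902
2010,GL,BD,0.170
2010,GL,CR,0.140
2010,GL,EC,0.006
2010,GL,FP,0.047
2010,GL,GR,0.125
2010,GL,RM,0.008
2010,GL,SFR,0.304
2010,GL,WD,0.204
2010,GL,WS,0.125
2010,WA,BD,3.436
2010,WA,CR,0.635
2010,WA,EC,5.989
2010,WA,FP,0.138
2010,WA,GR,0.000
2010,WA,RM,0.014
2010,WA,SFR,0.014
2010,WA,WD,25.086
2010,WA,WS,28.121
2010,WL,BD,0.415
2010,WL,CR,2.837
2010,WL,EC,0.921
2010,WL,FP,0.050
2010,WL,GR,0.299
2010,WL,RM,0.012
2010,WL,SFR,0.284
2010,WL,WD,3.017
2010,WL,WS,2.572
2010,WO,BD,12.953
2010,WO,CR,10.728
2010,WO,EC,5.086
2010,WO,FP,0.397
2010,WO,GR,13.907
2010,WO,RM,10.331
2010,WO,SFR,15.496
2010,WO,WD,5.205
2010,WO,WS,12.715
2018,CL,BD,3.297
2018,CL,CR,4.133
2018,CL,EC,0.046
2018,CL,FP,4.643
2018,CL,GR,2.322
2018,CL,RM,0.464
2018,CL,SFR,6.779
2018,CL,WD,7.615
2018,CL,WS,2.786
2018,GL,BD,0.166
2018,GL,CR,0.137
2018,GL,EC,0.006
2018,GL,FP,0.046
2018,GL,GR,0.122
2018,GL,RM,0.008
2018,GL,SFR,0.297
2018,GL,WD,0.200
2018,GL,WS,0.122
2018,WA,BD,3.420
2018,WA,CR,0.632
2018,WA,EC,5.961
2018,WA,FP,0.137
2018,WA,GR,0.000
2018,WA,RM,0.014
2018,WA,SFR,0.014
2018,WA,WD,24.968
2018,WA,WS,27.990
2018,WL,BD,0.513
2018,WL,CR,3.506
2018,WL,EC,1.138
2018,WL,FP,0.062
2018,WL,GR,0.369
2018,WL,RM,0.014
2018,WL,SFR,0.351
2018,WL,WD,3.728
2018,WL,WS,3.178
2018,WO,BD,12.984
2018,WO,CR,10.754
2018,WO,EC,5.098
2018,WO,FP,0.398
2018,WO,GR,13.940
2018,WO,RM,10.356
2018,WO,SFR,15.534
2018,WO,WD,5.218
2018,WO,WS,12.745
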