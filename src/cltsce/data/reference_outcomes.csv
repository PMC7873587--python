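arm,region,n_households,n_people,delta_od,delta_ownership,households_stopping_od,households_gaining_ownership
All CLTS interventions,All regions,12217,58248,-0.13,0.09,1605,1086
HEW CLTS,Ethiopia,1624,9829,-0.10,0.04,168,70
Teacher CLTS,Ethiopia,3838,21216,-0.11,0.06,421,229
HEW CLTS,Oromia,651,4013,-0.48,0.43,310,282
Teacher CLTS,Oromia,1586,9153,-0.56,0.53,895,841
HEW CLTS,SNNP,973,5816,0.15,-0.22,-141,-211
Teacher CLTS,SNNP,2252,12063,0.21,-0.27,-474,-612
NGO CLTS,Ghana,3443,14263,-0.09,0.09,298,305
CLTS + NL Training,Ghana,3312,12940,-0.22,0.15,718,481
NGO CLTS,Central,1463,4670,-0.06,0.07,89,102
CLTS + NL Training,Central,1495,5041,-0.16,0.04,237,58
NGO CLTS,Upper West,808,5208,-0.13,0.08,108,64
CLTS + NL Training,Upper West,540,3474,-0.53,0.33,287,180
NGO CLTS,Volta,1172,4385,-0.09,0.12,100,139
CLTS + NL Training,Volta,1277,4425,-0.15,0.19,195,243
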