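arm,region,total_usd
All CLTS interventions,All regions,576061
HEW CLTS,Ethiopia,36739
Teacher CLTS,Ethiopia,63348
HEW CLTS,Oromia,20573
Teacher CLTS,Oromia,30239
HEW CLTS,SNNP,16166
Teacher CLTS,SNNP,33110
NGO CLTS,Ghana,131783
CLTS + NL Training,Ghana,344190
NGO CLTS,Central,45800
CLTS + NL Training,Central,110754
NGO CLTS,Upper West,33803
CLTS + NL Training,Upper West,106458
NGO CLTS,Volta,52180
CLTS + NL Training,Volta,126978
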