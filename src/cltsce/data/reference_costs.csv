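arm,region,category,amount_usd,hours,rate_usd_per_hour
All CLTS interventions,All regions,management,79660,,
All CLTS interventions,All regions,training,210850,,
All CLTS interventions,All regions,facilitation,169595,,
All CLTS interventions,All regions,local_actor_time,12583,,
All CLTS interventions,All regions,community_time,21529,,
All CLTS interventions,All regions,hired_labor,21942,,
All CLTS interventions,All regions,hardware,59901,,
HEW CLTS,Ethiopia,management,8690,,
HEW CLTS,Ethiopia,training,17617,,
HEW CLTS,Ethiopia,facilitation,4891,,
HEW CLTS,Ethiopia,local_actor_time,1926,,
HEW CLTS,Ethiopia,community_time,2546,,
HEW CLTS,Ethiopia,hired_labor,0,,
HEW CLTS,Ethiopia,hardware,1070,,
Teacher CLTS,Ethiopia,management,14867,,
Teacher CLTS,Ethiopia,training,33229,,
Teacher CLTS,Ethiopia,facilitation,6225,,
Teacher CLTS,Ethiopia,local_actor_time,3863,,
Teacher CLTS,Ethiopia,community_time,4151,,
Teacher CLTS,Ethiopia,hired_labor,0,,
Teacher CLTS,Ethiopia,hardware,1013,,
HEW CLTS,Oromia,management,4345,,
HEW CLTS,Oromia,training,9979,,
HEW CLTS,Oromia,facilitation,2820,,
HEW CLTS,Oromia,local_actor_time,1084,,
HEW CLTS,Oromia,community_time,1435,,
HEW CLTS,Oromia,hired_labor,0,,
HEW CLTS,Oromia,hardware,911,,
Teacher CLTS,Oromia,management,7434,,
Teacher CLTS,Oromia,training,17279,,
Teacher CLTS,Oromia,facilitation,1118,,
Teacher CLTS,Oromia,local_actor_time,1889,,
Teacher CLTS,Oromia,community_time,1886,,
Teacher CLTS,Oromia,hired_labor,0,,
Teacher CLTS,Oromia,hardware,633,,
HEW CLTS,SNNP,management,4345,,
HEW CLTS,SNNP,training,7638,,
HEW CLTS,SNNP,facilitation,2071,,
HEW CLTS,SNNP,local_actor_time,842,,
HEW CLTS,SNNP,community_time,1110,,
HEW CLTS,SNNP,hired_labor,0,,
HEW CLTS,SNNP,hardware,159,,
Teacher CLTS,SNNP,management,7434,,
Teacher CLTS,SNNP,training,15951,,
Teacher CLTS,SNNP,facilitation,5107,,
Teacher CLTS,SNNP,local_actor_time,1974,,
Teacher CLTS,SNNP,community_time,2265,,
Teacher CLTS,SNNP,hired_labor,0,,
Teacher CLTS,SNNP,hardware,380,,
NGO CLTS,Ghana,management,26958,,
NGO CLTS,Ghana,training,4076,,
NGO CLTS,Ghana,facilitation,73428,,
NGO CLTS,Ghana,local_actor_time,1242,,
NGO CLTS,Ghana,community_time,5847,,
NGO CLTS,Ghana,hired_labor,7132,,
NGO CLTS,Ghana,hardware,13101,,
CLTS + NL Training,Ghana,management,29145,,
CLTS + NL Training,Ghana,training,155928,,
CLTS + NL Training,Ghana,facilitation,85052,,
CLTS + NL Training,Ghana,local_actor_time,5552,,
CLTS + NL Training,Ghana,community_time,8985,,
CLTS + NL Training,Ghana,hired_labor,14810,,
CLTS + NL Training,Ghana,hardware,44718,,
NGO CLTS,Central,management,8797,,
NGO CLTS,Central,training,1199,,
NGO CLTS,Central,facilitation,28573,,
NGO CLTS,Central,local_actor_time,314,,
NGO CLTS,Central,community_time,1502,,
NGO CLTS,Central,hired_labor,1096,,
NGO CLTS,Central,hardware,4319,,
CLTS + NL Training,Central,management,9525,,
CLTS + NL Training,Central,training,38427,,
CLTS + NL Training,Central,facilitation,32281,,
CLTS + NL Training,Central,local_actor_time,1525,,
CLTS + NL Training,Central,community_time,3661,,
CLTS + NL Training,Central,hired_labor,1835,,
CLTS + NL Training,Central,hardware,23501,,
NGO CLTS,Upper West,management,9308,,
NGO CLTS,Upper West,training,928,,
NGO CLTS,Upper West,facilitation,18270,,
NGO CLTS,Upper West,local_actor_time,372,,
NGO CLTS,Upper West,community_time,1452,,
NGO CLTS,Upper West,hired_labor,2191,,
NGO CLTS,Upper West,hardware,1282,,
CLTS + NL Training,Upper West,management,10037,,
CLTS + NL Training,Upper West,training,62874,,
CLTS + NL Training,Upper West,facilitation,23209,,
CLTS + NL Training,Upper West,local_actor_time,1998,,
CLTS + NL Training,Upper West,community_time,2028,,
CLTS + NL Training,Upper West,hired_labor,3859,,
CLTS + NL Training,Upper West,hardware,2452,,
NGO CLTS,Volta,management,8853,,
NGO CLTS,Volta,training,1949,,
NGO CLTS,Volta,facilitation,26584,,
NGO CLTS,Volta,local_actor_time,555,,
NGO CLTS,Volta,community_time,2893,,
NGO CLTS,Volta,hired_labor,3845,,
NGO CLTS,Volta,hardware,7501,,
CLTS + NL Training,Volta,management,9582,,
CLTS + NL Training,Volta,training,54627,,
CLTS + NL Training,Volta,facilitation,29562,,
CLTS + NL Training,Volta,local_actor_time,2030,,
CLTS + NL Training,Volta,community_time,3297,,
CLTS + NL Training,Volta,hired_labor,9115,,
CLTS + NL Training,Volta,hardware,18765,,
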