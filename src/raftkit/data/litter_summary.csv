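beach_id,group,litter_per_m2,gen_HPl,gen_OPl,gen_Foam,gen_NPl,gen_SumPl,gen_S,gen_F,gen_HH,gen_NA,raft_total,raft_HPl,raft_OPl,raft_Foam,raft_NPl,raft_SumPl,raft_S,raft_F,raft_HH,raft_NA
andrin,Mix,0.31,23,5,18,55,45,0,0,0,100,5,40,40,20,0,100,0,20,60,20
sta_marina,Mix,0.22,44,6,31,19,81,6,0,13,81,2,50,50,0,0,100,0,0,50,50
barayo,Mix,0.17,58,17,0,25,75,0,8,8,83,5,40,20,40,0,100,0,40,0,60
xago,OPl_dominant,2.68,18,74,8,0,100,34,24,0,41,4,75,0,25,0,100,0,75,0,25
penarronda,OPl_dominant,1.25,43,54,2,0,100,3,42,0,54,20,75,10,10,5,95,0,25,10,65
bayas,OPl_dominant,1.15,41,45,10,5,95,8,4,2,86,7,71,14,14,0,100,0,33,0,67
navia,OPl_dominant,4.25,26,68,1,6,94,17,5,6,72,1,100,0,0,0,100,0,100,0,0
salinas,HPl_dominant,1.50,80,11,7,2,98,13,3,3,81,25,48,20,20,12,88,0,4,12,84
xivares,HPl_dominant,5.00,89,3,8,1,99,18,2,0,80,4,75,25,0,0,100,0,25,25,50
banugues,HPl_dominant,1.03,72,14,12,3,97,9,7,5,78,2,100,0,0,0,100,0,0,0,100
rodiles,HPl_dominant,0.47,71,21,6,3,97,9,6,3,82,8,88,0,13,0,100,0,75,0,25
poo,HPl_dominant,0.50,78,11,8,3,97,19,3,6,72,1,100,0,0,0,100,0,0,0,100
silencio,,,,,,,,,,,,4,100,0,0,0,100,0,25,0,75
nieva,,,,,,,,,,,,1,100,0,0,0,100,0,0,0,100
figueras,,,,,,,,,,,,5,0,80,0,20,80,0,0,20,80
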