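item_id,beach_id,object_type,material,goose_barnacles,acorn_barnacles,bryo_hydro_colonies,decapods,molluscs,polychaetes
andrin_01,andrin,Netfloats,HPl,1,6,3,1,1,5
andrin_02,andrin,Cosmetics container,HPl,1,5,3,1,1,5
andrin_03,andrin,Shoes,OPl,11,3,3,0,1,32
andrin_04,andrin,Sandals,OPl,11,3,3,0,1,31
andrin_05,andrin,Unknown objects,Foam,61,0,0,0,1,0
sta_marina_01,sta_marina,Sandals,HPl,1,5,3,1,1,5
sta_marina_02,sta_marina,Unknown objects,OPl,11,3,3,0,1,31
barayo_01,barayo,Netfloats,HPl,1,5,3,1,1,5
barayo_02,barayo,Ropes,HPl,1,5,3,1,1,5
barayo_03,barayo,Fragments,OPl,11,3,3,0,1,31
barayo_04,barayo,Bottles,Foam,61,0,0,0,1,0
barayo_05,barayo,Unknown objects,Foam,61,0,0,0,1,0
xago_01,xago,Netfloats,HPl,1,5,3,1,1,5
xago_02,xago,Ropes,HPl,1,5,3,1,1,5
xago_03,xago,Buoys,HPl,1,5,3,1,1,5
xago_04,xago,Bottles,Foam,61,0,0,0,1,0
penarronda_01,penarronda,Netfloats,HPl,1,5,3,1,1,5
penarronda_02,penarronda,Ropes,HPl,1,5,3,1,1,5
penarronda_03,penarronda,Buoys,HPl,1,5,3,1,1,5
penarronda_04,penarronda,Netfloats,HPl,1,5,3,1,1,5
penarronda_05,penarronda,Ropes,HPl,1,5,3,1,1,4
penarronda_06,penarronda,Shoes,HPl,1,5,3,1,1,4
penarronda_07,penarronda,Sandals,HPl,1,5,3,1,1,4
penarronda_08,penarronda,Unknown objects,HPl,1,5,3,1,1,4
penarronda_09,penarronda,Fragments,HPl,1,5,3,0,1,4
penarronda_10,penarronda,Bottles,HPl,1,5,3,0,1,4
penarronda_11,penarronda,Unknown objects,HPl,1,5,3,0,1,4
penarronda_12,penarronda,Fragments,HPl,1,5,3,0,1,4
penarronda_13,penarronda,Bottles,HPl,1,5,3,0,1,4
penarronda_14,penarronda,Unknown objects,HPl,1,5,3,0,1,4
penarronda_15,penarronda,Fragments,HPl,1,5,3,0,1,4
penarronda_16,penarronda,Bottles,OPl,11,3,3,0,1,31
penarronda_17,penarronda,Unknown objects,OPl,11,3,3,0,1,31
penarronda_18,penarronda,Fragments,Foam,61,0,0,0,1,0
penarronda_19,penarronda,Bottles,Foam,61,0,0,0,1,0
penarronda_20,penarronda,Unknown objects,NPl,156,4,0,0,2,0
bayas_01,bayas,Netfloats,HPl,1,5,3,0,1,4
bayas_02,bayas,Ropes,HPl,1,5,3,0,1,4
bayas_03,bayas,Fragments,HPl,1,5,3,0,1,4
bayas_04,bayas,Bottles,HPl,1,5,2,0,1,4
bayas_05,bayas,Unknown objects,HPl,1,5,2,0,1,4
bayas_06,bayas,Fragments,OPl,11,2,2,0,1,31
bayas_07,bayas,Bottles,Foam,61,0,0,0,1,0
navia_01,navia,Netfloats,HPl,1,5,2,0,1,4
salinas_01,salinas,Netfloats,HPl,1,5,2,0,1,4
salinas_02,salinas,Cosmetics container,HPl,1,5,2,0,1,4
salinas_03,salinas,Shoes,HPl,1,5,2,0,1,4
salinas_04,salinas,Sandals,HPl,1,5,2,0,0,4
salinas_05,salinas,Unknown objects,HPl,1,5,2,0,0,4
salinas_06,salinas,Fragments,HPl,1,5,2,0,0,4
salinas_07,salinas,Bottles,HPl,1,5,2,0,0,4
salinas_08,salinas,Unknown objects,HPl,1,5,2,0,0,4
salinas_09,salinas,Fragments,HPl,1,5,2,0,0,4
salinas_10,salinas,Bottles,HPl,1,5,2,0,0,4
salinas_11,salinas,Unknown objects,HPl,1,5,2,0,0,4
salinas_12,salinas,Fragments,HPl,1,5,2,0,0,4
salinas_13,salinas,Bottles,OPl,11,2,2,0,1,31
salinas_14,salinas,Unknown objects,OPl,11,2,2,0,1,31
salinas_15,salinas,Fragments,OPl,11,2,2,0,1,31
salinas_16,salinas,Bottles,OPl,11,2,2,0,1,31
salinas_17,salinas,Unknown objects,OPl,11,2,2,0,1,31
salinas_18,salinas,Fragments,Foam,61,0,0,0,1,0
salinas_19,salinas,Bottles,Foam,61,0,0,0,0,0
salinas_20,salinas,Unknown objects,Foam,61,0,0,0,0,0
salinas_21,salinas,Fragments,Foam,61,0,0,0,0,0
salinas_22,salinas,Bottles,Foam,61,0,0,0,0,0
salinas_23,salinas,Unknown objects,NPl,155,3,0,0,2,0
salinas_24,salinas,Fragments,NPl,155,3,0,0,2,0
salinas_25,salinas,Bottles,NPl,155,3,0,0,1,0
xivares_01,xivares,Netfloats,HPl,1,5,2,0,0,4
xivares_02,xivares,Cosmetics container,HPl,1,5,2,0,0,4
xivares_03,xivares,Fragments,HPl,1,5,2,0,0,4
xivares_04,xivares,Bottles,OPl,11,2,2,0,1,31
banugues_01,banugues,Bottles,HPl,1,5,2,0,0,4
banugues_02,banugues,Unknown objects,HPl,1,5,2,0,0,4
rodiles_01,rodiles,Netfloats,HPl,1,5,2,0,0,4
rodiles_02,rodiles,Ropes,HPl,1,5,2,0,0,4
rodiles_03,rodiles,Buoys,HPl,1,5,2,0,0,4
rodiles_04,rodiles,Netfloats,HPl,1,5,2,0,0,4
rodiles_05,rodiles,Ropes,HPl,1,5,2,0,0,4
rodiles_06,rodiles,Buoys,HPl,1,5,2,0,0,4
rodiles_07,rodiles,Bottles,HPl,1,5,2,0,0,4
rodiles_08,rodiles,Unknown objects,Foam,60,0,0,0,0,0
poo_01,poo,Bottles,HPl,1,5,2,0,0,4
silencio_01,silencio,Netfloats,HPl,1,5,2,0,0,4
silencio_02,silencio,Unknown objects,HPl,1,5,2,0,0,4
silencio_03,silencio,Fragments,HPl,0,5,2,0,0,4
silencio_04,silencio,Bottles,HPl,0,5,2,0,0,4
nieva_01,nieva,Bottles,HPl,0,5,2,0,0,4
figueras_01,figueras,Sandals,OPl,11,2,2,0,1,31
figueras_02,figueras,Unknown objects,OPl,10,2,2,0,1,31
figueras_03,figueras,Fragments,OPl,10,2,2,0,1,31
figueras_04,figueras,Bottles,OPl,10,2,2,0,0,31
figueras_05,figueras,Unknown objects,NPl,155,3,0,0,1,0
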