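beach_id,name,longitude,latitude
figueras,Figueras,-7.02,43.54
penarronda,Penarronda,-6.99,43.55
navia,Navia,-6.72,43.55
barayo,Barayo,-6.62,43.56
silencio,Silencio,-6.29,43.57
bayas,Bayas,-6.04,43.57
salinas,Salinas,-5.95,43.58
nieva,Nieva,-5.94,43.59
xago,Xago,-5.92,43.6
banugues,Banugues,-5.81,43.63
xivares,Xivares,-5.72,43.57
rodiles,Rodiles,-5.38,43.53
sta_marina,Sta. Marina,-5.07,43.47
poo,Poo,-4.78,43.43
andrin,Andrin,-4.71,43.41
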