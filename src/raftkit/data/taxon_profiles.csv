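material,goose_barnacles,acorn_barnacles,bryo_hydro_colonies,decapods,molluscs,polychaetes
HPl,0.070707,0.373737,0.181818,0.020202,0.040404,0.313131
OPl,0.227723,0.049505,0.049505,0.000000,0.019802,0.653465
Foam,0.990000,0.000000,0.000000,0.000000,0.010000,0.000000
NPl,0.970000,0.020000,0.000000,0.000000,0.010000,0.000000
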