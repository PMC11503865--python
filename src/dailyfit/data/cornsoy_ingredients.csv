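name,price,me,cp,sid_lys,sid_met_cys,sid_thr,sid_trp,sid_val,sttd_p,ca,na,min_incl,max_incl
corn,0.85,3.40,72,2.0,2.9,2.3,0.5,3.0,0.9,0.2,0.1,0,1
soybean_meal,1.90,3.15,460,26.3,11.8,16.5,5.9,19.5,2.3,3.0,0.1,0,0.40
soybean_oil,5.50,8.40,0,0,0,0,0,0,0,0,0,0,0.08
limestone,0.35,0,0,0,0,0,0,0,0,380,0,0,0.025
dicalcium_phosphate,3.50,0,0,0,0,0,0,0,160,230,0,0,0.03
salt,0.60,0,0,0,0,0,0,0,0,0,390,0,0.008
l_lysine_hcl,7.00,4.10,938,780,0,0,0,0,0,0,0,0,0.010
dl_methionine,14.00,5.20,586,0,990,0,0,0,0,0,0,0,0.005
l_threonine,9.00,4.20,721,0,0,980,0,0,0,0,0,0,0.005
l_tryptophan,28.00,5.90,851,0,0,0,980,0,0,0,0,0,0.003
l_valine,20.00,4.60,734,0,0,0,0,980,0,0,0,0,0.005
vitamin_mineral_premix,8.00,0,0,0,0,0,0,0,0,0,0,0.003,0.003
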