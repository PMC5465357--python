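# Published treatment-mean steady-state isotope compositions of effluent
# nitrogen species from flow-through intertidal sediment core incubations
# (permil; "ND" = not measured).  Treatments: LN low nitrate, LOLN low
# oxygen + low nitrate, HN high nitrate (~120 uM amendment with anomalous
# 17O-excess nitrate), LOHN low oxygen + high nitrate.  The 17O-excess
# (cap17O) was only measured where nitrate was amended.
core_id,treatment,no3_d15N,no3_d15N_sd,no3_cap17O,no3_cap17O_sd,no2_d15N,no2_d15N_sd,no2_cap17O,no2_cap17O_sd,trn_d15N,trn_d15N_sd,n2o_d15N,n2o_d15N_sd,n2o_cap17O,n2o_cap17O_sd,n2o_SP,n2o_SP_sd
LN-mean,LN,14.0,1.0,ND,ND,6.6,2.2,ND,ND,11.9,1.1,13.7,1.7,ND,ND,7.2,3.4
LOLN-mean,LOLN,14.0,0.6,ND,ND,7.7,2.7,ND,ND,11.6,1.9,14.5,2.0,ND,ND,6.2,3.2
HN-mean,HN,4.6,0.2,14.7,0.7,-1.2,1.8,8.5,2.4,11.9,1.1,0.0,0.6,6.5,1.2,16.2,5.0
LOHN-mean,LOHN,5.3,0.5,14.7,0.6,-1.5,1.9,9.2,3.2,12.9,6.8,-0.7,1.1,5.4,1.3,12.9,2.5
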