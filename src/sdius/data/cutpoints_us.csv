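indicator,direction,zero_rule,t1,t2,t3,t4
nrf93,higher,False,4.1,10.6,18.2,30.5
mar,higher,False,60.2,68.1,74.2,80.5
freshwater_l,lower,False,161.4,263.7,377.1,549.9
stress_water_l,lower,False,5601,9079,12806,18475
acid_g,lower,False,9.3,15.4,22.6,34.4
eutroph_g,lower,False,6.1,10.2,16.3,28.0
ghge_kg,lower,False,1.4,2.2,3.4,5.8
land_m2,lower,False,2.1,3.7,5.9,13.0
budget_share_pct,lower,False,9.0,13.3,20.0,34.1
freq_fastfood,lower,True,1,2,4,
freq_rte,lower,True,1,3,5,
freq_frozen,lower,True,2,3,7,
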