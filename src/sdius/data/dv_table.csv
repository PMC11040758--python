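nutrient,role,dv
protein_g,encourage,50
fiber_g,encourage,28
vitamin_a_ug,encourage,900
vitamin_c_mg,encourage,90
vitamin_e_mg,encourage,15
calcium_mg,encourage,1300
iron_mg,encourage,18
magnesium_mg,encourage,420
potassium_mg,encourage,4700
sat_fat_g,limit,20
added_sugar_g,limit,50
sodium_mg,limit,2300
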