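nutrient,sex,age_min,age_max,rda
vitamin_a_ug,male,20,50,900
vitamin_a_ug,male,51,120,900
vitamin_a_ug,female,20,50,700
vitamin_a_ug,female,51,120,700
thiamin_mg,male,20,50,1.2
thiamin_mg,male,51,120,1.2
thiamin_mg,female,20,50,1.1
thiamin_mg,female,51,120,1.1
vitamin_b6_mg,male,20,50,1.3
vitamin_b6_mg,male,51,120,1.7
vitamin_b6_mg,female,20,50,1.3
vitamin_b6_mg,female,51,120,1.5
folate_ug,male,20,50,400
folate_ug,male,51,120,400
folate_ug,female,20,50,400
folate_ug,female,51,120,400
vitamin_c_mg,male,20,50,90
vitamin_c_mg,male,51,120,90
vitamin_c_mg,female,20,50,75
vitamin_c_mg,female,51,120,75
vitamin_e_mg,male,20,50,15
vitamin_e_mg,male,51,120,15
vitamin_e_mg,female,20,50,15
vitamin_e_mg,female,51,120,15
calcium_mg,male,20,50,1000
calcium_mg,male,51,120,1000
calcium_mg,female,20,50,1000
calcium_mg,female,51,120,1200
magnesium_mg,male,20,50,420
magnesium_mg,male,51,120,420
magnesium_mg,female,20,50,320
magnesium_mg,female,51,120,320
iron_mg,male,20,50,8
iron_mg,male,51,120,8
iron_mg,female,20,50,18
iron_mg,female,51,120,8
zinc_mg,male,20,50,11
zinc_mg,male,51,120,11
zinc_mg,female,20,50,8
zinc_mg,female,51,120,8
copper_mg,male,20,50,0.9
copper_mg,male,51,120,0.9
copper_mg,female,20,50,0.9
copper_mg,female,51,120,0.9
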