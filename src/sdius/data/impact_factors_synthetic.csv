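group,freshwater_l,stress_water_l,acid_g,eutroph_g,ghge_kg,land_m2
wheat_rye_bread,25,700,1.0,0.9,0.06,0.30
maize_products,20,650,0.9,0.7,0.10,0.25
oatmeal,30,900,1.1,1.0,0.13,0.60
rice,135,4900,2.6,3.1,0.55,0.35
potatoes,12,350,0.6,0.9,0.08,0.17
cassava,1,10,0.5,0.1,0.25,0.35
cane_sugar,25,620,0.8,0.6,0.10,0.07
beet_sugar,9,220,0.7,0.5,0.06,0.05
other_pulses,60,2100,1.3,1.6,0.09,0.80
peas,35,1100,0.9,0.7,0.08,0.60
nuts,390,7100,1.2,1.7,0.09,0.45
groundnuts,50,1700,1.4,1.3,0.14,0.45
soymilk,5,110,0.6,0.6,0.20,0.15
tofu,15,290,1.1,1.2,0.16,0.22
soybean_oil,12,410,0.9,1.5,0.60,1.45
palm_oil,1,40,1.1,1.3,1.00,0.30
sunflower_oil,140,3400,0.9,1.9,0.48,2.40
rapeseed_oil,30,900,1.0,1.6,0.50,1.45
olive_oil,290,6800,1.2,2.8,0.72,3.50
tomatoes,40,1900,1.1,0.8,0.25,0.10
onions_leeks,2,45,0.4,0.4,0.06,0.05
root_vegetables,4,120,0.3,0.3,0.05,0.05
brassicas,25,750,0.6,0.8,0.06,0.07
other_vegetables,30,1000,0.7,0.7,0.08,0.09
citrus_fruit,11,300,0.5,0.4,0.05,0.10
bananas,15,420,0.6,0.4,0.10,0.25
apples,24,650,0.5,0.4,0.06,0.08
berries_grapes,60,1900,0.7,0.3,0.22,0.35
other_fruit,20,550,0.6,0.4,0.09,0.14
coffee,3,90,1.9,2.0,0.40,0.45
dark_chocolate,7,220,1.3,2.0,0.70,1.00
beef_beef_herd,110,4600,25.8,22.2,7.50,24.60
beef_dairy_herd,85,3200,15.5,13.2,4.10,5.40
lamb_mutton,70,2700,12.1,10.0,3.00,27.90
pig_meat,130,3900,7.3,5.9,1.85,2.75
poultry_meat,70,2100,5.4,4.9,1.45,1.85
eggs,30,900,2.7,2.2,0.55,0.70
milk,55,1600,2.2,2.1,0.65,1.85
cheese,170,5100,5.0,4.2,1.15,4.40
fish_farmed,120,3300,3.0,4.8,1.15,0.85
crustaceans_farmed,80,2400,4.1,6.2,1.60,0.20
wine,10,310,0.9,0.6,0.18,0.18
beer,9,260,0.5,0.4,0.24,0.22
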