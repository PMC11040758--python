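group,grams_per_serving,dga_group,amed_component,eat_lancet_component
wheat_rye_bread,50,refined_grains,,grains
maize_products,40,whole_grains,whole_grains,grains
oatmeal,40,whole_grains,whole_grains,grains
rice,160,refined_grains,,grains
potatoes,150,starchy_vegetables,,tubers
cassava,150,starchy_vegetables,,tubers
cane_sugar,8,added_sugars,,
beet_sugar,8,added_sugars,,
other_pulses,90,legumes,legumes,legumes
peas,80,legumes,legumes,legumes
nuts,28,nuts_seeds,nuts,nuts
groundnuts,28,nuts_seeds,nuts,nuts
soymilk,240,soy_products,,soy
tofu,85,soy_products,,soy
soybean_oil,14,oils,,
palm_oil,14,oils,,
sunflower_oil,14,oils,,
rapeseed_oil,14,oils,,
olive_oil,14,oils,,
tomatoes,120,red_orange_vegetables,vegetables,vegetables
onions_leeks,80,other_vegetables,vegetables,vegetables
root_vegetables,80,red_orange_vegetables,vegetables,vegetables
brassicas,85,dark_green_vegetables,vegetables,vegetables
other_vegetables,80,other_vegetables,vegetables,vegetables
citrus_fruit,130,fruits,fruits,fruits
bananas,118,fruits,fruits,fruits
apples,180,fruits,fruits,fruits
berries_grapes,100,fruits,fruits,fruits
other_fruit,120,fruits,fruits,fruits
coffee,240,other,,
dark_chocolate,30,other,,
beef_beef_herd,85,meats,red_processed_meat,beef_lamb_pork
beef_dairy_herd,85,meats,red_processed_meat,beef_lamb_pork
lamb_mutton,85,meats,red_processed_meat,beef_lamb_pork
pig_meat,85,meats,red_processed_meat,beef_lamb_pork
poultry_meat,85,poultry,,poultry
eggs,50,eggs,,eggs
milk,244,dairy,,dairy
cheese,42,dairy,,dairy
fish_farmed,85,seafood,fish,fish
crustaceans_farmed,85,seafood,fish,fish
wine,148,other,,
beer,356,other,,
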