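food_code,description,group
11000101,wheat rye bread (form 1),wheat_rye_bread
11000102,wheat rye bread (form 2),wheat_rye_bread
11000201,maize products (form 1),maize_products
11000202,maize products (form 2),maize_products
11000301,oatmeal (form 1),oatmeal
11000302,oatmeal (form 2),oatmeal
11000401,rice (form 1),rice
11000402,rice (form 2),rice
11000501,potatoes (form 1),potatoes
11000502,potatoes (form 2),potatoes
11000601,cassava (form 1),cassava
11000602,cassava (form 2),cassava
11000701,cane sugar (form 1),cane_sugar
11000702,cane sugar (form 2),cane_sugar
11000801,beet sugar (form 1),beet_sugar
11000802,beet sugar (form 2),beet_sugar
11000901,other pulses (form 1),other_pulses
11000902,other pulses (form 2),other_pulses
11001001,peas (form 1),peas
11001002,peas (form 2),peas
11001101,nuts (form 1),nuts
11001102,nuts (form 2),nuts
11001201,groundnuts (form 1),groundnuts
11001202,groundnuts (form 2),groundnuts
11001301,soymilk (form 1),soymilk
11001302,soymilk (form 2),soymilk
11001401,tofu (form 1),tofu
11001402,tofu (form 2),tofu
11001501,soybean oil (form 1),soybean_oil
11001502,soybean oil (form 2),soybean_oil
11001601,palm oil (form 1),palm_oil
11001602,palm oil (form 2),palm_oil
11001701,sunflower oil (form 1),sunflower_oil
11001702,sunflower oil (form 2),sunflower_oil
11001801,rapeseed oil (form 1),rapeseed_oil
11001802,rapeseed oil (form 2),rapeseed_oil
11001901,olive oil (form 1),olive_oil
11001902,olive oil (form 2),olive_oil
11002001,tomatoes (form 1),tomatoes
11002002,tomatoes (form 2),tomatoes
11002101,onions leeks (form 1),onions_leeks
11002102,onions leeks (form 2),onions_leeks
11002201,root vegetables (form 1),root_vegetables
11002202,root vegetables (form 2),root_vegetables
11002301,brassicas (form 1),brassicas
11002302,brassicas (form 2),brassicas
11002401,other vegetables (form 1),other_vegetables
11002402,other vegetables (form 2),other_vegetables
11002501,citrus fruit (form 1),citrus_fruit
11002502,citrus fruit (form 2),citrus_fruit
11002601,bananas (form 1),bananas
11002602,bananas (form 2),bananas
11002701,apples (form 1),apples
11002702,apples (form 2),apples
11002801,berries grapes (form 1),berries_grapes
11002802,berries grapes (form 2),berries_grapes
11002901,other fruit (form 1),other_fruit
11002902,other fruit (form 2),other_fruit
11003001,coffee (form 1),coffee
11003002,coffee (form 2),coffee
11003101,dark chocolate (form 1),dark_chocolate
11003102,dark chocolate (form 2),dark_chocolate
11003201,beef beef herd (form 1),beef_beef_herd
11003202,beef beef herd (form 2),beef_beef_herd
11003301,beef dairy herd (form 1),beef_dairy_herd
11003302,beef dairy herd (form 2),beef_dairy_herd
11003401,lamb mutton (form 1),lamb_mutton
11003402,lamb mutton (form 2),lamb_mutton
11003501,pig meat (form 1),pig_meat
11003502,pig meat (form 2),pig_meat
11003601,poultry meat (form 1),poultry_meat
11003602,poultry meat (form 2),poultry_meat
11003701,eggs (form 1),eggs
11003702,eggs (form 2),eggs
11003801,milk (form 1),milk
11003802,milk (form 2),milk
11003901,cheese (form 1),cheese
11003902,cheese (form 2),cheese
11004001,fish farmed (form 1),fish_farmed
11004002,fish farmed (form 2),fish_farmed
11004101,crustaceans farmed (form 1),crustaceans_farmed
11004102,crustaceans farmed (form 2),crustaceans_farmed
11004201,wine (form 1),wine
11004202,wine (form 2),wine
11004301,beer (form 1),beer
11004302,beer (form 2),beer
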