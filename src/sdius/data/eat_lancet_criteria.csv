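component,kind,direction,threshold
grains,grams,le,232
tubers,grams,le,100
vegetables,grams,ge,200
fruits,grams,ge,100
dairy,grams,le,500
beef_lamb_pork,grams,le,28
poultry,grams,le,58
eggs,grams,le,25
fish,grams,le,100
legumes,grams,ge,50
soy,grams,ge,25
nuts,grams,ge,25
added_fats,ratio,ge,0.8
added_sugar,grams,le,31
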