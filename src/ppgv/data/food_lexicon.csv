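keyword,group
rice,staples
noodle,staples
noodles,staples
bread,staples
porridge,staples
congee,staples
steamed bun,staples
bun,staples
mantou,staples
dumpling,staples
wonton,staples
pancake,staples
oat,staples
millet,staples
corn,staples
potato,staples
sweet potato,staples
taro,staples
vermicelli,staples
flour,staples
vegetable,vegetables
cabbage,vegetables
spinach,vegetables
broccoli,vegetables
cucumber,vegetables
tomato,vegetables
celery,vegetables
lettuce,vegetables
greens,vegetables
bok choy,vegetables
pak choi,vegetables
eggplant,vegetables
pepper,vegetables
mushroom,vegetables
carrot,vegetables
radish,vegetables
pumpkin,vegetables
wax gourd,vegetables
winter melon,vegetables
bitter melon,vegetables
bitter gourd,vegetables
cauliflower,vegetables
onion,vegetables
leek,vegetables
bean sprout,vegetables
apple,fruits
banana,fruits
orange,fruits
pear,fruits
grape,fruits
peach,fruits
watermelon,fruits
fruit,fruits
kiwi,fruits
pomelo,fruits
plum,fruits
cherry,fruits
strawberry,fruits
pork,animal_foods
beef,animal_foods
chicken,animal_foods
duck,animal_foods
fish,animal_foods
shrimp,animal_foods
prawn,animal_foods
egg,animal_foods
lamb,animal_foods
mutton,animal_foods
crab,animal_foods
meat,animal_foods
shellfish,animal_foods
squid,animal_foods
milk,dairy
yogurt,dairy
yoghurt,dairy
cheese,dairy
tofu,legumes_nuts_seeds
soy,legumes_nuts_seeds
soybean,legumes_nuts_seeds
bean,legumes_nuts_seeds
peanut,legumes_nuts_seeds
walnut,legumes_nuts_seeds
almond,legumes_nuts_seeds
nut,legumes_nuts_seeds
seed,legumes_nuts_seeds
sesame,legumes_nuts_seeds
sugar,sweets
candy,sweets
cake,sweets
cookie,sweets
biscuit,sweets
chocolate,sweets
ice cream,sweets
honey,sweets
sweet,sweets
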