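# concept_id	surface_forms (semicolon-separated)
garden	garden;gardens;gardening
flower	flower;flowers;blossom
rose	rose;roses
tree	tree;trees
vegetable	vegetable;vegetables
lawn	lawn;meadow
music	music;musical
song	song;songs;singing;sing
choir	choir;choirs
piano	piano;pianos
dance	dance;dances;dancing
melody	melody;melodies;tune
cooking	cooking;cook;cooked
baking	baking;bake;baked
bread	bread;breads
cake	cake;cakes
recipe	recipe;recipes
soup	soup;soups
travel	travel;travels;travelling;journey
mountain	mountain;mountains;alps
sea	sea;seaside;ocean
holiday	holiday;holidays;vacation
train	train;trains;railway
city	city;cities;town
animal	animal;animals
dog	dog;dogs;puppy
cat	cat;cats;kitten
horse	horse;horses;pony
bird	bird;birds
farm	farm;farms;farming;farmer
family	family;families
child	child;children;kids
wedding	wedding;weddings;marriage
grandchild	grandchild;grandchildren;grandson;granddaughter
home	home;homes;house
friend	friend;friends;friendship
sport	sport;sports
football	football;soccer
swimming	swimming;swim
hiking	hiking;hike;walking;walk
cycling	cycling;bicycle;bike
gymnastics	gymnastics;exercise;exercises
christmas	christmas;advent
birthday	birthday;birthdays
easter	easter
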