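# within-cluster star edges (hub first)
garden	flower
garden	rose
garden	tree
garden	vegetable
garden	lawn
flower	rose
music	song
music	choir
music	piano
music	dance
music	melody
song	melody
song	choir
cooking	baking
cooking	bread
cooking	cake
cooking	recipe
cooking	soup
baking	bread
baking	cake
travel	mountain
travel	sea
travel	holiday
travel	train
travel	city
animal	dog
animal	cat
animal	horse
animal	bird
animal	farm
family	child
family	wedding
family	grandchild
family	home
family	friend
child	grandchild
sport	football
sport	swimming
sport	hiking
sport	cycling
sport	gymnastics
# hub ring connecting the clusters
garden	music
music	cooking
cooking	travel
travel	animal
animal	family
family	sport
sport	garden
# a few semantic cross links
flower	wedding
dance	wedding
farm	vegetable
hiking	mountain
horse	farm
cake	birthday
christmas	family
easter	family
birthday	family
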