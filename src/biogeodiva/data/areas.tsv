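code	name
A	Mexican Transition Zone
B	Antillean subregion, Brazilian subregion
C	Mesoamerican Dominion
D	Pacific Dominion
E	Boreal Brazilian Dominion
F	South Brazilian Dominion, Chacoan subregion
G	South-eastern Amazonian Dominion
H	Chacoan Dominion
I	Parana Dominion
J	South American transition zone
K	Old World
L	North America (except Mexico)
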