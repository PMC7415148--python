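# Trivial fatty-acid name stems: stem <TAB> carbons <TAB> double_bonds
# Stems are matched case-insensitively after stripping a trailing " acid".
# Values follow standard fatty-acid nomenclature tables.
acetic	2	0
propionic	3	0
butyric	4	0
valeric	5	0
caproic	6	0
enanthic	7	0
caprylic	8	0
pelargonic	9	0
capric	10	0
undecylic	11	0
lauric	12	0
tridecylic	13	0
myristic	14	0
myristoleic	14	1
pentadecylic	15	0
palmitic	16	0
palmitoleic	16	1
sapienic	16	1
margaric	17	0
stearic	18	0
oleic	18	1
elaidic	18	1
vaccenic	18	1
petroselinic	18	1
linoleic	18	2
linolelaidic	18	2
linolenic	18	3
stearidonic	18	4
nonadecylic	19	0
arachidic	20	0
gondoic	20	1
gadoleic	20	1
mead	20	3
arachidonic	20	4
timnodonic	20	5
heneicosylic	21	0
behenic	22	0
erucic	22	1
cetoleic	22	1
adrenic	22	4
clupanodonic	22	5
cervonic	22	6
tricosylic	23	0
lignoceric	24	0
nervonic	24	1
cerotic	26	0
ximenic	26	1
montanic	28	0
melissic	30	0
cetyl	16	0
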