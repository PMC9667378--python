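# City-name abbreviation expansion table, one rule per line: token<TAB>expansion.
# Tokens are compared after lowercasing and accent removal.
st	saint
ste	sainte
stes	saintes
sts	saints
sr	sur
s	sur
ss	sous
sz	sous
les	les
lès	les
gd	grand
gde	grande
pt	petit
pte	petite
nd	notredame
chap	chapelle
vx	vieux
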