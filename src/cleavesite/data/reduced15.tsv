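# 15-group reduced amino-acid alphabet: biophysically similar residues share
# a group.  Columns: group name <TAB> member residues.  Any published
# 15-group scheme can be substituted via the alphabet.reduced_path config key.
ala	A
gly	G
cys	C
acidic	DE
aromatic	FY
trp	W
his	H
beta_branched	IV
leu	L
met	M
basic	KR
asn	N
gln	Q
pro	P
hydroxyl	ST
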