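# name: side_chain_charge
# kind: per-residue
# reference: Formal side-chain charge at neutral pH: Asp/Glu -1, Lys/Arg +1, His and all others 0.
A	0
C	0
D	-1
E	-1
F	0
G	0
H	0
I	0
K	1
L	0
M	0
N	0
P	0
Q	0
R	1
S	0
T	0
V	0
W	0
Y	0
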