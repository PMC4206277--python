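# Seven-way chemical classification of the standard amino acids.
A	hydrophobic
V	hydrophobic
L	hydrophobic
I	hydrophobic
M	hydrophobic
C	hydrophobic
F	aromatic
W	aromatic
Y	aromatic
S	polar
T	polar
N	polar
Q	polar
H	polar
X	polar
K	positive
R	positive
D	negative
E	negative
G	glycine
P	proline
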