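# Atomic solvation parameters sigma (kcal mol^-1 A^-2), applied as
# E_solv = sum_atoms sigma(type) * SASA(atom).  Atom classes:
#   C        apolar carbon
#   N/O      neutral nitrogen or oxygen
#   O-       charged oxygen (Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT)
#   N+       charged nitrogen (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2)
#   S        sulfur
C	0.016
N/O	-0.006
O-	-0.024
N+	-0.050
S	0.021
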