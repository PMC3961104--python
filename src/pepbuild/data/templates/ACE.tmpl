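# N-terminal acetyl (methyl) cap: CH3-C(=O)- group preceding residue 1.
# Seed atoms ('.' references) start the molecule coordinate frame.
cap methyl N ACE
atom CH3 C . . .    1.0000  90.0000   0.0000 abs
atom C   C . . CH3  1.5090  90.0000   0.0000 abs
atom O   O . CH3 C  1.2290 122.0000   0.0000 abs
atom H1  H O C CH3  1.0900 109.5000   0.0000 abs
atom H2  H O C CH3  1.0900 109.5000 120.0000 abs
atom H3  H O C CH3  1.0900 109.5000 -120.0000 abs
handoff -N O
handoff -CA CH3
handoff -C C
handoff_psi 180.0
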