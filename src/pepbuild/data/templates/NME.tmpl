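# C-terminal N-methylamide (methyl) cap: -NH-CH3 group following residue n.
# '-' references resolve to the last amino-acid residue.
cap methyl C NME
atom N    N -N -CA -C 1.3290 116.2000   0.0000 prev_psi
atom H    H -CA -C N  1.0100 119.2000 180.0000 omega
atom CH3  C -CA -C N  1.4500 121.7000   0.0000 omega
atom HH31 H -C N CH3  1.0900 109.5000 180.0000 abs
atom HH32 H -C N CH3  1.0900 109.5000  60.0000 abs
atom HH33 H -C N CH3  1.0900 109.5000 -60.0000 abs
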