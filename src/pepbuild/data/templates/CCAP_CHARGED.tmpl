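# Charged C-terminus: carboxylate -COO- (adds OXT to residue n).
cap charged C OXT
atom OXT O -N -CA -C 1.2490 117.0000 0.0000 prev_psi
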