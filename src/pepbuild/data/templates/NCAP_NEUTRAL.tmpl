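# Neutral N-terminus: -NH2 (two protons on the N of residue 1).
cap neutral N NT2
atom H1 H +C +CA +N 1.0100 109.5000  60.0000 abs
atom H2 H +C +CA +N 1.0100 109.5000 -60.0000 abs
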