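# Charged N-terminus: -NH3+ (three protons on the N of residue 1).
# '+' references resolve to residue 1.
cap charged N NT3
atom H1 H +C +CA +N 1.0300 109.5000 180.0000 abs
atom H2 H +C +CA +N 1.0300 109.5000  60.0000 abs
atom H3 H +C +CA +N 1.0300 109.5000 -60.0000 abs
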