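# Neutral C-terminus: carboxylic acid -COOH (adds OXT and its proton).
cap neutral C OXT
atom OXT O -N -CA -C  1.3300 111.4000   0.0000 prev_psi
atom HXT H -CA -C OXT 0.9800 106.9000 180.0000 abs
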