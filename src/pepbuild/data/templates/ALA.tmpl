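residue ALA A
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4677 121.7000 0.0000 omega
atom C  C  -C N CA    1.5055 109.5241 0.0000 phi
atom O  O  N CA C     1.2070 120.0308 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5294 109.4645 -119.9991 abs
atom HA   H  C N CA 1.0899 109.4655 120.0829 abs
atom HB1  H  N CA CB 1.0907 109.4905 -59.9713 abs
atom HB2  H  N CA CB 1.0899 109.4323 59.9976 abs
atom HB3  H  N CA CB 1.0901 109.5239 -179.9612 abs
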