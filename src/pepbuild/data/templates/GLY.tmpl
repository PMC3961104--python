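residue GLY G
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4697 121.7000 0.0000 omega
atom C  C  -C N CA    1.5069 109.4388 0.0000 phi
atom O  O  N CA C     1.2081 120.0513 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom HA2  H  C N CA 1.0896 109.4829 119.9854 abs
atom HA3  H  C N CA 1.0903 109.4504 -119.9678 abs
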