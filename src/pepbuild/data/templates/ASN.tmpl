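residue ASN N
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4682 121.7000 0.0000 omega
atom C  C  -C N CA    1.5072 109.5130 0.0000 phi
atom O  O  N CA C     1.2079 119.9724 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5309 109.4540 -119.9959 abs
atom CG   C  N CA CB 1.5066 109.4843 0.0000 chi1
atom OD1  O  CA CB CG 1.2133 119.9743 0.0000 chi2
atom ND2  N  CA CB CG 1.3476 120.0120 -179.9262 chi2
atom HA   H  C N CA 1.0899 109.5056 120.0627 abs
atom HB2  H  N CA CB 1.0903 109.4142 119.9676 chi1
atom HB3  H  N CA CB 1.0895 109.4697 -120.0326 chi1
atom HD21 H  CB CG ND2 0.9701 119.9863 -0.0515 abs
atom HD22 H  CB CG ND2 0.9696 120.0576 179.9901 abs
chi 1 N CA CB CG
chi 2 CA CB CG OD1
defchi -60.0 -60.0
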