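residue GLU E
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4685 121.7000 0.0000 omega
atom C  C  -C N CA    1.5078 109.4740 0.0000 phi
atom O  O  N CA C     1.2083 119.9809 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5302 109.4824 -119.9555 abs
atom CG   C  N CA CB 1.5306 109.4016 0.0000 chi1
atom CD   C  CA CB CG 1.5076 109.4303 0.0000 chi2
atom OE1  O  CB CG CD 1.2084 120.0030 0.0000 chi3
atom OE2  O  CB CG CD 1.3425 119.9977 -179.9373 chi3
atom HA   H  C N CA 1.0897 109.4997 120.0006 abs
atom HB2  H  N CA CB 1.0901 109.5095 119.9635 chi1
atom HB3  H  N CA CB 1.0891 109.5036 -119.9773 chi1
atom HG2  H  CA CB CG 1.0901 109.5026 119.9653 chi2
atom HG3  H  CA CB CG 1.0894 109.4463 -119.9539 chi2
atom HE2  H  CG CD OE2 0.9663 116.9918 179.9872 abs
chi 1 N CA CB CG
chi 2 CA CB CG CD
chi 3 CB CG CD OE1
defchi -60.0 180.0 60.0
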