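residue GLN Q
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5063 109.4529 0.0000 phi
atom O  O  N CA C     1.2072 120.0332 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5288 109.4592 -120.0663 abs
atom CG   C  N CA CB 1.5284 109.5344 0.0000 chi1
atom CD   C  CA CB CG 1.5066 109.5426 0.0000 chi2
atom OE1  O  CB CG CD 1.2122 119.9367 0.0000 chi3
atom NE2  N  CB CG CD 1.3471 120.0933 -179.9569 chi3
atom HA   H  C N CA 1.0896 109.4410 120.0190 abs
atom HB2  H  N CA CB 1.0906 109.4211 119.9936 chi1
atom HB3  H  N CA CB 1.0896 109.4409 -120.1141 chi1
atom HG2  H  CA CB CG 1.0906 109.4595 119.9623 chi2
atom HG3  H  CA CB CG 1.0896 109.5022 -120.0840 chi2
atom HE21 H  CG CD NE2 0.9694 120.1198 179.9882 abs
atom HE22 H  CG CD NE2 0.9704 119.9555 -0.0035 abs
chi 1 N CA CB CG
chi 2 CA CB CG CD
chi 3 CB CG CD OE1
defchi -60.0 180.0 60.0
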