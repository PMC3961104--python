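residue LYS K
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4694 121.7000 0.0000 omega
atom C  C  -C N CA    1.5066 109.4700 0.0000 phi
atom O  O  N CA C     1.2079 120.0256 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5300 109.4527 -119.9671 abs
atom CG   C  N CA CB 1.5307 109.4176 0.0000 chi1
atom CD   C  CA CB CG 1.5308 109.4405 0.0000 chi2
atom CE   C  CB CG CD 1.5291 109.4647 0.0000 chi3
atom NZ   N  CG CD CE 1.4694 109.5004 0.0000 chi4
atom HA   H  C N CA 1.0895 109.4517 119.9863 abs
atom HB2  H  N CA CB 1.0891 109.5091 120.0171 chi1
atom HB3  H  N CA CB 1.0901 109.4869 -119.9440 chi1
atom HG2  H  CA CB CG 1.0893 109.4687 119.9790 chi2
atom HG3  H  CA CB CG 1.0901 109.4908 -119.9438 chi2
atom HD2  H  CB CG CD 1.0901 109.5046 120.0360 chi3
atom HD3  H  CB CG CD 1.0901 109.4309 -119.9780 chi3
atom HE2  H  CG CD CE 1.0901 109.5336 119.9717 chi4
atom HE3  H  CG CD CE 1.0900 109.5014 -120.0475 chi4
atom HZ1  H  CD CE NZ 1.0095 109.3691 -60.0047 abs
atom HZ2  H  CD CE NZ 1.0084 109.4677 59.9500 abs
chi 1 N CA CB CG
chi 2 CA CB CG CD
chi 3 CB CG CD CE
chi 4 CG CD CE NZ
defchi -60.0 180.0 180.0 180.0
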