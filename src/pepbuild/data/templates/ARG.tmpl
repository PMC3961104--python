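residue ARG R
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4618 121.7000 0.0000 omega
atom C  C  -C N CA    1.5181 108.1385 0.0000 phi
atom O  O  N CA C     1.2241 125.4848 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5363 111.5499 -123.5605 abs
atom CG   C  N CA CB 1.5371 114.5356 0.0000 chi1
atom CD   C  CA CB CG 1.5273 112.4170 0.0000 chi2
atom NE   N  CB CG CD 1.4435 111.0161 0.0000 chi3
atom CZ   C  CG CD NE 1.4058 123.0046 0.0000 chi4
atom NH1  N  CD NE CZ 1.3905 120.9962 179.9864 abs
atom NH2  N  CD NE CZ 1.3912 119.8148 -0.0124 abs
atom HA   H  C N CA 1.0963 107.5544 116.2990 abs
atom HB2  H  N CA CB 1.0973 108.9071 -122.4150 chi1
atom HB3  H  N CA CB 1.0980 108.8390 122.1245 chi1
atom HG2  H  CA CB CG 1.0966 109.5461 -120.0966 chi2
atom HG3  H  CA CB CG 1.0967 110.0277 122.3820 chi2
atom HD2  H  CB CG CD 1.0955 109.4797 119.8157 chi3
atom HD3  H  CB CG CD 1.0952 110.6347 -121.9377 chi3
atom HE   H  CG CD NE 1.0270 120.4291 -179.8288 chi4
atom HH11 H  NE CZ NH1 1.0177 120.9037 -179.9595 abs
atom HH21 H  NE CZ NH2 1.0168 121.2005 0.0564 abs
atom HH22 H  NE CZ NH2 1.0174 121.1705 179.9065 abs
chi 1 N CA CB CG
chi 2 CA CB CG CD
chi 3 CB CG CD NE
chi 4 CG CD NE CZ
defchi -60.0 180.0 180.0 180.0
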