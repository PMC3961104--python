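residue HIS H
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4411 121.7000 0.0000 omega
atom C  C  -C N CA    1.5218 111.1470 0.0000 phi
atom O  O  N CA C     1.2269 122.9813 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5337 111.1252 -122.7794 abs
atom CG   C  N CA CB 1.5100 112.9791 0.0000 chi1
atom ND1  N  CA CB CG 1.3513 120.3285 0.0000 chi2
atom CD2  C  CA CB CG 1.3376 129.9283 179.8457 chi2
atom CE1  C  CB CG ND1 1.3369 107.8621 179.9049 abs
atom NE2  N  CG ND1 CE1 1.3370 107.6169 -0.0433 abs
atom HA   H  C N CA 1.0958 106.2509 115.9169 abs
atom HB2  H  N CA CB 1.0987 110.3817 121.1196 chi1
atom HB3  H  N CA CB 1.0982 110.1994 -123.0905 chi1
atom HD2  H  CB CG CD2 1.0723 137.1496 -0.0225 abs
atom HE1  H  CG ND1 CE1 1.0777 126.1756 179.9914 abs
atom HE2  H  ND1 CE1 NE2 1.0156 125.0781 -179.9159 abs
closure NE2 CD2
chi 1 N CA CB CG
chi 2 CA CB CG ND1
defchi -60.0 -60.0
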