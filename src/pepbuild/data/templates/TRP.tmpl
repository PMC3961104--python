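residue TRP W
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5074 109.4283 0.0000 phi
atom O  O  N CA C     1.2079 119.9979 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5286 109.5226 -120.0255 abs
atom CG   C  N CA CB 1.5067 109.4419 0.0000 chi1
atom CD1  C  CA CB CG 1.3426 126.4957 0.0000 chi2
atom CD2  C  CA CB CG 1.4639 126.5119 179.6215 chi2
atom NE1  N  CB CG CD1 1.3686 109.9318 179.9435 abs
atom CE2  C  CG CD1 NE1 1.3768 109.8503 -0.0618 abs
atom CE3  C  CB CG CD2 1.3961 134.0470 0.7839 abs
atom CZ2  C  CD1 NE1 CE2 1.3906 133.5052 -179.9980 abs
atom CZ3  C  CG CD2 CE3 1.3659 119.7952 179.6391 abs
atom CH2  C  CD2 CE3 CZ3 1.3877 120.5432 -0.3083 abs
atom HA   H  C N CA 1.0899 109.4788 119.9396 abs
atom HB2  H  N CA CB 1.0899 109.4702 119.9608 chi1
atom HB3  H  N CA CB 1.0895 109.5124 -119.9931 chi1
atom HD1  H  CB CG CD1 1.0792 125.0894 -0.0578 abs
atom HE1  H  CG CD1 NE1 0.9691 125.0687 -179.9699 abs
atom HE3  H  CG CD2 CE3 1.0802 120.0708 -0.6780 abs
atom HZ2  H  NE1 CE2 CZ2 1.0805 120.1130 -0.0432 abs
atom HZ3  H  CD2 CE3 CZ3 1.0799 119.7562 179.6597 abs
atom HH2  H  CE3 CZ3 CH2 1.0800 119.7231 -179.9135 abs
closure CE2 CD2
closure CH2 CZ2
chi 1 N CA CB CG
chi 2 CA CB CG CD1
defchi -60.0 -60.0
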