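residue TYR Y
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5072 109.4691 0.0000 phi
atom O  O  N CA C     1.2070 120.0078 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5287 109.4703 -120.0410 abs
atom CG   C  N CA CB 1.5062 109.4975 0.0000 chi1
atom CD1  C  CA CB CG 1.3823 119.9470 0.0000 chi2
atom CD2  C  CA CB CG 1.3830 119.9427 179.6919 chi2
atom CE1  C  CB CG CD1 1.3810 120.0729 -179.9763 abs
atom CE2  C  CB CG CD2 1.3809 120.0203 179.7745 abs
atom CZ   C  CG CD2 CE2 1.3881 119.9828 0.5048 abs
atom OH   O  CD2 CE2 CZ 1.3582 120.0357 179.7644 abs
atom HA   H  C N CA 1.0907 109.4279 119.9906 abs
atom HB2  H  N CA CB 1.0893 109.5118 120.1033 chi1
atom HB3  H  N CA CB 1.0909 109.4603 -119.9886 chi1
atom HD1  H  CB CG CD1 1.0793 119.9415 0.0277 abs
atom HD2  H  CB CG CD2 1.0795 119.9964 0.2438 abs
atom HE1  H  CG CD1 CE1 1.0795 120.0572 179.9540 abs
atom HE2  H  CG CD2 CE2 1.0800 120.0442 -179.6602 abs
atom HH   H  CE2 CZ OH 0.9664 106.8813 -89.9993 abs
closure CZ CE1
chi 1 N CA CB CG
chi 2 CA CB CG CD1
defchi -60.0 -60.0
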