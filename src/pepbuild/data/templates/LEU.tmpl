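residue LEU L
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4691 121.7000 0.0000 omega
atom C  C  -C N CA    1.5061 109.4377 0.0000 phi
atom O  O  N CA C     1.2077 120.0886 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5286 109.4163 -119.9728 abs
atom CG   C  N CA CB 1.5303 109.4950 0.0000 chi1
atom CD1  C  CA CB CG 1.5300 109.5000 0.0000 chi2
atom CD2  C  CA CB CG 1.5285 109.5008 120.0918 chi2
atom HA   H  C N CA 1.0895 109.4716 120.0527 abs
atom HB2  H  N CA CB 1.0898 109.4621 -119.9648 chi1
atom HB3  H  N CA CB 1.0902 109.5405 120.0807 chi1
atom HG   H  CA CB CG 1.0896 109.4031 -119.8613 chi2
atom HD11 H  CB CG CD1 1.0892 109.4929 179.9786 abs
atom HD12 H  CB CG CD1 1.0903 109.5083 -59.8779 abs
atom HD13 H  CB CG CD1 1.0898 109.4476 60.0410 abs
atom HD21 H  CB CG CD2 1.0898 109.4268 -60.0533 abs
atom HD22 H  CB CG CD2 1.0899 109.4971 59.9424 abs
atom HD23 H  CB CG CD2 1.0903 109.4847 179.9829 abs
chi 1 N CA CB CG
chi 2 CA CB CG CD1
defchi -60.0 180.0
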