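residue MET M
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4689 121.7000 0.0000 omega
atom C  C  -C N CA    1.5062 109.4319 0.0000 phi
atom O  O  N CA C     1.2072 120.0538 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5294 109.4274 -120.0367 abs
atom CG   C  N CA CB 1.5284 109.5449 0.0000 chi1
atom SD   S  CA CB CG 1.8137 109.5064 0.0000 chi2
atom CE   C  CB CG SD 1.8135 100.0339 0.0000 chi3
atom HA   H  C N CA 1.0895 109.4718 120.0072 abs
atom HB2  H  N CA CB 1.0901 109.4389 -120.0398 chi1
atom HB3  H  N CA CB 1.0905 109.4620 120.0543 chi1
atom HG2  H  CA CB CG 1.0903 109.4601 -119.9798 chi2
atom HG3  H  CA CB CG 1.0895 109.4834 120.0199 chi2
atom HE1  H  CG SD CE 1.0891 109.5482 179.9723 abs
atom HE2  H  CG SD CE 1.0893 109.4602 -60.0028 abs
atom HE3  H  CG SD CE 1.0899 109.4479 60.0303 abs
chi 1 N CA CB CG
chi 2 CA CB CG SD
chi 3 CB CG SD CE
defchi -60.0 180.0 180.0
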