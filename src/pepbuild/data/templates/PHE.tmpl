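residue PHE F
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4686 121.7000 0.0000 omega
atom C  C  -C N CA    1.5071 109.4925 0.0000 phi
atom O  O  N CA C     1.2070 119.9830 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5289 109.4735 -120.0941 abs
atom CG   C  N CA CB 1.5052 109.5165 0.0000 chi1
atom CD1  C  CA CB CG 1.3817 120.0585 0.0000 chi2
atom CD2  C  CA CB CG 1.3832 120.0047 179.7575 chi2
atom CE1  C  CB CG CD1 1.3820 120.0292 179.9942 abs
atom CE2  C  CB CG CD2 1.3819 119.9770 179.8391 abs
atom CZ   C  CG CD2 CE2 1.3821 120.0325 0.3819 abs
atom HA   H  C N CA 1.0896 109.4338 119.9573 abs
atom HB2  H  N CA CB 1.0905 109.4435 120.0521 chi1
atom HB3  H  N CA CB 1.0897 109.4924 -120.0699 chi1
atom HD1  H  CB CG CD1 1.0801 119.9524 0.0369 abs
atom HD2  H  CB CG CD2 1.0801 119.9717 0.1540 abs
atom HE1  H  CG CD1 CE1 1.0802 119.9773 179.9695 abs
atom HE2  H  CG CD2 CE2 1.0809 119.9333 -179.7324 abs
atom HZ   H  CD2 CE2 CZ 1.0800 119.9495 179.8945 abs
closure CZ CE1
chi 1 N CA CB CG
chi 2 CA CB CG CD1
defchi -60.0 -60.0
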