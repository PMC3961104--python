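residue ASP D
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4687 121.7000 0.0000 omega
atom C  C  -C N CA    1.5069 109.4805 0.0000 phi
atom O  O  N CA C     1.2091 119.9839 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5301 109.4797 -120.0113 abs
atom CG   C  N CA CB 1.5075 109.4630 0.0000 chi1
atom OD1  O  CA CB CG 1.2080 119.9590 0.0000 chi2
atom OD2  O  CA CB CG 1.3415 119.9993 -179.9359 chi2
atom HA   H  C N CA 1.0902 109.4922 119.9457 abs
atom HB2  H  N CA CB 1.0898 109.4853 119.9593 chi1
atom HB3  H  N CA CB 1.0901 109.4853 -120.0111 chi1
atom HD2  H  CB CG OD2 0.9664 117.0276 179.9933 abs
chi 1 N CA CB CG
chi 2 CA CB CG OD1
defchi -60.0 -60.0
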