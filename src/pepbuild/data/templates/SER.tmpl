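residue SER S
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4690 121.7000 0.0000 omega
atom C  C  -C N CA    1.5067 109.4353 0.0000 phi
atom O  O  N CA C     1.2069 120.0467 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5287 109.4711 -120.0204 abs
atom OG   O  N CA CB 1.4283 109.5115 0.0000 chi1
atom HA   H  C N CA 1.0897 109.4275 119.9663 abs
atom HB2  H  N CA CB 1.0902 109.4341 120.0069 chi1
atom HB3  H  N CA CB 1.0896 109.4805 -120.0365 chi1
atom HG   H  CA CB OG 0.9670 106.8145 -179.9690 abs
chi 1 N CA CB OG
defchi -60.0
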