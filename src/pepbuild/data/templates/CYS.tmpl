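residue CYS C
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5064 109.3894 0.0000 phi
atom O  O  N CA C     1.2068 120.0597 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5285 109.4957 -120.0138 abs
atom SG   S  N CA CB 1.8141 109.4981 0.0000 chi1
atom HA   H  C N CA 1.0897 109.4232 119.9603 abs
atom HB2  H  N CA CB 1.0901 109.4724 119.9825 chi1
atom HB3  H  N CA CB 1.0896 109.4416 -120.0181 chi1
atom HG   H  CA CB SG 1.3444 100.0342 -179.9618 abs
chi 1 N CA CB SG
defchi -60.0
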