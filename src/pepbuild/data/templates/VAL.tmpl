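residue VAL V
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5059 109.4632 0.0000 phi
atom O  O  N CA C     1.2075 120.0245 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5287 109.4452 -120.0037 abs
atom CG1  C  N CA CB 1.5299 109.5086 0.0000 chi1
atom CG2  C  N CA CB 1.5292 109.4895 120.0257 chi1
atom HA   H  C N CA 1.0896 109.4705 120.0076 abs
atom HB   H  N CA CB 1.0909 109.4560 -119.9712 chi1
atom HG11 H  CA CB CG1 1.0905 109.5198 -179.9893 abs
atom HG12 H  CA CB CG1 1.0896 109.4569 -59.9808 abs
atom HG13 H  CA CB CG1 1.0889 109.4590 60.0332 abs
atom HG21 H  CA CB CG2 1.0899 109.4733 -60.0212 abs
atom HG22 H  CA CB CG2 1.0897 109.4964 59.9747 abs
atom HG23 H  CA CB CG2 1.0903 109.5304 179.9528 abs
chi 1 N CA CB CG1
defchi 180.0
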