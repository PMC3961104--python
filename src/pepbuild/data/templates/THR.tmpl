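residue THR T
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4694 121.7000 0.0000 omega
atom C  C  -C N CA    1.5061 109.4088 0.0000 phi
atom O  O  N CA C     1.2071 120.0934 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5290 109.4115 -120.0002 abs
atom OG1  O  N CA CB 1.4280 109.5053 0.0000 chi1
atom CG2  C  N CA CB 1.5301 109.5255 -120.0308 chi1
atom HA   H  C N CA 1.0898 109.4163 120.0013 abs
atom HB   H  N CA CB 1.0898 109.4276 119.9922 chi1
atom HG1  H  CA CB OG1 0.9666 106.8126 -60.0565 abs
atom HG21 H  CA CB CG2 1.0893 109.4779 -179.9370 abs
atom HG22 H  CA CB CG2 1.0901 109.4679 -59.9435 abs
atom HG23 H  CA CB CG2 1.0888 109.4591 60.0412 abs
chi 1 N CA CB OG1
defchi -60.0
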