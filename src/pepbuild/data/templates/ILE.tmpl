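residue ILE I
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4688 121.7000 0.0000 omega
atom C  C  -C N CA    1.5061 109.4832 0.0000 phi
atom O  O  N CA C     1.2075 120.0001 180.0000 psi
atom H  H  -CA -C N   1.0100 119.2000 180.0000 omega
atom CB   C  C N CA 1.5288 109.4301 -120.0733 abs
atom CG1  C  N CA CB 1.5294 109.5474 0.0000 chi1
atom CG2  C  N CA CB 1.5303 109.4577 -119.9719 chi1
atom CD1  C  CA CB CG1 1.5288 109.5474 0.0000 chi2
atom HA   H  C N CA 1.0907 109.4979 119.9739 abs
atom HB   H  N CA CB 1.0893 109.4848 120.0904 chi1
atom HG12 H  CA CB CG1 1.0898 109.4338 -119.9715 chi2
atom HG13 H  CA CB CG1 1.0895 109.4756 120.0331 chi2
atom HG21 H  CA CB CG2 1.0885 109.4850 59.9726 abs
atom HG22 H  CA CB CG2 1.0900 109.4497 -179.9483 abs
atom HG23 H  CA CB CG2 1.0898 109.4798 -60.0297 abs
atom HD11 H  CB CG1 CD1 1.0891 109.6037 -179.9919 abs
atom HD12 H  CB CG1 CD1 1.0903 109.4936 -59.9014 abs
atom HD13 H  CB CG1 CD1 1.0897 109.4579 59.9796 abs
chi 1 N CA CB CG1
chi 2 CA CB CG1 CD1
defchi -60.0 180.0
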