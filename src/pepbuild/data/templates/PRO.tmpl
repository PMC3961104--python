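residue PRO P
atom N  N  -N -CA -C  1.3290 116.2000 0.0000 prev_psi
atom CA C  -CA -C N   1.4862 121.7000 0.0000 omega
atom C  C  -C N CA    1.5076 110.3844 0.0000 phi
atom O  O  N CA C     1.2085 119.9889 180.0000 psi
atom CB   C  C N CA 1.5434 104.7219 -118.8407 abs
atom CG   C  N CA CB 1.5426 105.0594 -23.7996 abs
atom CD   C  CA CB CG 1.5437 105.0631 0.0255 abs
atom HA   H  C N CA 1.0899 110.3996 122.2913 abs
atom HB2  H  N CA CB 1.0903 110.3550 95.0178 abs
atom HB3  H  N CA CB 1.0895 110.3543 -142.6888 abs
atom HG2  H  CA CB CG 1.0900 110.3647 118.8608 abs
atom HG3  H  CA CB CG 1.0904 110.3653 -118.8610 abs
atom HD2  H  CB CG CD 1.0903 110.4601 142.6493 abs
atom HD3  H  CB CG CD 1.0899 110.4192 -94.9126 abs
closure CD N
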