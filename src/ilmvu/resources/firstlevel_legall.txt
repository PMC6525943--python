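# first-level biorthogonal bank: columns dec_lo dec_hi rec_lo rec_hi (pywt convention, zero-padded)
+0.00000000000000000e+00 -0.00000000000000000e+00 +0.00000000000000000e+00 +0.00000000000000000e+00
-1.76776695296636893e-01 +3.53553390593273786e-01 +3.53553390593273786e-01 +1.76776695296636893e-01
+3.53553390593273786e-01 -7.07106781186547573e-01 +7.07106781186547573e-01 +3.53553390593273786e-01
+1.06066017177982119e+00 +3.53553390593273786e-01 +3.53553390593273786e-01 -1.06066017177982119e+00
+3.53553390593273786e-01 -0.00000000000000000e+00 +0.00000000000000000e+00 +3.53553390593273786e-01
-1.76776695296636893e-01 +0.00000000000000000e+00 +0.00000000000000000e+00 +1.76776695296636893e-01
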