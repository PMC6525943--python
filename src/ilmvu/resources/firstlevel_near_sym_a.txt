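# first-level biorthogonal bank: columns dec_lo dec_hi rec_lo rec_hi (pywt convention, zero-padded)
+0.00000000000000000e+00 -0.00000000000000000e+00 +0.00000000000000000e+00 +0.00000000000000000e+00
+8.83883476483184466e-02 +0.00000000000000000e+00 +0.00000000000000000e+00 -8.83883476483184466e-02
+3.53553390593273786e-01 -0.00000000000000000e+00 +0.00000000000000000e+00 +3.53553390593273786e-01
+5.30330085889910707e-01 +0.00000000000000000e+00 +0.00000000000000000e+00 -5.30330085889910707e-01
+3.53553390593273786e-01 -0.00000000000000000e+00 +0.00000000000000000e+00 +3.53553390593273786e-01
+8.83883476483184466e-02 +1.32582521472477621e-01 +1.32582521472477621e-01 -8.83883476483184466e-02
+0.00000000000000000e+00 +5.30330085889910485e-01 -5.30330085889910485e-01 +0.00000000000000000e+00
+0.00000000000000000e+00 +2.20970869120796165e-01 +2.20970869120796165e-01 -0.00000000000000000e+00
+0.00000000000000000e+00 -1.76776695296636843e+00 +1.76776695296636843e+00 +0.00000000000000000e+00
+0.00000000000000000e+00 +2.20970869120796054e-01 +2.20970869120796054e-01 -0.00000000000000000e+00
+0.00000000000000000e+00 +5.30330085889910374e-01 -5.30330085889910374e-01 +0.00000000000000000e+00
+0.00000000000000000e+00 +1.32582521472477705e-01 +1.32582521472477705e-01 -0.00000000000000000e+00
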