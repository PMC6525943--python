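# first-level biorthogonal bank: columns dec_lo dec_hi rec_lo rec_hi (pywt convention, zero-padded)
+0.00000000000000000e+00 -0.00000000000000000e+00 +0.00000000000000000e+00 +0.00000000000000000e+00
+3.78284555072640402e-02 -6.45388826286970585e-02 -6.45388826286970585e-02 -3.78284555072640402e-02
-2.38494650195568425e-02 +4.06894176091640580e-02 -4.06894176091640580e-02 -2.38494650195568425e-02
-1.10624404418437183e-01 +4.18092273221617239e-01 +4.18092273221617239e-01 +1.10624404418437183e-01
+3.77402855612830657e-01 -7.88485616405582901e-01 +7.88485616405582901e-01 +3.77402855612830657e-01
+8.52698679008893845e-01 +4.18092273221617239e-01 +4.18092273221617239e-01 -8.52698679008893845e-01
+3.77402855612830657e-01 +4.06894176091640580e-02 -4.06894176091640580e-02 +3.77402855612830657e-01
-1.10624404418437183e-01 -6.45388826286970585e-02 -6.45388826286970585e-02 +1.10624404418437183e-01
-2.38494650195568425e-02 -0.00000000000000000e+00 +0.00000000000000000e+00 -2.38494650195568425e-02
+3.78284555072640402e-02 +0.00000000000000000e+00 +0.00000000000000000e+00 -3.78284555072640402e-02
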