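# first-level biorthogonal bank: columns dec_lo dec_hi rec_lo rec_hi (pywt convention, zero-padded)
+0.00000000000000000e+00 -0.00000000000000000e+00 +0.00000000000000000e+00 +0.00000000000000000e+00
+0.00000000000000000e+00 +7.02779443345412846e-04 +7.02779443345412846e-04 -0.00000000000000000e+00
+0.00000000000000000e+00 +2.19349891226126051e-04 -2.19349891226126051e-04 +0.00000000000000000e+00
-9.09616553627429214e-03 -8.77076208838130714e-03 -8.77076208838130714e-03 +9.09616553627429214e-03
-2.83907410760157264e-03 -2.25039579398319351e-03 +2.25039579398319351e-03 -2.83907410760157264e-03
+4.30263971417490440e-02 +5.79055897692682259e-02 +5.79055897692682259e-02 -4.30263971417490440e-02
+7.12451779211010616e-03 -1.27983825082843040e-02 +1.27983825082843040e-02 +7.12451779211010616e-03
-4.63716015359831504e-03 -2.15115634328590488e-01 -2.15115634328590488e-01 +4.63716015359831504e-03
+3.49267946908765337e-01 +1.53540432506288044e-01 -1.53540432506288044e-01 +3.49267946908765337e-01
+6.48520638282794826e-01 +5.18831417797633865e-01 +5.18831417797633865e-01 -6.48520638282794826e-01
+3.49267946908765337e-01 -9.84528789377044466e-01 +9.84528789377044466e-01 +3.49267946908765337e-01
-4.63716015359831504e-03 +5.18831417797632644e-01 +5.18831417797632644e-01 +4.63716015359831504e-03
+7.12451779211010616e-03 +1.53540432506290098e-01 -1.53540432506290098e-01 +7.12451779211010616e-03
+4.30263971417490440e-02 -2.15115634328592487e-01 -2.15115634328592487e-01 -4.30263971417490440e-02
-2.83907410760157091e-03 -1.27983825082829961e-02 +1.27983825082829961e-02 -2.83907410760157091e-03
-9.09616553627429041e-03 +5.79055897692676430e-02 +5.79055897692676430e-02 +9.09616553627429041e-03
+0.00000000000000000e+00 -2.25039579398303219e-03 +2.25039579398303219e-03 +0.00000000000000000e+00
+0.00000000000000000e+00 -8.77076208838132969e-03 -8.77076208838132969e-03 -0.00000000000000000e+00
+0.00000000000000000e+00 +2.19349891226127379e-04 -2.19349891226127379e-04 +0.00000000000000000e+00
+0.00000000000000000e+00 +7.02779443345412738e-04 +7.02779443345412738e-04 -0.00000000000000000e+00
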