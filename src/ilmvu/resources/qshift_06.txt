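# q-shift orthonormal scaling filter (tree A; tree B is the time reverse)
+8.59741599888044356e-02
-2.54109093568953802e-02
-1.20268902085564067e-01
+3.07833225598968530e-01
+7.41122189098223694e-01
+5.63442324891587631e-01
+4.13281069183951688e-03
-1.25720175972414389e-01
-3.85347650675589484e-03
-1.30376839746992670e-02
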