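# q-shift orthonormal scaling filter (tree A; tree B is the time reverse)
-4.54498649713540055e-03
-5.61006272293590805e-03
+5.64518366234563751e-02
+6.47335215778226114e-02
-1.14837104524229058e-01
-1.13466349095372329e-01
+3.29321946263817833e-01
+7.38945170343642710e-01
+5.39306724300916196e-01
+3.87685937710558690e-02
-1.16012521530700838e-01
+1.64994386571150030e-02
+4.35253513616730217e-02
-5.39120364402795038e-02
-2.61044648112507827e-02
+2.11485050954993495e-02
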