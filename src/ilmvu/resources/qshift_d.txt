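# q-shift orthonormal scaling filter (tree A; tree B is the time reverse)
+3.54125131627200176e-02
-4.09772250052876713e-04
-5.36776021211840398e-02
+1.34102257963452029e-02
+6.73541936703677957e-02
-6.82545432620932924e-02
-1.06699264157775447e-01
+3.03917772089749405e-01
+7.25178146431599835e-01
+5.70821966986815532e-01
+5.05432303127635457e-02
-1.50866680109654233e-01
-1.67061840166474219e-02
+6.99388562359885696e-02
+5.89609679020047101e-03
-1.46554158387866146e-02
-1.94348885497190740e-04
-1.67956284617641512e-02
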