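# q-shift orthonormal scaling filter (tree A; tree B is the time reverse)
+8.21765048981776269e-02
-2.67488588670378273e-02
-1.27099683691878795e-01
+3.04416792347749876e-01
+7.48797387246974866e-01
+5.56685089245819276e-01
+7.77318423740375880e-03
-1.13296802225035215e-01
-4.54061150413011087e-03
-1.39494393149486289e-02
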