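# q-shift orthonormal scaling filter (tree A; tree B is the time reverse)
-4.69991671043697851e-02
+7.74870223132749936e-03
+8.47819210794249767e-02
-5.40117125402275744e-02
-1.11545631679460883e-01
+3.00428082402792174e-01
+7.52622666109624472e-01
+5.45631141863398561e-01
+3.64517718455971695e-02
-1.35528823198294901e-01
-1.11598958160374889e-02
+2.49153533587664518e-02
+2.95511675176858947e-03
+1.79240370687854186e-02
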