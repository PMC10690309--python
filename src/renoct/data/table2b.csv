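true_label,cortex,medulla,calyx,fat,pelvis,tumor
cortex,9964,1,1,34,0,0
medulla,15,9978,7,0,0,0
calyx,69,38,9639,0,0,254
fat,121,0,30,9822,0,27
pelvis,0,11,15,1,9973,0
tumor,10,0,22,0,0,9968
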