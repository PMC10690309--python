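true_label,cortex,medulla,calyx,fat,tumor
cortex,9145,14,723,0,118
medulla,3,9154,756,87,0
calyx,4326,2820,1947,347,560
fat,1895,1872,1083,4942,208
tumor,17,0,0,0,9983
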