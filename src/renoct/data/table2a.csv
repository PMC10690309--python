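true_label,cortex,medulla,calyx,fat,pelvis,tumor
cortex,9875,75,23,27,0,0
medulla,43,9956,1,0,0,0
calyx,136,15,9553,148,0,148
fat,199,0,56,9745,0,0
pelvis,0,0,21,0,9969,10
tumor,123,0,0,9,2,9866
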