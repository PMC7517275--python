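# Synthetic-free reference fixture: published LDA confusion matrix for the
# 40-component PCA path (5 tissue classes, rows = true class, cols = predicted).
true\pred,fat,skin,nerve,bone,muscle
fat,279,0,0,1,0
skin,1,231,0,0,0
nerve,1,0,279,0,0
bone,3,0,0,301,0
muscle,0,0,0,2,214
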