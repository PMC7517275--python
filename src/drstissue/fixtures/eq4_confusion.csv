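# Synthetic-free reference fixture: published LDA confusion matrix for the
# gradient-feature path (5 tissue classes, rows = true class, cols = predicted).
true\pred,fat,skin,nerve,bone,muscle
fat,249,4,6,21,0
skin,27,195,10,0,0
nerve,26,6,245,3,0
bone,49,2,0,224,29
muscle,12,0,0,43,161
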