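block,Traditional,MD,CAE
VGG,0.631,0.637,0.75
ResNet,0.633,0.642,0.697
DenseNet,0.685,0.681,0.689
MobileNet,0.603,0.612,0.638
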