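block,Traditional,MD,CAE
VGG,83,87,93
ResNet,92,93,94
DenseNet,96,95,98
MobileNet,90,91,92
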