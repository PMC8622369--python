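block,Traditional,MD,CAE
VGG,80.0,83.2,87.6
ResNet,90.3,91.4,92.4
DenseNet,93.0,92.9,93.5
MobileNet,94.6,92.9,93.5
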