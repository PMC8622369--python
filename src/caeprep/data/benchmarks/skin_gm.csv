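block,Traditional,MD,CAE
VGG,38,39,40
ResNet,37,39,42
DenseNet,42,41,41
MobileNet,35,36,39
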