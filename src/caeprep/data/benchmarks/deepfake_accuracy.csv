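block,Traditional,MD,CAE
VGG,73.3,76.4,82.0
ResNet,80.8,81.2,82.1
DenseNet,84.3,83.4,86.1
MobileNet,79.0,79.5,81.0
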